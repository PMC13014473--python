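"""Independent brute-force oracles used by the test suite.

Everything here works by exhaustive enumeration of legal state paths (a path
is a composition of the signal length into per-k-mer dwells of at least 2),
with no dynamic programming, so results can be compared against the
forward/backward implementation without sharing code paths.
"""

import math
from typing import Iterator, List, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from squigseg.hmm_core import TransitionParams, emission_logpdf
from squigseg.pore_model import KmerModel


def dwell_compositions(total: int, parts: int) -> Iterator[Tuple[int, ...]]:
    """All ways to split ``total`` signal samples into ``parts`` dwells >= 2."""
    if parts == 1:
        if total >= 2:
            yield (total,)
        return
    for d in range(2, total - 2 * (parts - 1) + 1):
        for rest in dwell_compositions(total - d, parts - 1):
            yield (d,) + rest


def path_log_prob(
    samples: Sequence[float],
    kmers: Sequence[int],
    dwells: Tuple[int, ...],
    params: TransitionParams,
    model: KmerModel,
) -> float:
    """Joint log-probability of one legal path: emissions plus the fixed
    transition budget (n-1 a1 steps, n e1 steps, T-2n e2 steps)."""
    n, T = len(kmers), len(samples)
    lp = (n - 1) * math.log(params.a1) + n * math.log(params.e1)
    if T - 2 * n:
        lp += (T - 2 * n) * math.log(params.e2)
    i = 0
    for j, d in enumerate(dwells):
        for _ in range(d):
            lp += emission_logpdf(samples[i], kmers[j], model)
            i += 1
    return lp


def all_paths(samples, kmers, params, model) -> List[Tuple[Tuple[int, ...], float]]:
    n, T = len(kmers), len(samples)
    return [
        (dw, path_log_prob(samples, kmers, dw, params, model))
        for dw in dwell_compositions(T, n)
    ]


def oracle_log_Z(samples, kmers, params, model) -> float:
    return float(logsumexp([lp for _, lp in all_paths(samples, kmers, params, model)]))


def oracle_posteriors(samples, kmers, params, model):
    """Per-cell posteriors from enumerated path weights: P(A at (j,i)) is the
    total weight of paths whose segment j starts at i, etc."""
    n, T = len(kmers), len(samples)
    paths = all_paths(samples, kmers, params, model)
    log_Z = logsumexp([lp for _, lp in paths])
    pA = np.zeros((n, T))
    pE = np.zeros((n, T))
    for dw, lp in paths:
        w = math.exp(lp - log_Z)
        i = 0
        for j, d in enumerate(dw):
            pA[j, i] += w
            for q in range(1, d):
                pE[j, i + q] += w
            i += d
    return pA, pE, float(log_Z)


def path_posterior_score(dwells, pA, pE) -> float:
    """Sum of log posteriors along one path (the decode's objective)."""
    with np.errstate(divide="ignore"):
        lA, lE = np.log(pA), np.log(pE)
    s, i = 0.0, 0
    for j, d in enumerate(dwells):
        s += lA[j, i]
        for q in range(1, d):
            s += lE[j, i + q]
        i += d
    return float(s)


def oracle_map_path(samples, kmers, params, model) -> Tuple[Tuple[int, ...], float]:
    """Argmax of the summed log-posterior objective over all legal paths.

    Ties prefer the lexicographically largest dwell tuple (i.e. the latest
    boundaries), matching the decoder's prefer-extend rule.
    """
    n, T = len(kmers), len(samples)
    pA, pE, _ = oracle_posteriors(samples, kmers, params, model)
    best, best_score = None, -np.inf
    for dw in dwell_compositions(T, n):
        s = path_posterior_score(dw, pA, pE)
        if s > best_score + 1e-12 or (abs(s - best_score) <= 1e-12 and (best is None or dw > best)):
            best, best_score = dw, s
    return best, best_score


def oracle_expected_stats(samples, kmers, params, model):
    """Path-weighted expected sufficient statistics (transition uses and
    per-cell occupancy), straight from the enumeration."""
    n, T = len(kmers), len(samples)
    paths = all_paths(samples, kmers, params, model)
    log_Z = logsumexp([lp for _, lp in paths])
    exp_a1 = exp_e2 = exp_E = 0.0
    for dw, lp in paths:
        w = math.exp(lp - log_Z)
        exp_a1 += w * (n - 1)
        exp_e2 += w * (T - 2 * n)
        exp_E += w * (T - n)
    return {"a1_uses": exp_a1, "e2_uses": exp_e2, "E_occupancy": exp_E}


def min_segment_over_all_paths(T_max: int = 6, n_max: int = 2) -> int:
    """Minimum dwell over every legal path of every feasible instance shape."""
    best = None
    for n in range(1, n_max + 1):
        for T in range(2 * n, T_max + 1):
            for dw in dwell_compositions(T, n):
                m = min(dw)
                best = m if best is None else min(best, m)
    return best
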