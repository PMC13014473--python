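"""Baum-Welch re-estimation of transition and k-mer emission parameters.

The E-step accumulates posterior-weighted sufficient statistics from the
forward/backward matrices of each read; the M-step re-estimates a1 (and
e2 = 1 - a1) from expected transition usage and each k-mer's Gaussian
(mu_k, sigma_k) from posterior-weighted signal moments.  e1 is structural
(the single edge out of A) and is not trained.  Total log Z is
non-decreasing across iterations, the standard EM guarantee.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .hmm_core import (
    AlignmentResult,
    PosteriorMatrices,
    TransitionParams,
    emission_matrix,
    forward_backward,
    make_band,
    posterior,
)
from .pore_model import BasecalledRead, KmerModel, Orientation, SignalRead, sequence_to_kmers

logger = logging.getLogger(__name__)

SIGMA_MIN = 0.01  # floor on trained sigma_k, in model units


@dataclass
class SufficientStats:
    """Accumulated expectations over one E-step."""

    n_kmers_model: int
    exp_a1_uses: float = 0.0
    exp_e2_uses: float = 0.0
    exp_E_occupancy: float = 0.0
    weight: np.ndarray = None  # per model k-mer: total posterior occupancy
    weight_x: np.ndarray = None  # posterior-weighted signal sums
    weight_x2: np.ndarray = None  # posterior-weighted squared sums
    total_log_Z: float = 0.0
    n_reads: int = 0

    def __post_init__(self):
        if self.weight is None:
            self.weight = np.zeros(self.n_kmers_model)
            self.weight_x = np.zeros(self.n_kmers_model)
            self.weight_x2 = np.zeros(self.n_kmers_model)


def expected_counts(
    post: PosteriorMatrices,
    result: AlignmentResult,
    params: TransitionParams,
    model: KmerModel,
    signal: SignalRead,
    stats: Optional[SufficientStats] = None,
) -> SufficientStats:
    """Add one read's expected transition uses and emission moments to ``stats``.

    Expected a1 uses are the posterior mass of all A cells except the origin
    (every path enters A[0] exactly once without spending a1); expected e2
    uses come from the E->E transition posteriors
    exp(alpha_E[j, i-1] + ln e2 + emis[j, i] + beta_E[j, i] - log Z).
    Per-k-mer weights are the cell posteriors post_A + post_E, so each
    signal column contributes total weight 1.
    """
    if stats is None:
        stats = SufficientStats(n_kmers_model=model.n_kmers)
    pA, pE = post.post_A, post.post_E
    kmers = post.kmer_indices
    x = signal.samples

    stats.exp_a1_uses += float(pA.sum() - pA[0, 0])
    stats.exp_E_occupancy += float(pE.sum())
    em = emission_matrix(x, kmers, model)
    with np.errstate(invalid="ignore"):
        xi_e2 = np.exp(
            result.log_forward_E[:, :-1]
            + params.log_e2
            + em[:, 1:]
            + result.log_backward_E[:, 1:]
            - result.log_Z
        )
    stats.exp_e2_uses += float(np.nan_to_num(xi_e2, nan=0.0).sum())

    w = pA + pE
    occ = w.sum(axis=1)
    np.add.at(stats.weight, kmers, occ)
    np.add.at(stats.weight_x, kmers, w @ x)
    np.add.at(stats.weight_x2, kmers, w @ (x * x))
    stats.total_log_Z += result.log_Z
    stats.n_reads += 1
    return stats


def m_step(
    stats: SufficientStats,
    prior_params: TransitionParams,
    prior_model: KmerModel,
    sigma_min: float = SIGMA_MIN,
) -> Tuple[TransitionParams, KmerModel]:
    """Re-estimate (a1, e2) and the k-mer Gaussians from one E-step.

    a1 = E[a1 uses] / E[E-state occupancy]; k-mers with (numerically) zero
    occupancy keep their prior parameters, with a logged notice.
    """
    if stats.exp_E_occupancy > 0:
        a1 = float(np.clip(stats.exp_a1_uses / stats.exp_E_occupancy, 1e-9, 1.0 - 1e-9))
    else:
        a1 = prior_params.a1
    params = TransitionParams(a1=a1, e1=prior_params.e1)

    means = prior_model.means.copy()
    stdvs = prior_model.stdvs.copy()
    occupied = stats.weight > 1e-12
    n_kept = int((~occupied).sum())
    if n_kept:
        logger.info("%d k-mers had zero occupancy; keeping prior parameters", n_kept)
    w = stats.weight[occupied]
    mu = stats.weight_x[occupied] / w
    var = stats.weight_x2[occupied] / w - mu * mu
    means[occupied] = mu
    stdvs[occupied] = np.sqrt(np.maximum(var, sigma_min ** 2))
    model = KmerModel(
        k=prior_model.k, kmers=prior_model.kmers, means=means, stdvs=stdvs
    )
    return params, model


@dataclass
class TrainState:
    """Result of a Baum-Welch fit: final parameters and the log Z trajectory."""

    iteration: int
    params: TransitionParams
    model: KmerModel
    log_Z_trajectory: List[float]
    tol: float
    converged: bool


def _prepare(dataset, model, orientation) -> List[Tuple[SignalRead, np.ndarray]]:
    prepared = []
    for signal, read in dataset:
        if isinstance(read, BasecalledRead):
            kmers = sequence_to_kmers(read, model, orientation)
        else:
            kmers = np.asarray(read, dtype=np.int64)
        prepared.append((signal, kmers))
    return prepared


def e_step(
    prepared: Sequence[Tuple[SignalRead, np.ndarray]],
    params: TransitionParams,
    model: KmerModel,
    band_width: Union[int, str] = "full",
) -> SufficientStats:
    stats = SufficientStats(n_kmers_model=model.n_kmers)
    for signal, kmers in prepared:
        band = make_band(len(signal), kmers.size, band_width)
        result = forward_backward(signal, kmers, params, model, band)
        post = posterior(result)
        expected_counts(post, result, params, model, signal, stats)
    return stats


def fit(
    dataset: Iterable[Tuple[SignalRead, Union[BasecalledRead, np.ndarray]]],
    init_params: Optional[TransitionParams] = None,
    init_model: Optional[KmerModel] = None,
    *,
    model: Optional[KmerModel] = None,
    orientation: Orientation = Orientation.DNA_5TO3,
    max_iter: int = 20,
    tol: float = 1e-3,
    band_width: Union[int, str] = "full",
    train_emissions: bool = True,
    train_transitions: bool = True,
) -> TrainState:
    """Iterate E/M until the total log Z improves by less than ``tol``.

    ``dataset`` yields (SignalRead, BasecalledRead-or-kmer-index-array) pairs;
    signals must already be in model space.  ``init_model`` defaults to
    ``model`` (also used to window sequences); ``init_params`` defaults to
    a1 = 0.1 (mean dwell 11 samples, a typical samples-per-base figure at
    nanopore translocation speeds).
    """
    if init_model is None:
        init_model = model
    if init_model is None:
        raise ValueError("provide init_model (or model=) to start from")
    if init_params is None:
        init_params = TransitionParams(a1=0.1)
    prepared = _prepare(dataset, init_model, orientation)

    params, kmodel = init_params, init_model
    trajectory: List[float] = []
    converged = False
    updates = 0
    while updates < max_iter:
        stats = e_step(prepared, params, kmodel, band_width)
        trajectory.append(stats.total_log_Z)
        if len(trajectory) >= 2 and trajectory[-1] - trajectory[-2] < tol:
            converged = True
            break
        new_params, new_model = m_step(stats, params, kmodel)
        if train_transitions:
            params = new_params
        if train_emissions:
            kmodel = new_model
        updates += 1
    return TrainState(
        iteration=updates,
        params=params,
        model=kmodel,
        log_Z_trajectory=trajectory,
        tol=tol,
        converged=converged,
    )
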