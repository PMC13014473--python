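"""Two-state forward-backward HMM over (k-mer, signal) alignment lattices.

The model has states A ("align": advance one k-mer and open a new segment)
and E ("extend": stay on the current k-mer, consume one more signal sample).
Three transitions exist: a1 starts a new segment (E -> A), e1 is the first
extension after a segment opens (A -> E, structurally probability 1), and e2
continues an extension (E -> E).  Because every segment consists of exactly
one A step followed by at least one E step, no segment can be shorter than
2 signal samples -- the topology itself enforces the bound.

Both states emit the observed current sample from the Gaussian of the k-mer
occupying the pore, N(mu_k, sigma_k).  All computation is in natural-log
space; the forward score alpha[j, i] accumulates paths aligning samples
t_0..t_i with k-mers k_0..k_j such that the path occupies k_j at time i, the
backward score beta[j, i] accumulates the continuations.  The terminal
forward score Z sits at E[n-1, T-1]; the backward pass reproduces it at the
origin (Z*), and exp(alpha + beta - log Z) yields per-cell posteriors.

A rectangular diagonal band restricts the admissible k-mer range per signal
index; computation outside the band is skipped (cells stay -inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .errors import BandError, InfeasibleReadError, InputError, NumericalConsistencyError
from .pore_model import KmerModel, SignalRead

_LOG_2PI = math.log(2.0 * math.pi)
NEG_INF = -np.inf


@dataclass(frozen=True)
class TransitionParams:
    """The three transition probabilities of the A/E topology.

    ``a1`` opens a new segment from E, ``e2 = 1 - a1`` continues one, and
    ``e1`` (the single edge out of A) is structurally 1 unless training
    overrides it.  The expected dwell per k-mer is 1 + 1/a1 samples.
    """

    a1: float
    e1: float = 1.0
    e2: Optional[float] = None

    def __post_init__(self):
        e2 = 1.0 - self.a1 if self.e2 is None else self.e2
        object.__setattr__(self, "e2", float(e2))
        for name, p in (("a1", self.a1), ("e1", self.e1), ("e2", self.e2)):
            if not (0.0 < p <= 1.0):
                raise InputError(f"transition {name}={p} outside (0, 1]")
        if abs(self.a1 + self.e2 - 1.0) > 1e-12:
            raise InputError(f"a1 + e2 = {self.a1 + self.e2} != 1")

    @property
    def log_a1(self) -> float:
        return math.log(self.a1)

    @property
    def log_e1(self) -> float:
        return math.log(self.e1)

    @property
    def log_e2(self) -> float:
        return math.log(self.e2) if self.e2 > 0 else NEG_INF


@dataclass(frozen=True)
class Band:
    """Per-signal-index admissible k-mer range [lo[i], hi[i]] (inclusive)."""

    lo: np.ndarray
    hi: np.ndarray
    n_kmers: int
    width: Union[int, str]

    @property
    def T(self) -> int:
        return self.lo.size

    @property
    def is_full(self) -> bool:
        return bool(np.all(self.lo == 0) and np.all(self.hi == self.n_kmers - 1))

    def as_mask(self) -> np.ndarray:
        """(n_kmers, T) boolean mask of in-band cells."""
        j = np.arange(self.n_kmers)[:, None]
        return (j >= self.lo[None, :]) & (j <= self.hi[None, :])

    def contains(self, j: int, i: int) -> bool:
        return bool(self.lo[i] <= j <= self.hi[i])


def make_band(T: int, n_kmers: int, band_width: Union[int, str] = "full") -> Band:
    """Rectangular diagonal band of half-width ``band_width`` k-mer positions.

    For signal index i the band is centred on the rounded diagonal
    j = round(i * (n_kmers - 1) / (T - 1)) (half-even rounding) and clamped to
    [0, n_kmers - 1]; the origin (0, 0) and terminal (n_kmers - 1, T - 1)
    cells are always inside.  ``"full"`` admits every cell.
    """
    if T < 2 or n_kmers < 1:
        raise InputError(f"need T >= 2 and n_kmers >= 1, got T={T}, n_kmers={n_kmers}")
    if band_width == "full":
        return Band(
            lo=np.zeros(T, dtype=np.int64),
            hi=np.full(T, n_kmers - 1, dtype=np.int64),
            n_kmers=n_kmers,
            width="full",
        )
    w = int(band_width)
    if w < 0:
        raise InputError(f"band_width must be >= 0 or 'full', got {band_width}")
    centers = np.rint(np.arange(T) * (n_kmers - 1) / (T - 1)).astype(np.int64)
    lo = np.clip(centers - w, 0, n_kmers - 1)
    hi = np.clip(centers + w, 0, n_kmers - 1)
    return Band(lo=lo, hi=hi, n_kmers=n_kmers, width=w)


@dataclass
class AlignmentResult:
    """Banded log-space forward/backward matrices with terminal scores.

    Matrices have shape (n_kmers, T); cells outside the band are -inf.
    ``log_Z`` is read at E[n-1, T-1] on the forward pass, ``log_Z_star`` at
    the origin on the backward pass; the two agree to numerical tolerance.
    """

    kmer_indices: np.ndarray
    band: Band
    log_forward_A: Optional[np.ndarray] = None
    log_forward_E: Optional[np.ndarray] = None
    log_backward_A: Optional[np.ndarray] = None
    log_backward_E: Optional[np.ndarray] = None
    log_Z: Optional[float] = None
    log_Z_star: Optional[float] = None


@dataclass
class PosteriorMatrices:
    """Per-cell posterior occupancy P(state, j | T) per signal index i."""

    post_A: np.ndarray
    post_E: np.ndarray
    band: Band
    kmer_indices: np.ndarray


@dataclass(frozen=True)
class Segment:
    """One contiguous signal interval assigned to one k-mer (>= 2 samples)."""

    kmer_index: int
    kmer: str
    signal_start: int  # 0-based inclusive
    signal_end: int  # exclusive
    mean_posterior: float
    border_probability: float

    def __len__(self) -> int:
        return self.signal_end - self.signal_start


@dataclass(frozen=True)
class Segmentation:
    """Ordered, contiguous segments covering [0, T), one per k-mer index.

    ``orientation`` and ``sequence_length`` (when known) let writers report
    base positions in original-sequence coordinates for 3'->5' RNA reads.
    """

    read_id: str
    segments: tuple
    orientation: str = "dna_5to3"
    sequence_length: Optional[int] = None

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """Internal segment starts (excludes 0 and T)."""
        return np.array([s.signal_start for s in self.segments[1:]], dtype=np.int64)


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------

def emission_logpdf(sample: float, kmer_index: int, model: KmerModel) -> float:
    """ln N(sample; mu_k, sigma_k) for the k-mer at ``kmer_index``."""
    if not np.isfinite(sample):
        raise InputError(f"non-finite signal sample {sample!r}")
    mu = model.means[kmer_index]
    sd = model.stdvs[kmer_index]
    z = (sample - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def emission_matrix(samples: np.ndarray, kmer_indices: np.ndarray, model: KmerModel) -> np.ndarray:
    """Dense (n_kmers_in_read, T) matrix of emission log-densities."""
    if not np.all(np.isfinite(samples)):
        raise InputError("non-finite signal samples")
    mu = model.means[kmer_indices][:, None]
    sd = model.stdvs[kmer_indices][:, None]
    z = (samples[None, :] - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _check_instance(T: int, n: int, band: Band) -> None:
    if n < 1:
        raise InfeasibleReadError("empty k-mer series")
    if T < 2 * n:
        raise InfeasibleReadError(
            f"signal of length {T} cannot host {n} segments of >= 2 samples "
            f"(need T >= {2 * n})"
        )
    if band.T != T or band.n_kmers != n:
        raise BandError(f"band shape ({band.n_kmers}, {band.T}) != instance ({n}, {T})")
    if not band.contains(0, 0):
        raise BandError("band excludes the origin cell (j=0, i=0)")
    if not band.contains(n - 1, T - 1):
        raise BandError(f"band excludes the terminal cell (j={n - 1}, i={T - 1})")


# ---------------------------------------------------------------------------
# Forward / backward passes
# ---------------------------------------------------------------------------

def forward_pass(
    signal: SignalRead,
    kmers: np.ndarray,
    params: TransitionParams,
    model: KmerModel,
    band: Optional[Band] = None,
    _em: Optional[np.ndarray] = None,
) -> AlignmentResult:
    """Banded log-space forward recursion.

    A[j, i] = E[j-1, i-1] + ln a1 + emis(j, i); origin A[0, 0] = emis(0, 0).
    E[j, i] = logaddexp(A[j, i-1] + ln e1, E[j, i-1] + ln e2) + emis(j, i).
    log_Z is read at E[n-1, T-1].
    """
    kmers = np.asarray(kmers, dtype=np.int64)
    T, n = len(signal), kmers.size
    if band is None:
        band = make_band(T, n, "full")
    _check_instance(T, n, band)
    em = emission_matrix(signal.samples, kmers, model) if _em is None else _em

    la1, le1, le2 = params.log_a1, params.log_e1, params.log_e2
    fA = np.full((n, T), NEG_INF)
    fE = np.full((n, T), NEG_INF)
    fA[0, 0] = em[0, 0] if band.contains(0, 0) else NEG_INF
    in_band = band.as_mask()
    shiftA = np.empty(n)
    for i in range(1, T):
        shiftA[0] = NEG_INF
        shiftA[1:] = fE[:-1, i - 1] + la1
        colE = np.logaddexp(fA[:, i - 1] + le1, fE[:, i - 1] + le2)
        col_em = em[:, i]
        fA[:, i] = np.where(in_band[:, i], shiftA + col_em, NEG_INF)
        fE[:, i] = np.where(in_band[:, i], colE + col_em, NEG_INF)
    log_Z = float(fE[n - 1, T - 1])
    if not np.isfinite(log_Z):
        raise BandError("no legal path reaches the terminal cell inside the band")
    return AlignmentResult(
        kmer_indices=kmers,
        band=band,
        log_forward_A=fA,
        log_forward_E=fE,
        log_Z=log_Z,
    )


def backward_pass(
    signal: SignalRead,
    kmers: np.ndarray,
    params: TransitionParams,
    model: KmerModel,
    band: Optional[Band] = None,
    result: Optional[AlignmentResult] = None,
    _em: Optional[np.ndarray] = None,
) -> AlignmentResult:
    """Banded log-space backward recursion (mirror of the forward pass).

    beta excludes the current cell's emission; terminal condition
    beta_E[n-1, T-1] = 0, and log_Z_star = beta_A[0, 0] + emis(0, 0) is read
    at the origin.  If ``result`` (from :func:`forward_pass`) is given, the
    backward half is stored there and forward/backward consistency
    |log_Z - log_Z*| <= 1e-6 is enforced.
    """
    kmers = np.asarray(kmers, dtype=np.int64)
    T, n = len(signal), kmers.size
    if band is None:
        band = result.band if result is not None else make_band(T, n, "full")
    _check_instance(T, n, band)
    em = emission_matrix(signal.samples, kmers, model) if _em is None else _em

    la1, le1, le2 = params.log_a1, params.log_e1, params.log_e2
    bA = np.full((n, T), NEG_INF)
    bE = np.full((n, T), NEG_INF)
    if band.contains(n - 1, T - 1):
        bE[n - 1, T - 1] = 0.0
    in_band = band.as_mask()
    up = np.empty(n)
    for i in range(T - 2, -1, -1):
        nxt_em = em[:, i + 1]
        # A[j, i] -> E[j, i+1] with e1
        colA = bE[:, i + 1] + le1 + nxt_em
        # E[j, i] -> A[j+1, i+1] with a1, or E[j, i+1] with e2
        up[:-1] = bA[1:, i + 1] + la1 + em[1:, i + 1]
        up[-1] = NEG_INF
        colE = np.logaddexp(up, bE[:, i + 1] + le2 + nxt_em)
        bA[:, i] = np.where(in_band[:, i], colA, NEG_INF)
        bE[:, i] = np.where(in_band[:, i], colE, NEG_INF)
    log_Z_star = float(bA[0, 0] + em[0, 0])
    if not np.isfinite(log_Z_star):
        raise BandError("no legal path reaches the origin cell inside the band")
    if result is None:
        result = AlignmentResult(kmer_indices=kmers, band=band)
    result.log_backward_A = bA
    result.log_backward_E = bE
    result.log_Z_star = log_Z_star
    if result.log_Z is not None and abs(result.log_Z - log_Z_star) > 1e-6:
        raise NumericalConsistencyError(
            f"|log_Z - log_Z*| = {abs(result.log_Z - log_Z_star):.3e} > 1e-6"
        )
    return result


def forward_backward(
    signal: SignalRead,
    kmers: np.ndarray,
    params: TransitionParams,
    model: KmerModel,
    band: Optional[Band] = None,
) -> AlignmentResult:
    """Run both passes on one emission matrix and return the full result."""
    kmers = np.asarray(kmers, dtype=np.int64)
    if band is None:
        band = make_band(len(signal), kmers.size, "full")
    em = emission_matrix(signal.samples, kmers, model)
    res = forward_pass(signal, kmers, params, model, band, _em=em)
    return backward_pass(signal, kmers, params, model, band, result=res, _em=em)


# ---------------------------------------------------------------------------
# Posteriors and MAP extraction
# ---------------------------------------------------------------------------

def posterior(result: AlignmentResult, drift_tol: float = 1e-6) -> PosteriorMatrices:
    """Per-cell posteriors exp(alpha + beta - log Z), clipped to [0, 1].

    Numerical drift above 1 by more than ``drift_tol`` raises
    :class:`NumericalConsistencyError`; smaller excursions are clipped.
    """
    if result.log_forward_A is None or result.log_backward_A is None:
        raise InputError("posterior() needs both forward and backward halves")
    log_Z = result.log_Z
    with np.errstate(invalid="ignore"):
        pA = np.exp(result.log_forward_A + result.log_backward_A - log_Z)
        pE = np.exp(result.log_forward_E + result.log_backward_E - log_Z)
    pA = np.nan_to_num(pA, nan=0.0)  # -inf + inf never occurs; guard anyway
    pE = np.nan_to_num(pE, nan=0.0)
    drift = max(float(pA.max(initial=0.0)), float(pE.max(initial=0.0))) - 1.0
    if drift > drift_tol:
        raise NumericalConsistencyError(f"posterior exceeds 1 by {drift:.3e} > {drift_tol:.0e}")
    return PosteriorMatrices(
        post_A=np.clip(pA, 0.0, 1.0),
        post_E=np.clip(pE, 0.0, 1.0),
        band=result.band,
        kmer_indices=result.kmer_indices,
    )


def map_segmentation(
    post: PosteriorMatrices,
    params: Optional[TransitionParams] = None,
    model: Optional[KmerModel] = None,
    read_id: str = "",
) -> Segmentation:
    """MAP path through the posterior lattice ("posterior-Viterbi").

    Maximizes the sum of log-posteriors along a path restricted to the legal
    move set (A entered diagonally from the previous k-mer's E; E entered
    horizontally from A or E of the same k-mer).  Ties prefer extending (E)
    over opening a new segment, which favours longer segments and makes the
    output deterministic.  ``params`` is accepted for interface symmetry; the
    decode uses posteriors only.
    """
    pA, pE = post.post_A, post.post_E
    n, T = pA.shape
    with np.errstate(divide="ignore"):
        lpA = np.log(pA)
        lpE = np.log(pE)

    vA = np.full((n, T), NEG_INF)
    vE = np.full((n, T), NEG_INF)
    # from_A[j, i]: best predecessor of E[j, i] was A[j, i-1] (strictly better)
    from_A = np.zeros((n, T), dtype=bool)
    vA[0, 0] = lpA[0, 0]
    for i in range(1, T):
        vA[1:, i] = vE[:-1, i - 1] + lpA[1:, i]
        take_A = vA[:, i - 1] > vE[:, i - 1]
        vE[:, i] = np.where(take_A, vA[:, i - 1], vE[:, i - 1]) + lpE[:, i]
        from_A[:, i] = take_A
    if not np.isfinite(vE[n - 1, T - 1]):
        raise BandError("no legal MAP path inside the band")

    # Backtrack from E[n-1, T-1]; record the signal index where each A occurs.
    starts = np.empty(n, dtype=np.int64)
    j, i, state = n - 1, T - 1, "E"
    while True:
        if state == "A":
            starts[j] = i
            if j == 0:
                break
            j, i, state = j - 1, i - 1, "E"
        else:
            state = "A" if from_A[j, i] else "E"
            i -= 1
    if i != 0:
        raise NumericalConsistencyError("MAP backtrack did not reach the origin")

    border_prob = pA.sum(axis=0)
    ends = np.append(starts[1:], T)
    segments = []
    for jj in range(n):
        s, e = int(starts[jj]), int(ends[jj])
        occ = pA[jj, s:e] + pE[jj, s:e]
        kidx = int(post.kmer_indices[jj])
        segments.append(
            Segment(
                kmer_index=jj,
                kmer=model.kmers[kidx] if model is not None else "",
                signal_start=s,
                signal_end=e,
                mean_posterior=float(np.mean(occ)),
                border_probability=float(border_prob[s]),
            )
        )
    return Segmentation(read_id=read_id, segments=tuple(segments))
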