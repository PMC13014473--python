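"""K-mer pore models, read containers, and signal normalization.

A pore model is a lookup table mapping each k-mer context in the nanopore to
the Gaussian parameters (level mean mu_k, level spread sigma_k) of the current
it produces.  R9.4.1 chemistries use k=5, R10.4.1 ones k=9; any k >= 1 is
accepted (with a logged notice for unusual k).  RNA alphabets (U) are
canonicalized to T at load time so one model serves both nucleic acids.

Signals are carried as :class:`SignalRead` (a finite time series of current
values) and basecalled sequences as :class:`BasecalledRead`.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSignalError,
    InfeasibleReadError,
    InputError,
    ModelCompletenessError,
    ModelFormatError,
    ModelValidationError,
)

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CANONICAL = str.maketrans("acgtuU", "ACGTTT")


class Orientation(str, enum.Enum):
    """Direction in which k-mers of the basecalled sequence meet the pore.

    DNA translocates 5'->3' in signal time order; direct RNA is sequenced
    3'->5', so its basecalled sequence must be reversed before windowing to
    match signal time order.  There is no autodetection: the caller states
    the chemistry.
    """

    DNA_5TO3 = "dna_5to3"
    RNA_3TO5 = "rna_3to5"


@dataclass(frozen=True)
class KmerModel:
    """Per-k-mer Gaussian emission parameters (mu_k, sigma_k).

    ``kmers`` is the canonical lexicographic ordering over ACGT^k; ``means``
    and ``stdvs`` are aligned float arrays.  All spreads are positive and all
    means finite (validated at construction).
    """

    k: int
    kmers: tuple
    means: np.ndarray
    stdvs: np.ndarray
    _index: Dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if len(self.kmers) != 4 ** self.k:
            raise ModelCompletenessError(
                f"expected {4 ** self.k} k-mers for k={self.k}, got {len(self.kmers)}"
            )
        if not np.all(np.isfinite(self.means)):
            raise ModelValidationError("non-finite level_mean in model")
        bad = np.asarray(self.stdvs) <= 0
        if bad.any():
            names = [self.kmers[i] for i in np.flatnonzero(bad)[:10]]
            raise ModelValidationError(f"non-positive level_stdv for {names}")
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "stdvs", np.asarray(self.stdvs, dtype=float))
        object.__setattr__(self, "_index", {km: i for i, km in enumerate(self.kmers)})
        if self.k not in (5, 9):
            logger.info("unusual k-mer length k=%d (expected 5 or 9)", self.k)

    @property
    def n_kmers(self) -> int:
        return len(self.kmers)

    def index(self, kmer: str) -> int:
        return self._index[kmer]

    @property
    def global_mean(self) -> float:
        """Mean of all level means: the model-space signal centre."""
        return float(np.mean(self.means))

    @property
    def global_spread(self) -> float:
        """Population standard deviation of level means: model-space scale."""
        return float(np.std(self.means))


@dataclass(frozen=True)
class SignalRead:
    """One read's raw current trace (the time series T with entries t_i)."""

    read_id: str
    samples: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InputError(f"read {self.read_id}: need >= 2 samples, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise InputError(f"read {self.read_id}: non-finite samples")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class BasecalledRead:
    """One basecalled nucleotide sequence N (canonicalized to ACGT)."""

    read_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.translate(_CANONICAL)
        if set(seq) - set(ALPHABET):
            raise InputError(
                f"read {self.read_id}: non-ACGTU characters {sorted(set(seq) - set(ALPHABET))}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def _all_kmers(k: int) -> List[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in ALPHABET]
    return kmers


def load_kmer_model(path) -> KmerModel:
    """Load a tab-separated pore model (columns kmer, level_mean, level_stdv).

    Extra columns are ignored; U is canonicalized to T; k is inferred from the
    first k-mer.  Raises :class:`ModelFormatError` on ragged k-mer lengths,
    :class:`ModelCompletenessError` when k-mers are missing (listing up to 10),
    and :class:`ModelValidationError` on non-positive spreads.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"kmer", "level_mean", "level_stdv"}
    if not required.issubset(df.columns):
        raise ModelFormatError(
            f"{path}: header must name columns {sorted(required)}, got {list(df.columns)}"
        )
    raw_kmers = [str(km).translate(_CANONICAL) for km in df["kmer"]]
    if not raw_kmers:
        raise ModelFormatError(f"{path}: empty model file")
    k = len(raw_kmers[0])
    if any(len(km) != k for km in raw_kmers):
        raise ModelFormatError(f"{path}: ragged k-mer lengths (first is k={k})")
    levels = dict(zip(raw_kmers, zip(df["level_mean"].astype(float), df["level_stdv"].astype(float))))
    expected = _all_kmers(k)
    missing = [km for km in expected if km not in levels]
    if missing:
        raise ModelCompletenessError(
            f"{path}: {len(missing)} of {len(expected)} k-mers missing "
            f"(first {min(10, len(missing))}: {missing[:10]})"
        )
    if len(levels) != len(raw_kmers):
        logger.warning("%s: duplicate k-mer rows; last occurrence wins", path)
    means = np.array([levels[km][0] for km in expected])
    stdvs = np.array([levels[km][1] for km in expected])
    bad = np.flatnonzero(stdvs <= 0)
    if bad.size:
        raise ModelValidationError(
            f"{path}: non-positive level_stdv for {[expected[i] for i in bad[:10]]}"
        )
    return KmerModel(k=k, kmers=tuple(expected), means=means, stdvs=stdvs)


def write_kmer_model(model: KmerModel, path) -> None:
    """Write a model as the same TSV dialect `load_kmer_model` reads.

    Floats use repr-level precision so load->write->load round-trips
    bit-identically.
    """
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\tlevel_stdv\n")
        for km, mu, sd in zip(model.kmers, model.means, model.stdvs):
            fh.write(f"{km}\t{float(mu)!r}\t{float(sd)!r}\n")


def toy_model(k: int, level_min: float = 50.0, spacing: float = 3.0, stdv: float = 1.0) -> KmerModel:
    """Synthetic pore model with evenly spaced, perfectly distinct level means.

    The i-th k-mer (lexicographic over ACGT) gets mean ``level_min + i*spacing``
    and spread ``stdv``.  This is a synthetic test/benchmark model: real pore
    models have overlapping, context-correlated levels; this one makes every
    k-mer identifiable, which is what zero-noise recovery experiments need.
    """
    kmers = _all_kmers(k)
    means = level_min + spacing * np.arange(len(kmers), dtype=float)
    stdvs = np.full(len(kmers), float(stdv))
    return KmerModel(k=k, kmers=tuple(kmers), means=means, stdvs=stdvs)


def sequence_to_kmers(read: BasecalledRead, model: KmerModel, orientation: Orientation) -> np.ndarray:
    """Map a basecalled sequence to the time-ordered series of k-mer indices.

    For RNA (sequenced 3'->5') the sequence is reversed before windowing so
    that k-mer order matches signal time order.  Returns N - k + 1 indices.
    """
    seq = read.sequence
    if len(seq) < model.k:
        raise InfeasibleReadError(
            f"read {read.read_id}: sequence length {len(seq)} < k={model.k}"
        )
    if Orientation(orientation) is Orientation.RNA_3TO5:
        seq = seq[::-1]
    return np.array(
        [model.index(seq[j:j + model.k]) for j in range(len(seq) - model.k + 1)],
        dtype=np.int64,
    )


class NormalizationMethod(str, enum.Enum):
    MEDIAN_MAD = "median_mad"
    NONE = "none"


def normalize_signal(read: SignalRead, method, model: KmerModel) -> SignalRead:
    """Map raw current samples into model space.

    ``median_mad`` computes z = (x - median) / MAD (raw MAD, no consistency
    factor) and rescales affinely into model space:
    ``model.global_spread * z + model.global_mean``, so the output median is
    exactly the model's global level mean.  ``none`` passes samples through.
    Either way the result is flagged normalized.
    """
    method = NormalizationMethod(method)
    if method is NormalizationMethod.NONE:
        return replace(read, normalized=True)
    x = read.samples
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateSignalError(
            f"read {read.read_id}: MAD is 0 (constant or near-constant signal)"
        )
    z = (x - med) / mad
    return SignalRead(
        read_id=read.read_id,
        samples=model.global_spread * z + model.global_mean,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Signal / read I/O
# ---------------------------------------------------------------------------

def write_signals_tsv(reads: Iterable[SignalRead], path) -> None:
    """Portable signal table: read_id TAB comma-joined samples, with header."""
    with open(path, "w") as fh:
        fh.write("read_id\tsamples\n")
        for read in reads:
            fh.write(read.read_id + "\t" + ",".join(repr(float(v)) for v in read.samples) + "\n")


def read_signals_tsv(path) -> Iterator[SignalRead]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["read_id", "samples"]:
            raise InputError(f"{path}: expected header 'read_id\\tsamples', got {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            read_id, joined = line.split("\t", 1)
            samples = np.array([float(v) for v in joined.split(",")])
            yield SignalRead(read_id=read_id, samples=samples)


def read_signals_pod5(path) -> Iterator[SignalRead]:
    """Yield SignalReads from a pod5 file (requires the optional pod5 package)."""
    try:
        import pod5  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading pod5 files requires the optional 'pod5' package "
            "(pip install squigseg[pod5]); alternatively convert to the "
            "portable signal TSV format"
        ) from exc
    with pod5.Reader(path) as reader:  # pragma: no cover - optional dependency
        for rec in reader.reads():
            yield SignalRead(read_id=str(rec.read_id), samples=np.asarray(rec.signal, dtype=float))


def read_basecalls(path) -> Iterator[BasecalledRead]:
    """Yield basecalled reads from FASTQ/FASTA or (unaligned) BAM/SAM.

    Only read_id and sequence are consumed.  Format is chosen by extension:
    .bam/.sam via pysam.AlignmentFile (no reference required), anything else
    via pysam.FastxFile.
    """
    import pysam

    suffix = Path(str(path)).suffix.lower()
    if suffix in (".bam", ".sam", ".cram"):
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                    continue
                yield BasecalledRead(read_id=rec.query_name, sequence=rec.query_sequence)
    else:
        with pysam.FastxFile(str(path)) as fx:
            for rec in fx:
                yield BasecalledRead(read_id=rec.name, sequence=rec.sequence)
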