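"""Per-read orchestration and tabular I/O.

Pairs raw signals with basecalled reads, runs the forward-backward HMM and
the MAP decode, and writes one TSV row per segment.  Reads the topology
cannot segment (signal shorter than twice the k-mer count, sequence shorter
than k, constant signal) are returned as structured infeasibility records,
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd

from .errors import (
    BandError,
    DegenerateSignalError,
    InfeasibleReadError,
    PairingError,
    SquigsegError,
)
from .hmm_core import (
    Segmentation,
    TransitionParams,
    forward_backward,
    make_band,
    map_segmentation,
    posterior,
)
from .pore_model import (
    BasecalledRead,
    KmerModel,
    NormalizationMethod,
    Orientation,
    SignalRead,
    normalize_signal,
    read_basecalls,
    read_signals_tsv,
    sequence_to_kmers,
)

logger = logging.getLogger(__name__)

SEGMENTATION_COLUMNS = (
    "read_id",
    "signal_start",
    "signal_end",
    "base_position",
    "kmer",
    "posterior",
    "border_prob",
)


@dataclass
class RunConfig:
    """Everything one segmentation run needs besides the data."""

    model: KmerModel
    orientation: Orientation = Orientation.DNA_5TO3
    normalization: NormalizationMethod = NormalizationMethod.MEDIAN_MAD
    band_width: Union[int, str] = 100
    params: TransitionParams = field(default_factory=lambda: TransitionParams(a1=0.1))
    threads: int = 1  # per-read independence; scheduling never changes outputs


@dataclass(frozen=True)
class InfeasibilityRecord:
    """Why a read could not be segmented (reported, never dropped)."""

    read_id: str
    reason: str
    detail: str = ""


def segment_read(
    signal: SignalRead,
    read: BasecalledRead,
    config: RunConfig,
) -> Union[Segmentation, InfeasibilityRecord]:
    """Segment one signal/read pair, or explain why it cannot be done.

    Reason codes: ``sequence_too_short`` (N < k), ``signal_too_short``
    (T < 2 * (N - k + 1)), ``degenerate_signal`` (MAD = 0 under median/MAD
    normalization).
    """
    if signal.read_id != read.read_id:
        raise PairingError(f"signal {signal.read_id!r} paired with read {read.read_id!r}")
    model = config.model
    if len(read) < model.k:
        return InfeasibilityRecord(
            read.read_id, "sequence_too_short", f"N={len(read)} < k={model.k}"
        )
    kmers = sequence_to_kmers(read, model, config.orientation)
    n, T = kmers.size, len(signal)
    if T < 2 * n:
        return InfeasibilityRecord(
            read.read_id, "signal_too_short", f"T={T} < 2*(N-k+1)={2 * n}"
        )
    try:
        norm = signal if signal.normalized else normalize_signal(
            signal, config.normalization, model
        )
    except DegenerateSignalError as exc:
        return InfeasibilityRecord(read.read_id, "degenerate_signal", str(exc))
    band = make_band(T, n, config.band_width)
    result = forward_backward(norm, kmers, config.params, model, band)
    post = posterior(result)
    seg = map_segmentation(post, config.params, model=model, read_id=read.read_id)
    return Segmentation(
        read_id=seg.read_id,
        segments=seg.segments,
        orientation=config.orientation,
        sequence_length=len(read),
    )


def _base_position(seg_kmer_index: int, k: int, orientation: Orientation,
                   sequence_length: Optional[int]) -> int:
    """Index of the k-mer's central base (left-of-centre for even k) in the
    original basecalled sequence."""
    pos = seg_kmer_index + (k - 1) // 2
    if Orientation(orientation) is Orientation.RNA_3TO5 and sequence_length is not None:
        return sequence_length - 1 - pos
    return pos


def segmentation_to_frame(segs: Iterable[Segmentation]) -> pd.DataFrame:
    rows = []
    for seg in segs:
        for s in seg:
            k = len(s.kmer) if s.kmer else 1
            rows.append(
                (
                    seg.read_id,
                    s.signal_start,
                    s.signal_end,
                    _base_position(s.kmer_index, k, seg.orientation, seg.sequence_length),
                    s.kmer,
                    s.mean_posterior,
                    s.border_probability,
                )
            )
    return pd.DataFrame(rows, columns=SEGMENTATION_COLUMNS)


def write_segmentation(segs: Iterable[Segmentation], path) -> None:
    """Write segments as TSV (floats with 6 decimals); header always present."""
    df = segmentation_to_frame(segs)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segmentation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SquigsegError(f"{path}: segmentation table missing columns {sorted(missing)}")
    return df


def run_dataset(
    signals: Union[str, Path, Iterable[SignalRead]],
    reads: Union[str, Path, Iterable[BasecalledRead]],
    config: RunConfig,
    out: Optional[Union[str, Path]] = None,
) -> Tuple[Dict[str, int], List[Segmentation], List[InfeasibilityRecord]]:
    """Segment every paired read; write a deterministic table if ``out`` given.

    Reads present in only one source are counted as unpaired (basecallers can
    split one signal into two reads), not treated as errors.  The summary
    satisfies segmented + infeasible + failed = paired reads.  Output rows are
    ordered by read_id, so reruns with the same inputs are byte-identical.
    """
    if isinstance(signals, (str, Path)):
        signals = read_signals_tsv(signals)
    if isinstance(reads, (str, Path)):
        reads = read_basecalls(reads)
    sig_by_id = {s.read_id: s for s in signals}
    read_by_id = {r.read_id: r for r in reads}
    paired = sorted(set(sig_by_id) & set(read_by_id))
    summary = {
        "segmented": 0,
        "infeasible": 0,
        "failed": 0,
        "unpaired_signals": len(set(sig_by_id) - set(read_by_id)),
        "unpaired_reads": len(set(read_by_id) - set(sig_by_id)),
        "input_pairs": len(paired),
    }
    segmentations: List[Segmentation] = []
    infeasible: List[InfeasibilityRecord] = []
    for read_id in paired:
        try:
            result = segment_read(sig_by_id[read_id], read_by_id[read_id], config)
        except SquigsegError as exc:
            summary["failed"] += 1
            logger.error("read %s failed: %s", read_id, exc)
            continue
        if isinstance(result, InfeasibilityRecord):
            summary["infeasible"] += 1
            infeasible.append(result)
            logger.warning("read %s infeasible: %s (%s)", read_id, result.reason, result.detail)
        else:
            summary["segmented"] += 1
            segmentations.append(result)
    if out is not None:
        write_segmentation(segmentations, out)
    return summary, segmentations, infeasible
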