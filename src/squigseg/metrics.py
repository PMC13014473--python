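"""Segmentation-quality metrics, 0-1 score normalization, and AM aggregation.

Signal-placement metrics assume a well-placed border separates regions that
differ in level and spread, while the interior of a segment (one k-mer's
signal) is homogeneous:

* border deltas -- for each internal border, the absolute difference of the
  median (or MAD) of the 6 samples left vs. right of it; higher is better.
* homogeneity -- the standard deviation of the inner 80 % of each segment
  spanning >= 10 samples; lower is better.

Read statistics (segmented/truncated counts, min/N50/max segmented length)
measure how much of the input survives segmentation.  Raw metric values are
normalized per metric across tools: higher-better metrics map x -> x/max,
lower-better metrics map x -> 1 - x/max, so the best tool scores 1.0 and a
raw 0 on a lower-better metric scores 1.0.  The aggregated metric (AM)
score is the plain column sum of a tool's normalized scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .hmm_core import Segmentation

logger = logging.getLogger(__name__)

HIGHER_BETTER = "higher"
LOWER_BETTER = "lower"

#: direction flags for the built-in metric rows
METRIC_DIRECTIONS: Dict[str, str] = {
    "median delta": HIGHER_BETTER,
    "MAD delta": HIGHER_BETTER,
    "homogeneity": LOWER_BETTER,
    "segmented reads": HIGHER_BETTER,
    "truncated reads": LOWER_BETTER,
    "min read length": LOWER_BETTER,
    "n50 read length": HIGHER_BETTER,
    "max read length": HIGHER_BETTER,
}


def _mad(x: np.ndarray) -> float:
    """Raw median absolute deviation (no consistency factor)."""
    return float(np.median(np.abs(x - np.median(x))))


def _boundaries(segmentation) -> np.ndarray:
    if isinstance(segmentation, Segmentation):
        return np.asarray(segmentation.boundaries, dtype=np.int64)
    return np.asarray(segmentation, dtype=np.int64)


def _segment_intervals(segmentation) -> List[Tuple[int, int]]:
    if isinstance(segmentation, Segmentation):
        return [(s.signal_start, s.signal_end) for s in segmentation]
    return [(int(a), int(b)) for a, b in segmentation]


def border_deltas(
    signal: np.ndarray,
    segmentation,
    window: int = 6,
    stat: str = "median",
) -> np.ndarray:
    """Per-border |stat(left window) - stat(right window)|.

    For each internal border at signal index i the statistic (median or raw
    MAD) of samples[i-window:i] is compared with samples[i:i+window].
    Borders with fewer than ``window`` samples on either side are skipped,
    not padded.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if stat not in ("median", "mad"):
        raise ValueError(f"stat must be 'median' or 'mad', got {stat!r}")
    x = np.asarray(signal.samples if hasattr(signal, "samples") else signal, dtype=float)
    fn = np.median if stat == "median" else _mad
    values = []
    for b in _boundaries(segmentation):
        if b < window or b + window > x.size:
            continue
        left = x[b - window:b]
        right = x[b:b + window]
        values.append(abs(float(fn(left)) - float(fn(right))))
    return np.asarray(values, dtype=float)


def homogeneity(
    signal: np.ndarray,
    segmentation,
    min_len: int = 10,
    inner_frac: float = 0.8,
) -> np.ndarray:
    """Per-segment standard deviation of the inner ``inner_frac`` samples.

    Segments shorter than ``min_len`` are skipped; the inner window drops
    ceil((1 - inner_frac)/2 * len) samples from each end, excluding signal
    transitioning between segments.  Lower is better.
    """
    x = np.asarray(signal.samples if hasattr(signal, "samples") else signal, dtype=float)
    trim_frac = (1.0 - inner_frac) / 2.0
    values = []
    for start, end in _segment_intervals(segmentation):
        length = end - start
        if length < min_len:
            continue
        trim = math.ceil(trim_frac * length)
        inner = x[start + trim:end - trim]
        values.append(float(np.std(inner)))
    return np.asarray(values, dtype=float)


def n50(lengths: Sequence[float]) -> float:
    """Length L such that reads of length >= L hold >= half the total bases."""
    arr = np.sort(np.asarray(lengths, dtype=float))[::-1]
    if arr.size == 0:
        return 0.0
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return float(arr[idx])


def segmented_lengths(segmentations: Iterable[Segmentation]) -> Dict[str, int]:
    """Per read, the number of basecalled nucleotides covered by segments."""
    out: Dict[str, int] = {}
    for seg in segmentations:
        if len(seg) == 0:
            out[seg.read_id] = 0
            continue
        k = len(seg.segments[0].kmer) or 1
        out[seg.read_id] = len(seg) + k - 1
    return out


def read_stats(
    input_lengths: Mapping[str, int],
    seg_lengths: Mapping[str, int],
) -> Dict[str, float]:
    """Read-retention statistics of one tool's output against its input.

    A read is truncated when its segmented base span is shorter than its
    basecalled length (strict: any uncovered nucleotide counts).  Length
    statistics are computed on segmented lengths.
    """
    lengths = [seg_lengths[rid] for rid in seg_lengths]
    truncated = sum(
        1 for rid, L in seg_lengths.items()
        if rid in input_lengths and L < input_lengths[rid]
    )
    return {
        "segmented reads": float(len(seg_lengths)),
        "truncated reads": float(truncated),
        "min read length": float(min(lengths)) if lengths else 0.0,
        "n50 read length": n50(lengths),
        "max read length": float(max(lengths)) if lengths else 0.0,
    }


def normalize_scores(raw: Sequence[float], direction: str) -> np.ndarray:
    """Normalize one metric's raw values across tools to [0, 1].

    Higher-better: x / max (the max raw maps to 1.0).  Lower-better:
    1 - x / max (a raw 0 maps to 1.0, the max raw to 0.0).  When all raws
    are zero the scores are all 1.0 (lower-better) or 0.0 (higher-better),
    with a logged notice.
    """
    x = np.asarray(raw, dtype=float)
    if direction not in (HIGHER_BETTER, LOWER_BETTER):
        raise ValueError(f"direction must be {HIGHER_BETTER!r} or {LOWER_BETTER!r}")
    m = x.max(initial=0.0)
    if m == 0.0:
        logger.info("all raw values are 0; scores degenerate for this metric")
        fill = 1.0 if direction == LOWER_BETTER else 0.0
        return np.full(x.shape, fill)
    scaled = x / m
    return 1.0 - scaled if direction == LOWER_BETTER else scaled


def am_score(scores: pd.DataFrame) -> pd.Series:
    """Aggregated metric score per tool: the exact column sum of unrounded
    normalized scores (rounding happens only at presentation)."""
    return scores.sum(axis=0)


def round_half_up(value: float, decimals: int) -> float:
    """Presentation rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricTable:
    """Raw values and normalized scores per (metric, tool), plus AM row.

    ``raw`` and ``scores`` are DataFrames indexed by metric name with one
    column per tool; ``directions`` flags each metric higher-/lower-better.
    """

    raw: pd.DataFrame
    directions: Dict[str, str]
    scores: pd.DataFrame = None
    am: pd.Series = None

    def __post_init__(self):
        unknown = set(self.raw.index) - set(self.directions)
        if unknown:
            raise ValueError(f"no direction flag for metrics {sorted(unknown)}")
        scores = self.raw.copy().astype(float)
        for metric in self.raw.index:
            scores.loc[metric] = normalize_scores(
                self.raw.loc[metric].to_numpy(dtype=float), self.directions[metric]
            )
        self.scores = scores
        self.am = am_score(scores)

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Presentation layout: 'score (raw)' cells with the AM row last."""
        cells = {}
        for tool in self.raw.columns:
            col = [
                f"{round_half_up(self.scores.loc[m, tool], decimals):.{decimals}f}"
                f" ({self.raw.loc[m, tool]:g})"
                for m in self.raw.index
            ]
            col.append(f"{round_half_up(float(self.am[tool]), 2):.2f}")
            cells[tool] = col
        return pd.DataFrame(cells, index=list(self.raw.index) + ["AM score"])

    def to_tsv(self, path, decimals: int = 3) -> None:
        self.to_frame(decimals).to_csv(path, sep="\t", index_label="metric")


def build_metric_table(
    raw_values: Mapping[str, Mapping[str, float]],
    extra_directions: Optional[Mapping[str, str]] = None,
) -> MetricTable:
    """Assemble a MetricTable from {metric: {tool: raw}} nested mappings.

    Built-in metric names carry their standard direction; extra metric rows
    (e.g. externally computed assembly totals) need a flag in
    ``extra_directions``.
    """
    directions = dict(METRIC_DIRECTIONS)
    if extra_directions:
        directions.update(extra_directions)
    raw = pd.DataFrame(raw_values).T
    return MetricTable(raw=raw, directions=directions)
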