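"""Synthetic squiggle generator with ground-truth segment labels.

Each k-mer of a (random or supplied) sequence dwells in the pore for
1 + Geometric(a1) samples -- support starts at 2, matching the HMM topology
where a segment is one A step plus at least one E step, and giving mean
dwell 1 + 1/a1.  Samples are drawn from N(mu_k, noise_scale * sigma_k); at
noise_scale 0 the signal is each level mean repeated.  Because dwell
geometry and emissions share the inference model's own generative story,
simulator output supports parameter-recovery experiments directly.

The simulator reproduces dwell stochasticity and Gaussian level noise only;
real squiggles additionally show drift, low-pass filtering, adapter/poly-A
signal and modification effects, which are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InfeasibleReadError, InputError
from .hmm_core import Segment, Segmentation
from .pore_model import (
    ALPHABET,
    BasecalledRead,
    KmerModel,
    Orientation,
    SignalRead,
    sequence_to_kmers,
    write_signals_tsv,
)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    model: KmerModel
    a1: float = 0.1  # dwell geometry; mean dwell = 1 + 1/a1 samples
    noise_scale: float = 1.0  # multiplier on sigma_k
    n_reads: int = 10
    len_min: int = 20  # sequence lengths, nt
    len_max: int = 60
    seed: int = 0
    fixed_dwell: Optional[int] = None  # >= 2; overrides the geometric draw
    orientation: Orientation = Orientation.DNA_5TO3

    def __post_init__(self):
        if not (0.0 < self.a1 < 1.0):
            raise InputError(f"a1={self.a1} outside (0, 1)")
        if self.noise_scale < 0:
            raise InputError(f"noise_scale={self.noise_scale} < 0")
        if self.fixed_dwell is not None and self.fixed_dwell < 2:
            raise InputError(f"fixed_dwell={self.fixed_dwell} < 2")


def simulate_read(
    sequence: str,
    config: SimConfig,
    rng: np.random.Generator,
    read_id: str = "sim_read",
) -> Tuple[SignalRead, Segmentation]:
    """Generate one squiggle and its ground-truth segmentation.

    Dwell per k-mer is ``config.fixed_dwell`` or 1 + Geometric(a1) samples
    (support >= 2); truth segments use the same 0-based half-open signal
    intervals as the decoder.
    """
    model = config.model
    read = BasecalledRead(read_id=read_id, sequence=sequence)
    if len(read) < model.k:
        raise InfeasibleReadError(f"sequence length {len(read)} < k={model.k}")
    kmers = sequence_to_kmers(read, model, config.orientation)
    n = kmers.size
    if config.fixed_dwell is not None:
        dwells = np.full(n, config.fixed_dwell, dtype=np.int64)
    else:
        dwells = 1 + rng.geometric(config.a1, size=n)
    mu = model.means[kmers]
    sd = config.noise_scale * model.stdvs[kmers]
    samples = np.concatenate(
        [rng.normal(mu[j], sd[j], size=dwells[j]) if sd[j] > 0 else np.full(dwells[j], mu[j])
         for j in range(n)]
    )
    starts = np.concatenate(([0], np.cumsum(dwells)[:-1]))
    segments = tuple(
        Segment(
            kmer_index=j,
            kmer=model.kmers[kmers[j]],
            signal_start=int(starts[j]),
            signal_end=int(starts[j] + dwells[j]),
            mean_posterior=1.0,
            border_probability=1.0,
        )
        for j in range(n)
    )
    signal = SignalRead(read_id=read_id, samples=samples, normalized=True)
    truth = Segmentation(
        read_id=read_id,
        segments=segments,
        orientation=config.orientation,
        sequence_length=len(read),
    )
    return signal, truth


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def simulate_dataset(
    config: SimConfig,
    sequences: Optional[Sequence[str]] = None,
    out_prefix: Optional[str] = None,
) -> List[Tuple[SignalRead, BasecalledRead, Segmentation]]:
    """Generate ``n_reads`` cross-consistent (signal, read, truth) triples.

    With ``out_prefix`` set, also writes ``<P>.signal.tsv`` (portable signal
    table), ``<P>.fastq`` and ``<P>.truth.tsv``.  Fully reproducible under a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    triples = []
    for r in range(config.n_reads):
        if sequences is not None:
            seq = sequences[r % len(sequences)]
        else:
            length = int(rng.integers(config.len_min, config.len_max + 1))
            seq = random_sequence(length, rng)
        read_id = f"sim_{r:05d}"
        signal, truth = simulate_read(seq, config, rng, read_id=read_id)
        triples.append((signal, BasecalledRead(read_id=read_id, sequence=seq), truth))
    if out_prefix is not None:
        from .segmenter import write_segmentation

        write_signals_tsv((s for s, _, _ in triples), f"{out_prefix}.signal.tsv")
        with open(f"{out_prefix}.fastq", "w") as fh:
            for _, read, _ in triples:
                fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read)}\n")
        write_segmentation((t for _, _, t in triples), f"{out_prefix}.truth.tsv")
    return triples


def boundary_accuracy(
    truth: Segmentation,
    predicted: Segmentation,
    tolerances: Sequence[int] = (0, 1, 2, 5),
) -> Dict[int, float]:
    """Fraction of true internal borders matched by a predicted border
    within +/- d samples, for each tolerance d."""
    t = np.asarray(truth.boundaries)
    p = np.asarray(predicted.boundaries)
    out: Dict[int, float] = {}
    for d in tolerances:
        if t.size == 0:
            out[d] = 1.0
        elif p.size == 0:
            out[d] = 0.0
        else:
            dist = np.min(np.abs(t[:, None] - p[None, :]), axis=1)
            out[d] = float(np.mean(dist <= d))
    return out


def dataset_boundary_accuracy(
    pairs: Iterable[Tuple[Segmentation, Segmentation]],
    tolerances: Sequence[int] = (0, 1, 2, 5),
) -> Dict[int, float]:
    """Pooled boundary accuracy over (truth, predicted) pairs."""
    hits = {d: 0 for d in tolerances}
    total = 0
    for truth, predicted in pairs:
        t = np.asarray(truth.boundaries)
        p = np.asarray(predicted.boundaries)
        total += t.size
        for d in tolerances:
            if t.size and p.size:
                dist = np.min(np.abs(t[:, None] - p[None, :]), axis=1)
                hits[d] += int(np.sum(dist <= d))
    if total == 0:
        return {d: 1.0 for d in tolerances}
    return {d: hits[d] / total for d in tolerances}
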