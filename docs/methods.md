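# Methods

## The alignment model

A read's raw signal `T = (t_0 … t_{𝒯−1})` is aligned to the k-mer series of
its basecalled sequence `N` (n = 𝒩 − k + 1 k-mers in signal time order; for
direct RNA, which is sequenced 3′→5′, the sequence is reversed before
windowing — the orientation is an explicit flag, never autodetected). The
HMM has two states per lattice cell `(j, i)`:

* `A[j, i] = E[j−1, i−1] · a1 · φ(t_i; μ_{k_j}, σ_{k_j})` — open segment j
  at signal index i (entered diagonally, only from the previous k-mer's E);
* `E[j, i] = (A[j, i−1] · e1 + E[j, i−1] · e2) · φ(t_i; …)` — extend
  segment j by one sample (entered horizontally).

The origin is `A[0, 0]` with the emission of `t_0` and no transition factor;
the terminal forward score `Z` is read at `E[n−1, 𝒯−1]`. The backward pass
mirrors this with `β_E[n−1, 𝒯−1] = 1` and reproduces `Z` at the origin
(`Z*`); implementation bugs surface as `|log Z − log Z*| > 1e−6`, which is
raised as an error rather than tolerated. Posteriors are
`P[j, i] = α[j, i] β[j, i] / Z` per state.

Useful identities that the tests exploit: every legal path visits A exactly
once per k-mer and E exactly `𝒯 − n` times, so the transition budget
(`n−1` uses of a1, `n` of e1, `𝒯−2n` of e2) is identical for all paths of
one instance; path probabilities differ only through emissions. A read is
feasible only when `𝒯 ≥ 2n`; infeasible reads are reported with a reason
code, never dropped, because segmenting *everything* (and letting the user
filter on confidence) is the design goal.

### Assumptions

Emissions are independent Gaussians given the occupying k-mer, with
parameters from a pore-model table; dwell times are geometric (memoryless
motor-protein stepping); signal drift, low-pass filtering and modified
bases are not modeled. Dwells and levels are assumed stationary along the
read.

## Decoding

The reported segmentation maximizes the **sum of log-posteriors** along a
legal path ("posterior-Viterbi"), not the raw path likelihood; the two
objectives genuinely differ on ambiguous signals, and the posterior
objective is the one consistent with reporting per-cell confidence. Ties
prefer extending the current segment over opening a new one, which makes the
decode deterministic and favors longer segments. Each segment reports its
mean posterior occupancy; its `border_prob` is the column sum of A-state
posteriors at its start index, i.e. the probability that *some* segment
opens exactly there. (That column sum is also the quantity whose total over
all columns equals n.)

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `a1` | 0.1 | probability | mean dwell `1 + 1/a1` = 11 samples ≈ samples-per-base at nanopore translocation speeds (≈400 b/s at 4–5 kHz DNA, ≈130 b/s RNA) |
| `e1` | 1 (not trained) | probability | A has a single outgoing edge |
| band width | 100 | k-mer positions | generous slack around the diagonal; `full` disables banding |
| normalization | median/MAD | — | robust shift/scale into model space; raw MAD, no 1.4826 consistency factor, applied identically in normalization and metrics |
| `σ_min` | 0.01 | model units | EM floor preventing degenerate emissions |
| border window | 6 | samples | matches the smallest segment emitted by common basecaller move tables |
| homogeneity gate | 10 / inner 80 % | samples | segments ≥ 10 samples; `⌈0.1·len⌉` trimmed per end to exclude transition samples |

Median/MAD normalization maps `z = (x − median)/MAD` affinely into model
space using the model's global level mean and spread, so the output median
equals the global mean exactly. Which normalization a production basecaller
pipeline applies upstream is chemistry-dependent; `none` passes model-space
signals through untouched (the simulator emits model-space signals
directly).

## Banding

The band is a fixed rectangular diagonal: for signal index i, k-mer indices
within `round(i·(n−1)/(𝒯−1)) ± w` (half-even rounding), clamped so the
origin and terminal cells are always admissible. Cells outside the band are
`−∞`; widening the band can only add path mass, so `log Z` is monotone in w
and the full band is bit-identical to unbanded computation (both properties
are tested). In this implementation the matrices are stored dense and the
band only restricts which cells are computed — the savings are in work and
in path-space restriction, not in memory; an adaptive or compressed band is
a possible future optimization.

## Training

Baum–Welch with the standard expectations for this topology:
`a1 ← E[a1 uses]/E[E occupancy]`, `e2 = 1 − a1`, and per-k-mer
posterior-weighted mean/standard deviation (floored at `σ_min`) for the
emissions. K-mers with zero posterior occupancy keep their prior parameters.
Because the transition budget is path-independent (above), the a1 update is
driven by read lengths rather than by posterior detail, and converges in one
step; emission updates iterate. Convergence is declared when the total
`log Z` improves by less than `tol` (default 1e−3); the trajectory is
monotone non-decreasing up to 1e−6 numerical slack, the usual EM guarantee.

## Simulator

The generator draws, per k-mer, a dwell of `1 + Geometric(a1)` samples
(support starts at 2, mean `1 + 1/a1`, exactly the dwell law implied by the
A/E topology) and emits `Normal(μ_k, noise·σ_k)` samples. A `fixed_dwell`
mode replaces the geometric draw for fully deterministic instances. Sharing
the generative story with the inference model is deliberate: it makes
parameter-recovery experiments well-posed. It also bounds what passing
tests demonstrate — real squiggles additionally contain drift, filtering,
adapter/poly-A stretches, modification shifts and basecalling errors, none
of which the simulator produces, so recovery results here are statements
about the algorithm, not about accuracy on real flow-cell data.

Toy pore models used in tests (`toy_model(k)`) assign evenly spaced level
means (default gap 3 model units at σ = 1) so every k-mer is perfectly
identifiable; they are synthetic by construction, unlike real pore models
whose context levels overlap heavily.

## Metrics and scoring

Border deltas compare the median (or raw MAD) of the 6 samples on each side
of every internal border; borders without a full window on either side are
skipped, not padded (padding would fabricate signal). Homogeneity is the
standard deviation of the inner 80 % of segments spanning ≥ 10 samples.
Per-tool summaries are the median over all collected values. Read
statistics count segmented and truncated reads (strict truncation: any
uncovered basecalled nucleotide counts; the threshold is configurable in
the sense that callers can precompute lengths differently) and the
min/N50/max of segmented lengths. Scores normalize raw values across tools
per metric: `x/max` for higher-better, `1 − x/max` for lower-better; the
AM score is the exact column sum of unrounded scores. Rounding happens only
at presentation, half-up (so a column summing to 9.625 prints as 9.63).
Extra externally computed metric rows (e.g. assembly totals) are accepted
with a direction flag and scored the same way.

## Numerical choices

All DP in natural-log space with `logaddexp`; 𝒯 can reach 10⁵, where linear
space underflows. Posterior cells may exceed 1 by tiny round-off; excursions
≤ 1e−6 are clipped, larger ones raise a consistency error. Degenerate
inputs are errors with named causes: constant signal (MAD 0), non-finite
samples, bands excluding the origin/terminal cell, signals shorter than
`2n`.

## Problem sizes

The test suite and acceptance script run at desk scale by design: exhaustive
path enumeration up to 𝒯 = 6–8 and ≤ 3 k-mers (hundreds of paths), 200-read
randomized consistency sweeps, 50-read zero-noise recovery on a k = 5 toy
model, and 200 reads × 40 nt for Baum–Welch recovery on a k = 2 toy model.
These sizes make every check a few seconds to a few minutes on one CPU while
still exercising the full code paths; the algorithms themselves have no
size-specific shortcuts.

## Known limitations

* Dense matrix storage; memory is O(n·𝒯) even with a band.
* No adapter/poly-A trimming, read splitting, or reference mapping.
* The posterior-Viterbi path is not guaranteed to be the maximum-likelihood
  path (deliberately); downstream consumers wanting the likelihood argmax
  should decode from raw forward scores instead.
* pod5 input requires the optional `pod5` package; the portable path is the
  plain signal TSV.
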