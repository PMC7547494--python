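# Methods

## Quantification model

Each site–condition cell of a MeRIP-Seq experiment carries two non-negative
abundances: IP (`t`) and input (`h`).  The methylation level is the
pseudocount-stabilised IP fraction `p = (t + α)/(t + h + 2α)` with
`α = 1e-6` by default; any positive `α` keeps `p` strictly inside (0, 1) and
sends double-zero cells to exactly 0.5 (maximal uncertainty, which is the
honest value there).  The expression weight is `w = log(t + h + 1)` — the
natural logarithm by default.  The log base only rescales W globally, and
because the threshold tuner re-optimises (T_R, T_C) on whatever scale W has,
the choice is internally consistent; it is still exposed (`log_base`).

Biological replicates are merged by per-cell arithmetic averaging of both
levels and weights.  Weights could alternatively be recomputed from summed
counts; averaging was chosen because merging operates on already-quantified
profiles and keeps the merge a pure profile-level operation.

## Normalisation

The weighted search uses per-row and per-column min–max rescaling onto
[0, 1] (P^R, P^C) rather than z-scores: the weights are meant to carry the
confidence information, and min–max preserves the levels' bounded scale
instead of re-inflating low-variance (often low-coverage) slices.  Constant
rows/columns map to all-zeros, which makes them inert in the signature
scores.  The unweighted baseline mode standardises instead (z-scores,
population sd, zero-variance slices to zero), the conventional-ISA
preprocessing.

## Signature iteration and the selection rule

Condition scores are weighted means of P^R over the current site set;
site scores are weighted means of P^C over the current condition set; each
is thresholded at `T/√(set size)` on its deviation from the score mean.
Iteration stops when the site set's Jaccard distance to the previous
iterate is ≤ ε (default 0.01; ε = 0 demands exact fixed points).  A
convergence rule based on *low* overlap instead of low change is
self-defeating (it fires while the set is still churning), so the
small-change reading is used.

**One-sided vs two-sided selection.**  The selection rule admits two
readings: threshold the signed deviation (keep only above-mean scores) or
the absolute deviation (keep both tails).  The two-sided rule is the
conventional ISA convention — it captures up- and down-signatures on
centred, standardised data.  On weighted min–max data it fails
structurally: when the current site set contains a strong hyper-methylated
block, the scores of the non-block conditions sit far *below* the score
mean (the mean is dragged up by the block), so the low tail re-enters the
block at any threshold in the practical range and the iteration cycles
without converging.  The weighted mode therefore uses one-sided upward
selection by default — an LFB is a block of hyper-methylated sites and
conditions — while the unweighted baseline keeps the conventional
two-sided rule.  Both are overridable via `selection=`.  A measured
consequence on the default simulation: the weighted one-sided search
attains a maximum grid SoBC of ≈ 0.95, while the two-sided z-score
baseline stays near 0.1 — the weighted variant's advantage is inseparable
from its one-sided rule.

The printed condition-score formula uses row-normalised levels and the
site-score formula column-normalised levels; a `swap_normalization` switch
provides the transposed reading.

## Seeding, deduplication and the basin filter

Each search draws `n_seeds = 100` random initial site sets of
`seed_fraction = 0.02` of all sites (20 of 1000), without replacement.
Sparse seeds matter: seeds large enough to represent every planted block
evenly converge to "union" fixed points spanning several blocks, because no
block wins the early symmetry-breaking.  With sparse seeds the dynamics tip
into single-block attractors almost always.

Converged fixed points are consolidated in three steps: exact duplicates
are pooled (their seed counts add); near-duplicates (cell-set Jaccard
≥ 0.9) are merged into the larger block; and blocks reached from fewer
than `min_basin = 5 %` of the converged seeds are dropped.  The basin
filter is the load-bearing step: without it, every chance attractor found
by a single lucky seed is counted, and the reported block count grows with
`n_seeds` rather than measuring the data.  Requiring a minimum basin of
attraction is the standard robustness criterion in the ISA family.

## Threshold auto-tuning

The tuner runs the search over a (T_R, T_C) lattice (defaults: T_R 0.1–5
step 0.1, T_C 0.05–3 step 0.05), `repeats` times per pair with seeds
derived deterministically from the master seed and the (pair, repeat)
index.  The per-pair count is the mode over repeats; all mode-like
tie-breaks (repeats, window, frequency vote) resolve to the smaller value,
consistent with preferring smaller thresholds and hence larger, more
informative blocks.  The range then shrinks twice: the upper bounds come
from the componentwise maxima of the argmax-count pairs (the same count is
reachable with smaller thresholds); the lower bounds rise past the leading
rows/columns whose variance in the globally min–max-normalised count
matrix falls below the mean variance (the near-origin plateau carries no
selection signal).  A sliding window of odd size `2·ceil(0.1/step) + 1`
per axis (clipped at the borders) marks cells whose windowed modal count
equals their own; the relative frequency of each nonzero stable count is
tabulated and the modal count wins.  Among stable pairs with the winning
count, pairs with below-mean ASwC survive (undefined ASwC excludes a
pair), and the surviving pair with maximal SDwC is selected, ties to the
lexicographically smallest (T_R, T_C).

Per-pair ASwC/SDwC are computed from the blocks of the first repeat that
achieved the modal count at that pair; the bookkeeping of which repeat
feeds the metrics is a free choice and this one is deterministic.

## Evaluation metrics

IoU is cell-set intersection-over-union of two rectangular blocks.  SoBC
matches each obtained block greedily to its best-IoU truth block (ties to
the lower truth index, re-matches don't double-count) and equals
`(r / max(s, n)) · mean(best IoU)`.  SDwC is the square root of the summed
per-block mean squared deviation of `w·p`, divided by the block count;
ASwC is the square root of the summed per-block average pairwise Pearson
correlation of weighted condition profiles (ordered pairs, factor
`2/(n_k(n_k−1))`), divided by the block count.  As printed, ASwC can
exceed 1 (a single perfectly correlated block gives √2) and is undefined
when the correlation sum is negative or a weighted column is constant; the
implementation returns NaN rather than clamping, and the tuner excludes
such pairs.  WE_score weights each enriched term's −log10 p by its
in-block gene fraction and discounts genes enriched in no term.  Fisher's
exact test (two-sided, scipy) with the sample odds ratio (0.5 continuity
correction only when a zero in the off-diagonal would make it undefined)
and Benjamini–Hochberg adjustment (statsmodels) across a supplied batch
cover the enrichment tables.

## Synthetic data

The simulator emulates the MeRIP-Seq sampling process as a mixture of four
beta-binomials on a 1000 × 15 matrix: per cell, a total coverage
`n ~ NegBin(mean 50, dispersion 5)`, a methylation proportion `θ ~ Beta`
from the covering component — three disjoint planted blocks of
150 sites × 5 conditions with Beta(9, 1) (mean 0.9) over a Beta(2, 2)
background (mean 0.5) — then `t ~ Binomial(n, θ)`, `h = n − t`.  Weights
are *not* simulated separately; they derive from the simulated counts
through the standard quantification, as for real data.

What this emulates: hyper-methylated co-methylation blocks over a
symmetric background at realistic MeRIP coverage, with moderate per-cell
coverage variation.  What it does not: site-level expression heterogeneity
spanning orders of magnitude (each site shares one coverage law), shared
per-site random effects (within-block condition profiles are conditionally
independent, so within-block correlations — and hence ASwC — hover near
the undefined boundary), overlapping blocks (possible via
`allow_overlap=True` but off by default), hypo-methylated blocks, and any
genomic structure (coordinates are never used by the algorithm).  Passing
recovery tests on this design therefore demonstrates the search and tuning
machinery, not robustness to wildly varying expression.

## Problem sizes and numerical choices

The recovery experiments use the default 1000 × 15 design with a coarsened
tuning grid (T_R step 0.25, T_C step 0.15) and 10 repeats per pair, and a
single search per pair on the shrunken SoBC window (T_R 0.3–2.5 step 0.1,
T_C 0.1–1.15 step 0.05) — sizes chosen so a full run completes in about a
minute while the count surface keeps the structure of the full-resolution
scan.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawn keys, so grid scans are reproducible and
shardable.  Grid values are generated by rounding `lo + k·step` to 10
decimals to avoid float drift; the window-size ceiling subtracts 1e-9
before rounding up so that exact multiples (0.1/0.1) do not spill into the
next window size.  `max_iter = 100` update cycles per seed; non-converged
seeds are dropped silently.

## Known limitations

The search reports hard site/condition sets only (no membership scores).
The block count is sensitive to the consolidation parameters
(`dedup_jaccard`, `min_basin`), which is why the tuner votes over a
stability-filtered grid rather than trusting any single run.  ASwC as
printed is frequently undefined on data without shared site effects, in
which case the tuner's similarity filter degrades to a no-op with a
warning.  The two-sided selection variant cannot isolate strong blocks on
weighted min–max data (see above) and exists for baseline comparison, not
production use.
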