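# Methods

## The stoichiometry barcode

The core statistic is compositional: for sample *s*, each detected
ribosomal protein's ratio is its intensity divided by the summed intensity
of all RPs detected *in that sample*. iBAQ-type intensities are
proportional to molar amounts, so the ratios are molar proportions of the
ribosome pool. Three consequences follow directly from the definition and
are enforced as invariants:

- non-missing ratios of a sample sum to 1 (simplex);
- the barcode is invariant to any positive per-sample scale factor
  (loading, cell count, instrument response);
- the composition is *sub*-compositional: removing an RP from the panel
  rescales the remaining ratios of that sample by a common factor, and
  samples with different detected sets have slightly different
  denominators. We deliberately use the per-sample detected set (not a
  fixed panel intersection) as the denominator; the QC report
  (`detected_rp_counts`) exists so users can see when detection depth
  differs enough to matter.

No pseudocounts and no imputation are applied at the ratio stage. Zeros in
the input are treated as "not detected" (missing) by default, because a
measured molar amount of exactly zero is indistinguishable from a
detection failure in these data; `zeros_as_missing=False` disables this.
Duplicate gene symbols are an error by default (no silent aggregation);
an explicit `sum_duplicates=True` aggregates and logs.

## PCA with SVD imputation

Rows (RPs) are centered and scaled to unit variance (sd with n−1) using
each row's non-missing values; rows with fewer than two observations or
zero variance are dropped and recorded. Missing entries are then filled by
iterative SVD imputation: initialize with row means (zero after
centering), and repeat {rank-*k* SVD of the completed matrix; replace only
the missing entries with the reconstruction} until the relative change of
the imputed values drops below `tol` (default 1e-9) or `max_iter` (500) is
reached; non-convergence returns a flagged result with a warning rather
than failing. Sample scores are the right singular vectors scaled by the
singular values; explained variance per component is s²ᵢ/Σs². Component
signs are fixed by making the largest-magnitude loading positive, so
results are reproducible across LAPACK backends. On complete matrices the
loop is a no-op and the result equals direct SVD PCA; on exact low-rank
matrices the masked entries are recovered to numerical precision (both are
tested).

## Prediction ellipses

Per group, the ellipse is derived from the sample mean and covariance of
the first two scores. The default radius uses the small-sample prediction
quantile for one future observation,

    r² = 2 (n−1)(n+1) / (n (n−2)) · F₀.₉₅(2, n−2),

which is what makes 95% coverage hold at the n = 3 group sizes common in
these designs; `method="chi2"` gives the large-n limit χ²₂(0.95). Groups
need n ≥ 3 and a non-singular covariance (collinear points raise an
error). Coverage is verified by Monte Carlo in two regimes: refit-per-
replicate at n = 10 (true prediction coverage) and large-n fresh draws.

## Correlation and clustering

Sample–sample Pearson correlation uses pairwise-complete observations with
the shared-RP count recorded; pairs sharing fewer than 3 RPs get a missing
coefficient and a warning. Clustering uses correlation distance d = 1 − r
on the scaled matrix (rows scaled first, then distances — on both rows and
columns) and unweighted average linkage (UPGMA), implemented with the
Lance–Williams update and a deterministic lexicographic tie-break on
original node indices so dendrograms are bit-reproducible. Heights are
monotone, so cutting to k clusters undoes the last k−1 merges. The
implementation is checked against a naive O(n³) recompute-from-scratch
oracle and against scipy's average linkage on tie-free instances.

## Differential testing

Per RP with ≥ 2 non-missing values in each group: a two-tailed two-sample
t-test, Student's pooled-variance by default (the common default of
standard stats/plotting packages; Welch by flag, recorded in the output
metadata). Degenerate inputs are explicit: equal constant groups give
t = 0, p = 1; zero variance with unequal means is flagged untestable — no
p-value is fabricated. BH adjustment runs over all RPs tested within the
one comparison (that is the family), missing entries excluded from m.
Significance is p_adj strictly below alpha (0.05 default); direction
requires a nonzero log2 fold change, computed as log2 of the ratio of
group arithmetic means of the linear-space ratios (the alternative — mean
of per-sample log ratios — is deliberately not the default, since the
plotted quantity is the expression ratio itself).

## Synthetic data generator

Each dataset is built as composition × scale: a group target simplex
(baseline barcode × planted fold effects, renormalized), optional
per-sample Dirichlet draw around the target (precision =
`bio_concentration`), a lognormal per-sample total-abundance factor, and
multiplicative lognormal measurement noise of coefficient of variation
`noise_cv`. Dropout is a logistic in log10 intensity (probability of
detection rising with abundance) plus an optional small
missing-at-random rate for bulk designs; intensities are never negative
and every sample keeps at least its most intense RP. All randomness flows
from the single spec seed; identical spec + seed is bit-identical.

The baseline barcode is drawn as normalized lognormal(0, σ = 1.2)
variates, giving the 2–3 orders of magnitude spread seen in real iBAQ RP
tables. Presets freeze their baseline with a per-preset constant seed so
the identity of the planted RPs does not depend on the user's seed.

Preset structure (group sizes, panel sizes, single-cell detection depth)
is a fixed study condition; effect sizes are didactic defaults (2-fold in
the single-cell and two-group designs), not estimates from real data:

- `tissues6` — 6 tissues × 3 samples, 82 RPs; each tissue up-shifts its
  own block of 8 RPs (2.2-fold); fat and spleen suppress each other's
  blocks, making them the most divergent pair.
- `testis4` — 4 ages × 3, 81 RPs including RPL10L/RPL39L with stagewise
  increases (RPL39L up from day 14; RPL10L up at day 14 and again at
  day 28) plus per-stage blocks.
- `neuron2` — 3 vs 3, 81 RPs, four up / three down.
- `gastric_cohort` — 82 vs 58, 86 RPs, 34 up (1.35×) / 23 down (0.75×).
- `macrophage_sc` — 10 vs 38 cells, 71 RPs, 9 up / 9 down at 2-fold,
  noise CV 20%, dropout midpoint 5.0 (log10) with slope 2 per decade and
  total-abundance σ = 0.3, calibrated by simulation so the median
  detected-RP count per cell sits near 55 of 71 (the realistic "more than
  50 RPs per cell" single-cell depth).

Planted up/down blocks are mass-balanced: the up block is chosen so its
planted intensity gain cancels the down block's loss. Without this,
renormalization drags every unplanted ratio by the factor 1/Σ(baseline ×
fold) — a real compositional effect that would turn "null" RPs into true
(if tiny) changes. The truth table's planted directions refer to the fold
map; residual renormalization shifts on unplanted RPs are treated as null,
so recovery metrics count calls on them as false positives. This is the
honest convention for a compositional readout and is documented rather
than hidden.

What the generator does *not* emulate: peptide-level identification,
batch/instrument effects, correlated noise between RPs beyond the
compositional constraint, and real effect-size distributions. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its stated noise model, not that real datasets have this
signal-to-noise.

## Problem sizes and numerical choices

The validation harness uses: 1,000 random tables for the simplex/scale
checks; 1,000 random p-vectors (BH), 300 random samples (t), 150 random
n ≤ 6 instances (UPGMA) for oracle agreement; 20 replicates each for the
PCA contracts; 10,000 Monte-Carlo points/replicates for ellipse coverage;
and 200 null simulations at the single-cell design scale for the
false-discovery control check, judged against the exact binomial 99.9%
band around the nominal 5% any-discovery rate. Tolerances: simplex 1e-12,
oracle equality 1e-10, rank-1 imputation 1e-6, coverage ±0.01.

## Known limitations

- Ratios are compositional; users comparing datasets with very different
  detected panels should inspect `n_shared` and the QC report before
  trusting cross-dataset correlations.
- The correlation-distance clustering requires complete profiles after
  scaling; sparse single-cell matrices rely on upstream detection, not
  imputation (only PCA imputes).
- Group-aware stages need ≥ 2 (tests) or ≥ 3 (ellipses) samples per
  group; the pipeline skips ellipses, with a logged note, when a design
  cannot support them.
- `level` mode compares raw intensities and is sensitive to loading
  differences by construction; it exists to expose exactly the abundance
  shifts that ratio mode removes.
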