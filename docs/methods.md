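# Methods

## Study design being modelled

Five pooled plasma samples (healthy controls and disease stages I–IV, each a
pool of many patients) are quantified by SWATH-MS in technical triplicate,
under four sample-preparation branches ("depletion arms"): non-depleted,
MARS-14, MARS-14→API and API→MARS-14. Each arm yields its own protein × run
peak-area matrix; depleted arms see partially different protein subsets. All
statistics operate on these matrices; nothing upstream of protein-level
quantitation (spectra, peptides, library search) is modelled.

## Normalization

Each arm is normalized independently by total area: run *r* is scaled by
(mean of run totals)/(total of run *r*), computed over observed values.
The target is the mean run total rather than 1.0 so values stay on a
peak-area-like scale for the replicate-SD computations downstream; any
common target is equivalent up to a global factor. Normalization is
idempotent, preserves within-run ratios, and preserves the missing mask.
Log transform defaults to base 2 (the proteomics convention; the base is
recorded on the matrix and configurable). Zeros are masked as missing at
the log step rather than pseudo-counted — a pseudo-count offset is
available but off by default, since any offset is an invention. A protein
is analyzed only in runs where observed; a protein missing a whole
condition group (fewer than two observed replicates) is excluded from the
tests for that arm.

## Differential expression

Per protein and arm, on log₂ values: one-way fixed-effects ANOVA across the
five condition groups, and two-sided unpaired t-tests for each
stage-vs-healthy contrast (Welch by default; Student available for
textbook-exact pooled-variance behaviour). Degenerate inputs have explicit
policies: identical group means → F = 0, p = 1; zero within-group variance
with distinct means → p reported as 0; both t-test groups constant → p = 1
if means are equal, else 0.

Fold changes are computed on the linear normalized scale,
FC_s = mean(stage s)/mean(healthy); tests run on the log scale. A candidate
passes when

* ANOVA p < α (default 0.05, raw — the study protocol used unadjusted
  p-values; Benjamini–Hochberg adjustment can be switched on, in which case
  it gates the pass flag and is reported alongside),
* max over stages of the symmetric fold change max(FC_s, 1/FC_s) is
  **strictly** greater than the cutoff (default 1.5) — "maximum fold
  change" is read as the maximum over the four stage-vs-healthy contrasts,
  with the symmetric form matching a ±1.5 cutoff, and
* (default) the trend sign of FC_s is identical and nonzero in all four
  stages.

Per-arm selections are consolidated by union; a protein selected with
opposite directions in different arms is conflict-flagged and excluded from
the default candidate list. Output ordering is ascending ANOVA p then
accession, so results are reproducible.

## Unsupervised structure

Replicate-run dissimilarities default to Euclidean distance on log₂
normalized profiles (the metric is configurable; correlation distance
1 − r is provided). Classical (Torgerson) MDS: square the dissimilarities,
double-center (B = −½ J D² J), eigendecompose, scale the leading
eigenvectors by √λ. Negative eigenvalues (non-Euclidean inputs) are
truncated and their relative mass reported; an input with no positive
eigenvalue is an error. Axis signs are fixed deterministically (largest
|coordinate| positive). On Euclidean-realizable inputs the embedding is an
isometry and coincides with PCA of the underlying configuration up to an
orthogonal transform — the PCA cross-check asserts Procrustes agreement.

Protein-profile dissimilarities are computed over the five condition means
with per-protein z-scoring first (otherwise absolute abundance, spanning
ten decades, would dominate the distances rather than the stage response);
correlation distance is the default there. A profile with zero variance is
assigned distance 1 to everything under the correlation metric.

## Cohort augmentation

From class centroids (replicate means) and technical-replicate SDs, each
synthetic patient value is drawn independently per protein from
Normal(centroid, k·SD) with k = 10 and 1000 patients per class — a
deliberately conservative variance inflation intended to overcover the
biological spread of a real population. Draws come from one seeded
generator in fixed (class, patient, protein) order as
centroid + k·SD·z, which makes cohorts bit-reproducible across machines
and exactly equivariant under rescaling of (centroids, SDs). Negative
draws are truncated to zero by default (concentrations are non-negative);
`resample` and `allow` policies exist, and the distribution-moment tests
use `allow` because truncation deliberately distorts the moments.
Correlated multivariate noise is out of scope: the augmentation is
per-protein independent by design.

## Classification

Stratified 70/15/15 train/validation/test split (per-class sizes within one
of the exact fractions; seeded shuffle). The network is a single hidden
layer of 10 tanh units with softmax output and cross-entropy loss — the
classic pattern-recognition default — trained with Adam
(learning rate 0.01) and early stopping on held-out validation performance
(patience 30 epochs, max 400). Because the underlying sklearn optimizer
holds out its own stratified validation subset, `train_nn(train, val, ...)`
pools the two sets and sizes the internal validation fraction to match
|val|. Inputs are z-scored by training-set statistics (peak areas span
orders of magnitude). Prediction is a pure function of the stored scaler
statistics and weights — the forward pass is computed from the serialized
arrays, so the JSON round trip is exact — and argmax ties break toward the
lowest class index in (healthy, I, II, III, IV) order.

Real-data deployment classifies each technical replicate independently
(15 items for a triplicate design); a pooled-mean mode (5 items) is
provided since the study's wording admits both readings. kNN (k over
{1,3,5,7,9}) and decision-tree (depth over {2,3,5,8,∞}) baselines pick
their hyperparameter on the validation set.

### Determinism contract

All randomness flows from explicit integer seeds. Network training wraps
BLAS in a single-threaded context so the result does not depend on host
core count; the frozen-seed regression values in the test suite
(synthetic-test and real-deployment accuracies of the seed-17 end-to-end
run) are reproduced bit-for-bit under that contract on the same CPU
architecture and library versions. Seed-dependent quantities are otherwise
always reported as medians (with IQR) over an explicit seed set.

## Panel minimization

Candidate proteins are grouped by average-linkage hierarchical clustering
of their profile dissimilarities (tree cut at the largest merge-height gap
unless a group count is given); within a group, proteins are ranked by mean
distance to the rest of the group (most representative first, ties broken
lexicographically). The greedy forward search starts from an empty panel
with the candidate pool ordered representatives-first, evaluates every
remaining candidate as an addition (median test accuracy over the seed
set), adds the best, and stops at the target accuracy; the full search log
(every evaluated subset with its accuracies) is returned, and an exhaustive
mode covers ≤ 12 candidates. The one-sentence published description of
panel narrowing does not fix a procedure; this grouping + retrain-evaluate
search is an explicit interpretation. Greedy accuracy is not mathematically
guaranteed to be non-decreasing in panel size for a neural network (an
added feature can hurt a small model); on informative fixtures it is, and
the regression test checks it there. If the target is unreachable the best
panel found is returned flagged `not_met`.

## Synthetic study fixtures

The generator emulates the study inputs:

* healthy centroids log-uniform over 10 decades (the plasma dynamic range);
* 37 planted differentially expressed proteins with stage-consistent
  directions and per-stage symmetric fold changes log-uniform in [1.5, 8]
  (optionally non-decreasing with stage); the 5 largest-magnitude planted
  proteins form a recoverable "driver" panel;
* technical triplicates with multiplicative noise
  value = centroid·(1 + N(0, σ_s)) truncated at 0, per-stage CVs
  33/36/42/45/31 % (healthy, I–IV);
* four depletion arms drawing per-arm protein subsets (non-depleted arm
  retains everything, depleted arms retain 85 %), each arm an independent
  acquisition sharing the same centroids.

**CV calibration.** The configured per-stage CVs are treated as expected
*triplicate sample* CVs (SD/mean with n = 3), because that is the statistic
the study reports. The sample SD of a normal underestimates σ by the
c₄(3) ≈ 0.886 factor, and 1/mean adds a further small-sample bias, so the
generator solves numerically for the underlying σ_s whose expected
triplicate sample CV (truncation included) equals the configured value,
using bisection against a fixed 200 000-triplet z-sample (deterministic, no
user-seed dependence). Naively planting σ = CV would under-recover by ≈ 11 %.
The optional heteroscedastic mode draws a per-protein CV from the reported
per-stage mean ± SD (e.g. 33 ± 28 %) with an analytic small-n debias
instead of the exact solve; the fixed-CV default keeps oracle tests clean.
A lognormal noise mode (exact mean-one multiplicative noise, Gaussian on
the log scale) exists for null-calibration studies of the log-scale tests.

CV-recovery checks run on the fixture matrices as emitted: the fixture
plants no run-level scale factors, so its raw values are already on a
common per-run scale, and total-area renormalization would only re-inject
the dominant protein's noise into every other protein (with a 10-decade
dynamic range the run total is dominated by the top protein). Real MS data
does need the normalization; this is a property of the simulation, not of
the pipeline.

**What the fixtures do not model:** peptide-level structure, correlated
noise between proteins (mirroring the augmentation's independence
assumption — a known simplification), batch/run-order drift, and
non-normal heavy-tailed technical error. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not performance on reprocessed study data; externally
supplied quantitation matrices enter through `read_quant_table` and flow
through the identical pipeline.

## Problem sizes used in the checks

The regression/acceptance suite runs the generator at the full study
geometry (300 proteins × 15 runs × 4 arms) and the augmentation at the full
5000-patient cohort for the frozen-seed end-to-end run; multi-seed
classifier properties (noise-sweep monotonicity, chance-level permuted
labels) use 80–200 patients per class so that ten-seed medians stay cheap,
and panel-search tests use small driver fixtures (40 proteins, 10 planted)
— sizes chosen as the smallest at which the checked properties are
statistically unambiguous.
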