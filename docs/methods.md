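# Methods

## Response model and likelihood

Abundance responses along pH are modeled with the five-shape HOF hierarchy.
pH is mapped affinely onto x ∈ [0, 1] over a fixed gradient range (default
3.63–8.75, the span of the survey the method is designed around); values
outside the range extend affinely, which matters only for prediction. With
the logistic kernel g(t) = 1/(1 + eᵗ):

- I: μ = M·g(a) — no trend;
- II: μ = M·g(a + bx) — monotone;
- III: μ = M·g(a + bx)·g(c) — monotone with a plateau below M;
- IV: μ = M·g(a + bx)·g(c − bx) — symmetric unimodal;
- V: μ = M·g(a + bx)·g(c + dx) — skewed unimodal.

M is not estimated: it is pinned to the OTU's maximum observed count, the
convention of the standard HOF software. Only a–d count as free parameters
(k = 1, 2, 3, 3, 4), keeping AIC comparable across types. Counts enter a
Poisson likelihood, NLL = Σ μᵢ − yᵢ ln μᵢ + ln yᵢ!, with μ floored at 1e-10
inside the log to survive fully saturated logistic terms.

Bounds are a, c ∈ [−50, 50] and b ∈ [0, 200]; the sign of the trend is
handled by fitting every model on both gradient orientations (x and 1 − x)
and keeping the better likelihood. The skew parameter d of model V is the
one deviation from an all-non-negative box: both logistic terms of V flip
together under gradient reversal, so with b, d ≥ 0 model V could never be
unimodal; d ∈ [−200, 200] with sign(d) ≠ sign(b) producing the skewed
shapes. Optimization is bounded L-BFGS-B with analytic gradients
(ftol 1e-10, gtol 1e-8, ≤ 500 iterations) from a deterministic multi-start
set: a logit-linear regression of smoothed proportions (y + 0.5)/(M + 1)
seeds (a, b); c and d start from small grids. Each fit also warm-starts from
the fitted parameters of the models it nests (II from I, III/IV from II, V
from III and IV), which makes the measured likelihoods respect the hierarchy
I ⊆ II ⊆ {III, IV} ⊆ V up to optimizer tolerance — a property the test
suite asserts at 1e-6.

## Model selection

The lowest-AIC type is chosen first (ties to fewer parameters). Robustness
is then tested on 100 bootstrap datasets — resamples of (pH, count) pairs
with replacement — refitting all five types per resample (warm-started from
the original fits) and recording the AIC-best type. If the modal bootstrap
choice differs from the initial choice, the mode is selected; tally ties go
to the fewer-parameter type. Final parameters are the original-data fit of
the final type. Resamples that degenerate (all-zero counts, optimizer
failure) are excluded from the tally and counted separately; whether the
original analysis excluded or retried such refits is not documented, and
exclusion is the simpler reproducible rule. Each bootstrap refit uses the
resample's own maximum count as M, i.e. it is a true refit of the resampled
dataset.

## Optima and response classes

Type I yields no optimum; type II the gradient endpoint with the higher
response; types IV and V the interior argmax, located on a grid of step
1e-3 in x and polished by bounded scalar minimization (the IV closed form
x* = (c − a)/(2b) is used as an independent oracle in tests, with grid
agreement required at |Δx| ≤ 2e-3). Type III reports two optima bounding
the plateau, defined as the region where the response is ≥ 0.95 of the
fitted maximum; the reference software's exact plateau-edge rule is not
published, so the 0.95 fraction is this package's documented substitute.

Classes use thresholds 5.2 and 7.0: acid (< 5.2), mid, neutral (> 7.0); a
two-optima fit straddling a threshold gets a range class (acid_to_mid,
mid_to_neutral, acid_to_neutral); flat fits are "no_preference". The source
rules are strict inequalities on both sides, leaving optima exactly at a
threshold formally unassigned; they are placed in the closed middle band.
Monotone fits whose optimum is a gradient endpoint are classified by the
same thresholds.

## Filtering, coverage, matching

Tables are filtered samples-first (depth ≥ 5,000 reads, recomputed from the
matrix, never trusted from metadata), then OTUs by prevalence (≥ 30 occupied
samples); both thresholds read "at least" literally, i.e. inclusive. The
composite is order-dependent because dropping OTUs changes depths; the
samples-then-OTUs order is the pipeline default and a test documents the
non-commutativity with a counterexample.

Accumulation curves are permutation-based (default 100 random sample
orders; the number used originally is unstated), reported as mean and
population SD of cumulative richness, per habitat class and pooled. The
analytic sample-based rarefaction mean E[S_k] = Σᵢ [1 − C(N − nᵢ, k)/C(N, k)]
is kept in the package as a cross-check oracle, and an exact enumeration
mode exists for tiny tables.

Match records use the 12-column tabular alignment format. A hit requires
identity ≥ 97% and e-value ≤ 0.001, both inclusive; per query the best hit
is kept by bitscore, ties broken by e-value then subject id, so the result
is independent of input order. The package deliberately consumes match
tables rather than embedding an aligner; any BLAST-compatible tool with
12-column tabular output produces them. Rank-bin coverage sorts queries by
decreasing total abundance (ties by id) into contiguous near-equal bins,
earlier bins absorbing the remainder.

## Indicator analysis

Samples are banded acid/mid/neutral by the same thresholds. The indicator
value is the group-equalized variant: specificity A is the group mean of
within-sample relative abundances, normalized across groups (so Σ_g A = 1);
fidelity B is presence/absence occupancy; IndVal = 100·A·B, reported for
the argmax group. Group-equalization matches the default of the standard
indicator-analysis software and is appropriate because pH bands have
unequal sizes; relative abundances make A robust to depth variation.
Significance is a label-permutation test on the per-OTU maximum IndVal with
the add-one estimator p = (1 + #{permuted ≥ observed})/(1 + n_perm),
default 999 permutations, indicator status at p ≤ 0.05 (the original
analysis states neither setting, so its indicator count is not expected to
be matched exactly). Null p-values are checked for uniformity in the test
suite (Kolmogorov–Smirnov at α = 0.01).

## Community prediction

The most abundant query OTUs with best hits (rank by total count, then
match — default top 100) inherit their matched reference fit. Predicted
abundance at a query sample is the fitted response at the sample's pH
divided by the reference study's median sample depth; since the matrix is
renormalized per sample before Bray–Curtis, this scale choice is immaterial
to the ordination and exists only to keep the matrix on a relative scale.
Bray–Curtis dissimilarity (the community-ecology default; the original
metric is unnamed and this is a documented assumption, as are k = 2
dimensions) feeds non-metric MDS minimizing Kruskal stress-1 (SMACOF,
best of several seeded random starts). Zero-dissimilarity samples are
collapsed before embedding and share scores exactly; scores are centered
and rotated to principal axes with a deterministic sign convention, so
axis 1 carries the dominant gradient. Agreement between predicted and
observed ordinations is the squared Pearson correlation of first-axis
scores, invariant to reflection and affine rescaling. The observed
ordination uses the full query table's relative abundances. Two all-zero
samples are defined to have Bray–Curtis distance 0.

## Synthetic data

The generator emulates the structure of a large national soil survey:
sample pH uniform on [3.63, 8.75]; sequencing depths log-normal (median
10,000, log-sd 0.5, truncated at 1,000 — the survey publishes only its
≥ 5,000 filter, so the spread is a realistic choice); habitat labels drawn
from the survey's aggregate vegetation classes, loosely tied to pH band.
Counts are Poisson draws from HOF truth curves; realized table depths are
therefore the column sums. Default truth priors: a, c ~ U(−10, 5), b and
|d| ~ U(2, 60), M log-uniform on [5, 500], types stratified round-robin,
with true optima clipped into the gradient range.

The strong-signal variant (floors |b| ≥ 10, M ≥ 50) additionally
rejection-samples until each type's distinguishing features express inside
the window; these constraints were fixed from the identifiability analysis
of the model family, before recovery was measured, and are not tuned:

- unimodal truths need an interior optimum (x ∈ [0.15, 0.85]) and must fall
  to ≤ 35% of their peak at both window ends — a unimodal curve whose near
  flank never declines is observationally a plateau;
- V truths need flank-rate asymmetry 2–5× (|d| = b is exactly IV);
- II truths must not flat-top below the scaling constant (top of curve
  ≤ ~0.8 of the asymptote): the plateau family is closed under rescaling
  while the monotone family is not, so a II curve saturating below the
  max-count M is mathematically a III;
- III truths need the rise completed inside the window and a plateau
  covering ≥ 35% of it; I truths need mean counts ≥ 10.

Study pairs share round(f·n_query) truths between reference and query,
drawn without replacement with probability decreasing in the reference
taxon's abundance rank, so rare taxa are disproportionately study-specific
and the rank-bin coverage curve declines by construction. Simulated match
records place shared pairs at identity U(97, 100) (e-value 1e-50) and novel
taxa at U(80, 96.9), cleanly on either side of the hit criteria; no
nucleotide sequences are simulated.

What the generator does not emulate: overdispersion beyond Poisson,
compositional coupling between taxa (each OTU is sampled independently),
covariates other than pH, spatial autocorrelation, and sequence-level
artifacts (chimeras, primer bias). Passing recovery tests therefore show
the estimator is correct and well-calibrated under its own error model, not
that real soil data meet that model.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale, chosen to
exercise every stage in a few minutes on one CPU: recovery cohorts of
100–200 OTUs at 500 samples with the full 100 bootstraps; end-to-end study
pairs of 120 reference / 150 query OTUs at 300 samples, with 25 bootstraps
for the reference fits (the community-prediction result is insensitive to
the bootstrap override, which only hardens the type label) and 4 NMDS
restarts. All randomness flows from explicit seeds; the pipeline derives
per-stage seeds from a master seed and the stage name, so toggling one
stage never perturbs another and reruns are byte-identical.

## Known limitations

- Model II is structurally handicapped under the fixed-M convention (see
  above); this mirrors the reference convention and plausibly contributes
  to monotone fits being rare in practice relative to plateau fits.
- AIC (not AICc) is used, per the method description this implements.
- Type-III plateau edges depend on the 0.95-of-maximum convention.
- Poisson error ignores overdispersion common in amplicon counts; a
  log-depth offset is deliberately not applied by default (raw counts are
  modeled, matching the published fits), though predictions are rescaled
  to relative abundance for ordination.
- NMDS is a local optimizer; results are reproducible only under the seeded
  restart scheme used here.
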