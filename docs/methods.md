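# Methods

## The data model

The pipeline operates on per-CpG counts: for sample *i* and site *j*, a
methylated read count and a total read count from bisulphite-converted
RRBS libraries, read from 6-column Bismark-style coverage files
(1-based coordinates; the redundant percentage column is re-derived and
only checked).  A (site, sample) cell with zero total reads is
*missing* — the only operational definition count data support.  CpG
records reported separately for the two strands can optionally be
collapsed onto the plus-strand C (counts summed); the synthetic
generator emits already-collapsed sites, so collapsing is off by
default and enabled by a flag for real Bismark output.  Internal
coordinates are 1-based inclusive everywhere; BED/BED12 inputs are
converted on read.

## Site filtering

Three rules applied jointly (order-independent), with defaults:

* **Coverage** — mean total reads across all samples ≥ 5×, counting
  missing cells as zero coverage.  "Mean coverage depth" most naturally
  averages over all samples, so a site unobserved in many samples is
  penalized.
* **Mean methylation** — mean ratio over observed samples inside
  [0.1, 0.9], both ends inclusive; this removes constitutively hyper-
  and hypomethylated sites that cannot carry an age signal.  Boundary
  hits are vanishingly rare in count data, but the rule must be
  deterministic, so inclusivity is fixed.
* **Missingness** — fraction of missing samples strictly below 5%;
  a site missing in exactly 5% of samples is excluded.  The fraction is
  computed over samples by default; a `missing_unit="individual"`
  option counts an individual as missing when *any* of its samples is
  missing there (the conservative reading when individuals are sampled
  repeatedly).

Filtering is idempotent, and the report records per-rule failure counts
(rules can overlap, so the failures need not sum to the number
removed).

## Imputation

Remaining missing ratios are filled by a k-nearest-site rule (k = 10,
matching the default behaviour of the standard kNN imputer for
expression/methylation matrices): the distance between two sites is
Euclidean over the samples both observe, rescaled by
`n_samples / n_shared` so sparsely shared pairs are not spuriously
close; the imputed value is the mean of the target sample's values at
the k nearest donor sites observed in that sample.  Sites missing in at
least half the samples fall back to their own observed mean.  Observed
entries are never altered, and imputed values are clipped to [0, 1].
The implementation is a chunked masked-matrix computation; the test
suite checks it cell-by-cell against an exhaustive scan and against an
independent library implementation of the same rule.

## Per-sample rank normalization

Each sample's ratios over the retained site universe are replaced by
`Φ⁻¹((r − a) / (n + 1 − 2a))` with average ranks for ties and
`a = 3/8` for n ≤ 10 else `1/2` — the qqnorm plotting-position
convention.  Because the transform involves only the sample's own
values, normalization commutes with sample subsetting: a single new
sample can be normalized at prediction time with no training-state
leakage.  The site universe the ranks were computed over is stored with
the trained model, and prediction-time samples are normalized over that
same universe (not over the clock's final sites), reproducing the
training-time value distribution.

## Feature selection and the elastic net

Clock candidates are sites whose normalized methylation has |Pearson
r| > 0.5 with chronological age (strict inequality).  Absolute-value
selection is the default: clocks in this design regularly carry both
hyper- and hypomethylating sites, and a signed `r > 0.5` reading would
exclude the latter; the signed mode is retained as an option.

The elastic net minimizes

    (1/2n) Σ (y_i − β₀ − x_iβ)² + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)

on internally standardized features (population SD; coefficients are
returned on the caller's scale).  The solver is cyclic coordinate
descent with soft-thresholding and incremental residuals, alternating
full sweeps with sweeps over the active set.  On the feature sets this
pipeline produces — hundreds of mutually correlated age-tracking CpGs —
plain coordinate descent converges too slowly for a meaningful
optimality guarantee, and small per-sweep coefficient changes do not
imply a small gradient.  Final fits therefore alternate short
coordinate-descent runs (which identify the active set and its signs)
with exact restricted quadratic solves — via the Woodbury identity when
the active set is wider than the sample count — and terminate only when
the subgradient (KKT) residual is below 10⁻⁷, a certificate checked
again in the tests.  Lambda paths evaluated inside cross-validation use
sweep-capped loose descent (200 sweeps/point, tolerance 10⁻⁵): only the
out-of-fold MSE ranking of neighbouring lambdas matters there.

Lambda paths are 100 points, log-spaced from λ_max (the smallest λ with
an all-zero lasso solution) down to 10⁻³·λ_max; at α = 0 the exact
λ_max is infinite, so the path top is computed at the conventional
surrogate mixing value 10⁻³.  `lambda="cv"` picks the MSE-minimizing
point by 10-fold internal cross-validation.  The mixing parameter α is
grid-searched (0 to 1 in steps of 0.01 by default) on the squared
Pearson correlation between out-of-fold predictions and age, with folds
shared across alphas and grouped by individual when repeated samples
exist; exact ties go to the larger (sparser) α.  An epsilon-SVR with an
RBF kernel is available as a non-linear comparator and appears next to
the elastic net in tuning tables; it never feeds the clock itself.

## Cross-validation design

Repeated sampling of the same individual makes sample-level CV leak:
two samples of one elephant resemble each other far beyond their age
difference.  Evaluation therefore uses leave-one-individual-out CV —
one fold per individual, all of that individual's samples held out
together.  Feature selection runs once on the full data before LOIOCV
by default (`selection_mode="paper"`, the protocol historically used
with this design); `"nested"` repeats selection inside each fold and
quantifies the pre-selection optimism.  Fold models are refit at the
globally tuned (α, λ); per-fold λ re-tuning is available via the
config.  An age-stratified random train/test split (quantile bins,
default 5) is provided for held-out evaluation, with a `unit=individual`
mode that keeps individuals intact.

Predicted age is the affine clock applied to the rank-normalized
sample; predictions are not clamped, so a negative DNAm age is reported
as-is.  A prediction-time sample may lack up to 5% of the candidate
universe (filled from stored training-site means); beyond that the
sample does not cover the clock and the call errors.

## Downstream analyses

* **Metrics** — MAE (years); Pearson r; R² reported as squared Pearson
  correlation (the pairing conventional in the clock literature when
  quoted next to r), with the residual-based 1 − SSE/SST variant
  computed and labelled separately; relative error = 100·MAE / maximum
  recorded lifespan (79.6 y for the Asian elephant).
* **Δage** — residuals of OLS of DNAm age on chronological age; zero
  mean by construction.
* **Age classes** — calf [0,1), juvenile [1,5), subadult [5,20), adult
  [20,50), senior [50,∞); boundaries half-open on the left value so the
  classes partition the age axis (published class tables write "> 50",
  but 50 must belong somewhere).  Group differences: one-way ANOVA plus
  pairwise Welch t-tests (unequal variances; groups here are strongly
  unbalanced) with Benjamini–Hochberg adjustment and a compact-letter
  display.
* **PCA** — samples over clock sites, columns centred and unit-scaled,
  SVD, sign fixed so each component's largest-magnitude loading is
  positive.
* **Sex effects** — per clock site, `methylation ~ DNAm age + sex +
  DNAm age:sex`.  Discovery takes the smaller of the sex and
  interaction p-values (the winning term is reported); since that
  minimum is itself a two-test family, it is Bonferroni-doubled before
  BH across sites (flag at q < 0.05).  Sites are rank
  inverse-normal-transformed before fitting, and per-site variances are
  moderated by empirical-Bayes shrinkage toward a scaled
  inverse-chi-square prior (the moderated-t construction): methylation
  ratios are bounded and heteroskedastic, and with a small minority sex
  the far tail of a raw t reference is anti-conservative — permutation
  experiments in the test suite show the moderated, transformed test
  holds its nominal false-positive level where the raw test does not.
  A companion Gaussian model of Δage on sex (with and without a
  chronological-age covariate) gives the global test.  Samples of
  unknown sex are excluded; the analysis refuses to run with fewer than
  3 samples of either sex.
* **Longitudinal change** — per repeatedly sampled individual, only the
  chronologically first and last samples are kept; pairs closer than
  one day (1/365.25 y) are dropped as near-duplicates; the per-
  individual change in DNAm age is tested against zero with a
  one-sample, one-sided (greater) t-test, df = n − 1.  Sidedness is
  deliberate: the scientific hypothesis is that epigenetic age
  *increases* with elapsed time.  Intervals are always recomputed from
  ages; `check_interval_consistency` cross-checks any reported interval
  column and flags transcription errors (the bundled reference table of
  17 repeatedly sampled elephants contains one gross inconsistency,
  individual 15, and two ~0.1–0.2 y ones).
* **Genomic context** — density: island (inside a merged island
  interval), shore (within 2,000 bp of an island boundary, inclusive),
  else outside — a strict partition.  Genic: promoter (within ±2,000 bp
  of the strand-aware TSS, inclusive) takes precedence over exon, exon
  over intron, else intergenic with the nearest gene by TSS distance
  (ties to the lower gene start, then name).  Direction of ageing
  change is the sign of the site's age correlation.  Summaries report
  counts, hyper/hypo splits and mean r per category plus a one-way
  ANOVA of r across density groups.

## The synthetic cohort generator

The generator emulates the statistical structure of a captive-elephant
blood RRBS study; its defaults are the study conditions.  Per site *j*,
class ∈ {age-up, age-down, constitutively high, constitutively low,
null} with proportions 12% age-associated (hyper:hypo ≈ 288:101,
the split reported for elephant clock sites), 4% + 4% constitutive, the
rest null.  Methylation probability follows a logit-linear age model

    p_ij = expit(β₀ⱼ + β₁ⱼ·age_i + e_ij),   e_ij ~ N(0, σ_site)

with |β₁| uniform on 0.03–0.08 per year for age sites (calibrated so
|r| > 0.5 is attainable, not to elephant biology, which reports no
effect-size distribution), σ_site = 0.3, and baseline β₀ ~ N(0.8, 0.8)
for null/age sites — calibrated analytically so sites surviving the
[0.1, 0.9] filter average ≈ 0.66 methylation.  Age sites are re-centred
so their trajectory stays away from saturation over the age range.
Read totals are negative-binomial (mean 30, dispersion 5), zeroed with
probability 0.01 (sparse missingness); methylated counts are binomial.
Cohort structure: 30 individuals, ages uniform on 0–56 y (an "elephant"
profile draws baseline ages from the observed age-class mixture
7/4/41/30/9 instead), 70% longitudinal with 2–6 samples at 0.5–4 y
intervals, 90% female.  All randomness flows from one seed through
per-operation substreams, so partial re-runs are reproducible and
fixtures are byte-identical across runs.

What the generator does *not* model: the late-life plateau and early-
life acceleration of methylation change (the per-site model is strictly
logit-linear in age), batch and library-size effects, cell-composition
shifts, genomic autocorrelation between neighbouring CpGs, and
bisulphite conversion error.  Passing tests on these cohorts therefore
demonstrate the pipeline's correctness and its statistical behaviour
under the stated model — not clock accuracy on real elephants, where
non-linearity and technical structure will inflate errors.

For scoring feature selection against ground truth, a planted site's
*attainable* correlation is computed analytically from the generative
model: on the logit scale, signal SD is |β₁|·sd(age) and noise SD
combines σ_site with the binomial sampling noise
`1/(coverage·p(1−p))` at the mid-age methylation level.  Recall is
measured over planted sites whose attainable |r| exceeds the selection
threshold; the false-positive rate over null sites.

## Numerical and scale choices

Scaled-down experiment sizes keep the default suite fast while leaving
wide statistical margins: the clock-recovery cohort uses 20,000 sites
with ~300 planted age sites over ~30 individuals (observed recovery
r ≈ 0.998, selection recall ≈ 1.0 at those margins), permutation
calibrations use 100 replicates, and the sign-flip uniformity check 500
replicates.  Coordinate-descent tolerances are stated above; KNN
imputation chunks 512 sites at a time against the full site set; the
trigamma inversion inside the variance moderation uses Newton's method.
Degenerate inputs are handled explicitly: zero-variance sites are
skipped (selection, PCA) with warnings; an individual owning all
samples, single-sex data, constant ages, and zero-variance deltas all
raise informative errors rather than returning NaN.

## Known limitations

* The sex model's linear DNAm-age adjustment is misspecified at sites
  with strongly sigmoidal age trajectories; permutations that are
  imbalanced in age can then pick up residual age structure as a
  spurious sex effect.  The moderated test controls the false-positive
  rate on null sites; at strong age sites the companion Δage-on-sex
  model is the more trustworthy global test.
* LOIOCV with pre-selected features (the default, protocol-faithful
  mode) inherits the optimism of selecting on all data; nested mode
  exists to measure it, and on synthetic data the gap is small only
  because the planted signals are strong.
* The generator's logit-linear age model cannot probe the reduced
  late-life resolution real clocks show; an age-transformation hook
  would be the natural extension.
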