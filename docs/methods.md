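# Methods

## The analysis problem

A longitudinal plasma-proteomics panel measures 184 immune analytes (115
cytokine/chemokine/interferon/TNFSF mediators and 69 soluble receptors) in
trauma patients at 0, 24 and 72 h after admission.  Patients fall into
outcome groups — early non-survivors (ENS, death ≤ 72 h, 0 h sample only),
resolvers (R, alive at 30 d with < 7 ICU days) and non-resolvers (NR, death
after 72 h or ≥ 7 ICU days) — plus minimally injured controls (ISS ≤ 1).
The pipeline asks three questions: how mediator levels differ by outcome and
injury severity over time, whether those differences survive matching on
age/sex/ISS, and how well 72 h mediator levels predict eventual outcome.

## Synthetic cohort model

Real patient-level data are not public, so validation runs on a generator
whose defaults encode the study conditions.  On the log2 scale, analyte *a*
in patient *p* (group *g*, ISS *s*) at time *t* hours is

    y = b_a + A_a · c_g · (1 + k·s) · 2^(−t/h)          (early release)
      + ramp(t) · d_g · 1[a ∈ delayed subset]           (delayed release)
      + u_{p,a} + ε,   u ~ N(0, σ_p²),  ε ~ N(0, σ²)

with raw values 2^y (log-normal noise, consistent with an analysis that
log2-transforms everything).  Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| group sizes | ENS 38 / R 34 / NR 78 / control 29 | published cohort sizes |
| baseline b_a | N(10, 1.5²) log2 RFU | typical aptamer-assay fluorescence scale |
| amplitude A_a | abs(N(1.0, 0.4²)) | early-release burst per analyte, log2 units |
| group scale c_g | ENS 1.0, NR 0.9, R 0.45, control 0 | "early massive release", strongest in ENS/NR |
| ISS slope k | 0.02 per point | severity-dependent release (≈ +60 % at ISS 30) |
| half-life h | 24 h mediators, 48 h receptors | decay of the 0 h burst; the data show but do not parameterize it, so an exponential with per-role half-life is used |
| delayed subset | 15 % of mediators | "small subset" elevated late; fraction is a calibration choice, no published value exists |
| delayed effect d | NR 1.5, R 0.5 at 72 h (ramp 0 / 0.5 / 1) | NR − R = 1.0 log2 units at 72 h, the planted effect recovery tests target |
| noise σ, patient σ_p | 0.5, 0.3 log2 units | within/between-patient variability giving a per-feature standardized NR-vs-R effect ≈ 1.7 for delayed analytes |
| missingness | 2 % LOD censoring + 3 % MCAR | censoring below a per-analyte quantile motivates the minimum-value imputation; MCAR covers sporadic assay dropout |

Covariates (age, ISS, sex, intervention arm, ICU/ventilation/hospital days)
are drawn from per-group truncated normals and Bernoullis matching the
published demographics tables; durations are drawn so that outcome
classification recovers the generating group exactly.  Delayed-subset
analytes get amplitude 0 (they start low, as observed).  Amplitudes are
nonnegative, so at 0 h every early-release analyte is ordered
ENS ≥ NR > R > control in expectation.

Covariate, analyte-parameter, noise and missingness draws use four
independent RNG streams spawned from the single config seed, so changing
the panel size never reshuffles the covariates and a fixed seed fixes every
value bit-for-bit.

**What the generator does not emulate:** plate/batch effects beyond scale
factors, hemolysis artifacts, heavy-tailed or analyte-correlated noise,
informative dropout of late samples in deteriorating patients, and the full
7.5K assay content.  Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and calibrated under its stated model, not
that clinical effect sizes would be this clean: with 17 planted mediators at
a 1.0 log2 shift the prediction ensemble reaches near-perfect out-of-bag
AUROC, whereas real cohorts sit much lower.

## Preprocessing

Fixed order, re-applied to each analysis subset: extract panel roles →
remove analytes with strictly more than 20 % missing values (exactly 20 %
is retained) → impute remaining gaps with the per-analyte observed minimum
(analyte-specific detection limits argue against a global minimum) →
log2 transform.  QC ranges are treated as closed intervals (the printed
ranges carry no bracket semantics).  Scale-factor normalization itself is
assumed applied upstream by the assay vendor; the module gates on the
factors rather than re-normalizing.

## Statistics

* **Two-group tests**: Shapiro–Wilk at α = 0.05 per group gates between a
  two-sample t-test and Mann–Whitney U.  The t-branch uses Welch's unequal
  variance form because the outcome groups differ in size and spread.
  The MWU p is exact (full null enumeration in scipy) when both groups have
  ≤ 8 observations and no ties, otherwise the normal approximation with tie
  correction.  Groups below n = 3 are flagged untestable rather than tested.
* **Volcano tables** use MWU unconditionally (the convention for the
  volcano displays), BH-adjusted across analytes within one
  (contrast, timepoint) family; significance requires both |log2fc| ≥
  log2 1.5 ≈ 0.585 and adjusted p < 0.05.  log2fc is mean(NR) − mean(R).
* **Multi-group**: all-normal → one-way ANOVA + Tukey HSD; otherwise
  Kruskal–Wallis + Dunn's rank z-test with tie correction, pairwise p
  BH-adjusted.  An all-identical input returns omnibus p = 1 rather than an
  error.
* **Heatmap z-scores** standardize the per-(group, timepoint) cell means of
  each analyte row (one column per category, as displayed), using the
  sample (n−1) SD so cross-language ports agree; unsampled cells (ENS at
  24/72 h) are absent, not zero, and constant rows return z = 0 with a
  degenerate flag.
* **Cohort summaries** use Pearson's χ² *without* continuity correction for
  categoricals — this reproduces the published sex-table p of 0.8124 — and
  the gated two-group test for numerics, with the choice logged per
  covariate.

## Matching

The original matching tool's algorithm is undocumented, so the package uses
greedy nearest-neighbor matching without replacement on the
tolerance-normalized (Δage/10 y, ΔISS/8 pt) Euclidean distance, restricted
to exact sex matches within both calipers.  Case order is shuffled under a
seed; distance ties break on the lowest control id, making results
reproducible.  An optional many-to-one phase lets unmatched cases reuse the
nearest admissible control, yielding the balanced-but-unequal group sizes
seen in matched designs.  Caliper widths are package defaults, not
published values; no downstream result depends on their exact value.

## Prediction engine

Per iteration: draw 112 patients with replacement from the R∪NR pool
(unstratified — the draw size equals the pool size, so the expected
out-of-bag fraction is e⁻¹ ≈ 0.368); redraw up to 10 times if either the
in-bag or out-of-bag set lacks a class, then skip with a logged warning;
standardize features on in-bag statistics only; select features by
L1-penalized logistic regression with the penalty chosen by inner 5-fold CV
maximizing in-bag AUROC over C ∈ logspace(−2, 1, 7) (the method names LASSO
but no hyperparameter rule, so CV is the natural completion); train a
linear-kernel SVM with C = 1 on the selected features; score the
out-of-bag patients by decision values.  "Selected" means nonzero
coefficient — literal strict positivity would discard protective markers —
with a strict-positive mode behind a flag.  If nothing is selected the
iteration scores AUROC 0.5 (constant rule) and is flagged.

The B out-of-bag AUROCs are summarized by median and 2.5/97.5 percentiles.
The permuted control permutes **in-bag** labels after the draw and evaluates
against true out-of-bag labels; because per-iteration RNG streams are
spawned from the seed and the permutation consumes draws only after the
bootstrap sample is fixed, real and control iterations share draws
pair-for-pair.  Significance is a one-sided Wilcoxon signed-rank on the
paired AUROC differences (a two-sample MWU mode is available; which test
the original summary statistic used is ambiguous).  Importance is
RMS(weights over all B iterations, zeros included), scaled to max 100 —
invariant to global weight rescaling.  PLS-DA regresses the 0/1 outcome on
standardized features and reports X-scores plus per-component explained
X-variance.

## Problem sizes in tests

Validation suites run at the study's native cohort size (n = 112 pool,
115 mediator features) with B = 200 bootstrap iterations and 5–20
simulation seeds per property — enough for the percentile and recovery
statistics to stabilize while keeping the full suite in the minutes range.
Null calibration checks that the permuted-control median AUROC lies in
[0.45, 0.55] and that an effect-free cohort yields ≤ 7 % BH-significant
volcano calls; recovery checks demand volcano sensitivity ≥ 0.8 at observed
FDR ≤ 0.2, a real-ensemble median above the control's 97.5th percentile,
and ≥ 4 of the top-5 importance ranks on planted features.

## Known limitations

* The delayed-subset fraction, effect decay and noise levels are
  calibration choices where no published values exist; conclusions from the
  synthetic cohort are conditional on them.
* Dunn's post hoc uses the large-sample normal approximation; very small
  groups (< 5) inflate its error, where Tukey on ranks would behave better.
* The pipeline accepts only the plain tab-delimited matrix dialect, not
  binary vendor formats.
* Matching is covariate matching, not propensity modeling, by design.
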