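# Methods

## The model

Each study i compares mean serum TSH (mU/L) between cases (thyroid cancer)
and controls (benign nodules). The effect is the log ratio of means
y_i = ln(x̄_case/x̄_control) with delta-method variance
v_i = s²_c/(n_c x̄²_c) + s²_k/(n_k x̄²_k) — the sum of the squared
coefficients of variation of the two group means. The ratio is used, rather
than a mean difference or standardized difference, because TSH assays differ
across laboratories: a ratio is invariant to a common rescaling of both
groups, which the tests assert exactly.

True study effects are modelled as θ_i = μ + u_i with u_i ~ N(0, τ²);
observed y_i ~ N(θ_i, v_i). Pooling is DerSimonian–Laird: fixed-effect
weights w_i = 1/v_i give Cochran's Q = Σw_i(y_i − ȳ_w)², the moment
estimator τ̂² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), random weights
w*_i = 1/(v_i + τ̂²). I² = max(0, (Q − df)/Q). Confidence intervals use the
normal quantile on the log scale and are exponentiated only at the reporting
boundary; no Knapp–Hartung adjustment is applied, keeping the z-based P
values of the rest of the pipeline. When Q ≤ df, τ̂² truncates to zero and
the random-effects result coincides with the fixed-effect result exactly
(asserted in tests). A single study is returned as itself with τ² = 0.
k must be ≥ 3 for leave-one-out (each re-pool keeps ≥ 2 studies).

Subgroup levels are pooled independently; two pooled subgroups are
contrasted with z = (y_a − y_b)/√(se_a² + se_b²). A between-group Q test is
a known variant; the z contrast is what the package reports.

## Median/range conversion

Studies reporting median m and range [a, b] are converted with
mean = (a + 2m + b)/4 and an SD rule switching on sample size:
√(((a − 2m + b)²/4 + (b − a)²)/12) for n ≤ 15, (b − a)/4 for 15 < n ≤ 70,
(b − a)/6 for n > 70. The band boundaries are closed on the left band (15
and 70 belong to the lower band); the convention is a documented choice, as
is rejecting a degenerate range (a = b), which would produce SD 0. Only the
full-range conversion is implemented; interquartile ranges are out of scope.

## Meta-regression

Residual heterogeneity is estimated by REML: the restricted log-likelihood
−½[Σln(v_i + τ²) + ln det(XᵀWX) + rᵀWr] is maximised by bounded scalar
search (tolerance 1e-10 on τ², upper bound 10·max(var(y), max v_i, 0.1)),
with the τ² = 0 endpoint checked explicitly. Coefficients are the GLS
solution at τ̂² with normal-theory z tests. Categorical covariates:
size_class enters as an ordered integer 0/1/2 (the bands < 200, 200–500,
> 500 cases are ordinal); other factors are treatment-coded indicators, with
the coding recorded in the fit for transparency. Modifiers are screened one
per model (`screen_modifiers`), the usual practice when hunting
heterogeneity sources; joint models are available through `meta_regress`
directly. An intercept-only REML fit differs numerically from the
DerSimonian–Laird moment pool — both are correct answers to different
estimating equations.

## Small-study-effect tests

Egger: unweighted least squares of the standardized effect y_i/se_i on the
precision 1/se_i; the intercept is t-tested on k − 2 df. This
parameterization is algebraically the inverse-variance-weighted regression
of y on se (asserted in tests). Begg: Kendall correlation between the
variance-stabilised deviates (y_i − ȳ_w)/√(v_i − 1/Σw) and the v_i; the
p-value is an exact permutation enumeration for k ≤ 8 (no ties) and the
tie-corrected normal approximation with continuity correction otherwise.
Galbraith coordinates are (1/se, y/se) with the no-intercept fitted slope —
identically the fixed-effect pooled estimate — and studies flagged when the
residual exceeds ±2 (strict inequality, the conventional band).

Egger's test is only calibrated under a homogeneous null: with the
generator's default between-study SD τ = 0.3 the measured rejection rate at
α = 0.05 is ≈ 0.02 (conservative), while under τ = 0 it is ≈ 0.05. The
type-I calibration check therefore simulates the homogeneous null; the
generator default is unchanged.

## Diagnostic arm

Per study, sensitivity tp/(tp+fn) and specificity tn/(tn+fp) at the study's
TSH cut-off; cut-offs are grouped into the bands < 0.5, 0.5–1.5, 1.5–2.5 and
> 3.5 mU/L, and a cut-off in the gap (2.5, 3.5] is rejected rather than
silently assigned. A continuity correction of 0.5 is added to all four
cells only when some cell is zero, before both pooling and the SROC.
Proportions are pooled on the logit scale with the same DL engine and
back-transformed (raw-scale pooling is a known alternative and a potential
source of numeric discrepancy with other software). Likelihood ratios
PLR = sens/(1 − spec), NLR = (1 − sens)/spec are pooled as log LRs with
delta-method variances; a test is "clinically useful" only when PLR > 10
and NLR < 0.1 (strict).

The summary ROC is the Moses–Littenberg construction: D = logit TPR −
logit FPR regressed on S = logit TPR + logit FPR, unweighted by default
(inverse-variance weighting available behind a flag). The curve
TPR(x) = expit((a + (1+b)·logit x)/(1 − b)) is integrated over the full
FPR ∈ (0, 1) by adaptive quadrature for the AUSROC; |b| ≥ 1 makes the
back-transform non-monotone, so coefficients are reported but the area is
NaN. The AUSROC CI is a seeded nonparametric percentile bootstrap over
studies (2000 resamples by default; resamples with |b| ≥ 1 are dropped, and
the CI is suppressed if fewer than 100 remain). The bivariate
(Reitsma/HSROC) model is deliberately out of scope.

## Synthetic data generator

`simulate_rom_studies` draws, per study, θ_i = μ + τ·u_i; a control mean
from a lognormal (location ln 1.5, scale 0.3 on the log scale — typical
benign-nodule TSH around 1.5 mU/L); and n individual TSH values per arm from
a lognormal with coefficient of variation 0.9 (TSH is positive and
right-skewed; a gamma option exists). Observed means/SDs are sample
statistics of the draws, so the delta-method variance faces genuine sampling
noise; category counts tabulate the same draws, guaranteeing internal
consistency between the RoM and odds-ratio arms. The small-study-effect knob
adds λ·se_i to θ_i, with se_i the anticipated delta-method standard error.
Defaults emulate a literature-scale synthesis: k = 56 studies, true ratio
1.44, τ = 0.3, case n ∈ [20, 800], control n ∈ [40, 2000], a 75/20/5
Asian/Caucasian/other mix, mostly adult, mostly retrospective
cross-sectional. What the generator does **not** emulate: non-lognormal
assay artefacts, correlated subgroup structure within a study, rounding of
published summaries, or selective reporting — so green tests certify the
statistics, not robustness to every pathology of real literatures.

`simulate_diagnostic_studies` draws study-level (logit sens, logit spec)
from a bivariate normal (default correlation −0.3, the usual
threshold-driven trade-off) and binomial 2×2 cells. Defaults (sens 0.76,
spec 0.44, k = 22) sit at a mid-band TSH cut-off scale.

All randomness flows from one integer seed through numpy's splittable
generator; emitted CSVs record the seed in a header comment, and identical
seeds reproduce byte-identical tables.

## Numerical and interface choices

- Validation is fail-fast: a study table with any invalid row raises a
  single error listing every offending row number; the CLI maps validation
  to exit code 2 and statistical degeneracy (too few studies for a stage)
  to exit 3.
- `size_class` is always recomputed from n_case; a conflicting supplied
  column warns and is overridden (the bands are definitional).
- Odds-ratio bins are half-open [low, high); a range that does not align
  with a study's bin edges is an error naming the offending edge.
- The continuity correction (0.5) is applied only in the presence of a zero
  cell, never unconditionally.
- TSV reports round to 2 decimals; `report.json` keeps full precision and
  is byte-stable across reruns with the same seed (the output directory
  path is kept out of it).
- Problem sizes in the validation suite (k = 200 recovery, 2000-replicate
  Egger calibration, k = 100 diagnostic recovery) are chosen so Monte-Carlo
  error is small relative to the tolerances being checked while the whole
  suite stays fast enough to run routinely.

## Known limitations

- DL is the only τ² estimator for pooling (REML appears only in
  meta-regression); Paule–Mandel and Knapp–Hartung are not offered.
- The Moses–Littenberg SROC ignores within-study imprecision and the
  sens/spec correlation; it is kept because it is the classical summary the
  reporting tables are built around.
- No trim-and-fill or permutation meta-regression p-values.
- Real supplementary datasets must be transcribed to the documented CSV
  dialects by the user; no PDF/table extraction is provided.
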