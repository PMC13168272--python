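# Methods

## Problem setting

`splsmorph` implements a morphometry-to-trait prediction analysis: given a
table of parcel-wise cortical features (mean cortical thickness, gyrification
index, or sulcal depth for ~600 Schaefer-style parcels) and a per-subject
trait score (the 7-item Toronto Empathy Questionnaire sum, an integer in
0–28), it asks whether the trait can be predicted from cortical morphology in
unseen subjects, and whether individual regions relate to the trait at the
group level. The regime of interest is small-n / large-p (tens of subjects,
hundreds of correlated parcels), where in-sample fit is uninformative and
honest out-of-sample validation is the whole game.

## Sparse partial least squares (single response)

The predictive model is sparse PLS1. Component k is built from the current
(deflated) standardized feature matrix X and response y:

1. candidate weight `w ∝ Xᵀy`;
2. soft-threshold `w` at the magnitude of its (keepX+1)-th largest entry, so
   at most keepX entries stay nonzero;
3. normalize `w` to unit length; score `t = Xw`;
4. loadings `p = Xᵀt/tᵀt`, `c = yᵀt/tᵀt`;
5. regression-mode deflation of both blocks: `X ← X − tpᵀ`, `y ← y − tc`.

The coefficient vector on the standardized scale is `β = W(PᵀW)⁻¹c`;
prediction adds the training response mean. Successive scores are mutually
orthogonal by construction. With keepX equal to the feature count the
procedure reduces exactly to dense PLS1 (verified against an independent
NIPALS implementation to 1e-8 in the tests).

Numerical choices:

- **Thresholding.** Pure soft-thresholding is used. When entries tie exactly
  with the cutoff magnitude they are all zeroed, so a component may retain
  fewer than keepX features; with continuous data this is a measure-zero
  event. Where a deterministic tie-break is needed on discrete quantities
  (the importance ranking), ties in |coefficient| break by ascending feature
  index.
- **Degenerate components.** A zero weight vector or zero score norm
  truncates the decomposition early with a warning; a model with no usable
  component predicts the training mean.
- **Variance filter.** Features with training-sample SD ≤ 1e-8 (ddof = 1
  throughout) are removed before standardization; the tolerance is
  configurable. A fold in which no feature survives falls back to the
  training-mean prediction and is logged.
- **keepX is one scalar per model**, shared by all components.

## Nested leave-one-out validation

Each subject is held out in turn. Inside each training fold, the variance
filter, the centering/scaling parameters, and the keepX budget are recomputed
from the n−1 training rows only; the held-out subject is transformed with the
stored training parameters and predicted. keepX is tuned by an inner LOO loop
over the training fold, minimizing mean squared prediction error, ties going
to the smaller budget (parsimony). The grid defaults to multiples of 5 up to
the retained feature count; values above a fold's retained count are dropped
and the retained count itself appended, so the dense model stays reachable.
The grid is capped once per tuning call using that training set's retained
count; inner folds that lose a feature to the variance filter simply exclude
it (zero weight) without re-capping.

The component count K is selected by a BIC on the outer cross-validated
residuals, `BIC = n·log(RSS/n) + k·log(n)` (natural log, k = number of
components), smallest k winning ties. The same outer-CV residuals then supply
the reported metrics — RMSEP, `Q² = 1 − PRESS/TSS` (baseline: mean of the
full observed vector, so Q² < 0 means worse than predicting the mean), and
R² (squared Pearson correlation of observed vs cross-validated predictions,
which can be sizeable even when Q² is negative since correlation ignores
calibration). This double use of the residuals for selection and reporting is
optimistic by construction and is flagged in the written report.

With fewer than three training rows, or a single-value grid, there is
nothing to tune and the single candidate is used directly.

### Fast path for single-component models

For K = 1 the inner LOO is evaluated in closed form for all folds at once:
per-fold training means, SDs and feature–response covariances come from
rank-one downdates of full-data sums, and the score norms from one
matrix product per grid value. The generic per-fold loop is used for K > 1;
the two paths agree to numerical precision (unit-tested), so the fast path is
an implementation detail, not a model variant.

### Permutation inference

Significance of Q² is assessed by permutation: the responses are reshuffled,
the pipeline rerun — variance filtering, standardization and keepX retuning
redone per fold — and Q² recomputed. The component count is frozen at the
observed selection to bound cost; full reselection per permutation is
available via `retune_components`. The add-one convention
`p = (1 + #{Q²_b ≥ Q²_obs})/(B + 1)` avoids p = 0. Each permutation draws
from an independent substream spawned from the master seed, making results
reproducible and order-independent. Calibration (uniform p-values on null
data) is verified in the acceptance tests.

## ROI-level regression

For a designated parcel, the trait is regressed on centered powers of the
parcel value (degree 1–4) plus age and a female indicator (female = 1).
The underlying subject-level model has one observation per subject, so a
subject-specific random intercept is unidentifiable — its variance cannot be
separated from the residual — and the model is therefore estimated as
fixed-effects least squares (via statsmodels OLS), with the intercept
variance absorbed into σ². Degrees are compared by the Gaussian
log-likelihood BIC, ties resolved toward the lower degree. Centering the
polynomial basis keeps coefficients interpretable; fitted values and BIC are
invariant to affine rescaling of the parcel values (tested). No
multiple-comparison correction is applied across the small set of a-priori
ROI hypotheses; the output states this.

Supporting screens: MAD outlier detection flags values whose absolute
deviation from the median exceeds `threshold × 1.4826 × MAD` (defaults 3.0
and the normal-consistency constant, both configurable); when MAD = 0 any
value differing from the median is flagged (logged). Flagged subjects are
reported but retained by default. Group comparisons use the two-sided
Wilcoxon rank-sum test with the rank-biserial effect size
`rbc = 1 − 2U/(n₁n₂)`, where U is the first group's Mann–Whitney statistic
(positive rbc: the first group tends to score lower). Spearman correlations
(mid-ranks, t-approximation p) provide a nonparametric check of the ROI
associations.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw images: parcel values are drawn from a block-equicorrelated covariance
(equicorrelated within block, independent across blocks) — a cheap,
controllable stand-in for spatial correlation on the cortical sheet that is
sufficient to stress the multicollinearity handling motivating sparse PLS —
with per-parcel SDs drawn from a configurable range (heterogeneous variance)
and measure-specific baselines (cosmetic; the analysis standardizes). The
latent trait is

    intercept + Σⱼ bⱼ·dⱼ + (b₁·d_r + b₂·d_r²) + gender_effect·female
    + age_effect·(age − mean age) + N(0, noise_sd²),

with dⱼ the centered parcel deviations; the observed score is the latent
rounded to the nearest integer and clipped to [0, 28] (clipping after
rounding preserves the Likert-sum semantics). Age is centered in the
generative equation so the intercept stays on the trait scale.

Defaults describe the emulated study conditions: n = 62 adults aged 18–85
(uniform), 56.45% female, 600 parcels in 60 blocks with within-block
correlation 0.4, a +2.19-point female effect on the trait, intercept 21.90
and residual latent SD 2.6 (together reproducing an overall trait SD near
2.9 and group means near 22.9/20.7), and **no parcel→trait effects** — the
emulated study's machine-learning outcome is essentially null. Parcel-level
covariance and variance values are plausibility choices; no parcel-level
summaries were available to calibrate them.

`inject_outliers` shifts k subjects' scores by a given magnitude, choosing
the direction that lands farthest from the cohort median (so a sufficiently
large shift is MAD-detectable even near the scale ceiling), then clips back
to [0, 28].

What passing tests on these cohorts do **not** show: robustness to scanner
or site effects, non-Gaussian parcel distributions, geodesic (distance-decay)
spatial correlation, item-level response processes, or missingness
mechanisms beyond listwise-removable gaps. Results on synthetic cohorts
certify the pipeline's statistical behaviour, not any empirical claim about
real cortical data.

## Experiment sizes and design choices

The packaged experiments run at desk scale, chosen once:

- **Null calibration**: 100 cohorts (n = 30, p = 40), grid {5, 10, 20, 40},
  one component, B = 49 permutations; the fraction of p ≤ 0.05 must sit in
  the binomial band [0.01, 0.11] around the nominal rate.
- **Null Q²**: 100 cohorts (n = 40, p = 60), candidates {1, 2}; median
  nested-CV Q² ≤ 0 — the mechanism behind negative cross-validated Q² when
  over-parameterised models meet trait-independent features.
- **Signal recovery**: 10 informative parcels of 300 carrying ~50% of trait
  variance at n = 200, blocks of 5 parcels. Each informative parcel sits in
  its own block: giving informative parcels many highly correlated
  block-mates makes "recall of the planted parcels" ill-posed (a near-copy
  is nearly as informative) and lets proxy covariances crowd the selection
  threshold. Soft-thresholding is conservative here — selected covariances
  are shrunk toward the threshold — so cross-validated Q² (~0.2–0.3) sits
  well below the planted R² of ~0.5 even with correct selection; this gap is
  a property of the estimator at this signal-to-noise ratio, not a defect.
- **Quadratic ROI detection**: n = 62, quadratic parcel effect sized to
  ~15% of trait variance, intercept mid-scale (14) so the planted share is
  realized on the observed integer scale rather than attenuated by ceiling
  clipping; degree-2 wins the BIC race in the order of 85% of replicates,
  and degree-1 wins on null cohorts at a similar rate.
- **Study-scale run** (`scripts/acceptance.py`): n = 62, p = 600 null
  cohort with a keepX grid in steps of 25 and component candidates {1, 2},
  B = 49 permutations. The paper-scale search (grid step 5 up to 600,
  candidates 1..61, B = 1000) is expressible through the configuration but
  is not the packaged default.

## Known limitations

- The LOO-based pipeline is O(n²·|grid|·fit) per component candidate; the
  closed-form inner loop makes K = 1 cheap, but deep component searches at
  p = 600 remain expensive by design of the validation scheme.
- Q² uses the full observed mean as baseline, exactly as defined here; a
  training-fold-mean baseline (the common alternative) gives slightly
  different values.
- The ROI model's standard errors assume homoscedastic Gaussian residuals;
  no robust variants are provided.
- The rank-biserial sign convention follows `1 − 2U/(n₁n₂)` with U the first
  group's statistic; other software may report the opposite sign.
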