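# Methods

## The statistical model

Each observation *i* is a paired comparison of a management practice
against conventional management at one site, summarised as an effect size
`y_i` with known sampling variance `v_i`. Three effect metrics are
implemented:

* **ROM** `ln(X_t/X_c)` with variance `s_t²/(n_t X_t²) + s_c²/(n_c X_c²)`,
  back-transformed to a relative change `(e^y − 1)·100 %`. Undefined for
  nonpositive group means; such rows are flagged at ingestion and excluded
  from ROM analyses only.
* **MD** `X_t − X_c` (NUEr percentage points) with variance
  `s_t²/n_t + s_c²/n_c`.
* **SMD** `(X_t − X_c)/SD_p` with the pooled within-group SD and variance
  `(n_t+n_c)/(n_t n_c) + SMD²/(2(n_t+n_c))`. The printed, uncorrected
  standardized difference is the default; the Hedges small-sample factor
  `1 − 3/(4(n_t+n_c−2)−1)` is available behind `hedges_correction=True`.

ROM and SMD results are converted to absolute NUEr changes with the
practice-group mean control NUEr (X̄_c) and mean pooled SD (SD̄_p)
respectively. The relative→absolute conversion treats the relative change
as a *fraction* of X̄_c (25 % at X̄_c = 32 gives 8 points); multiplying two
percentages literally would be dimensionally wrong, and the fraction
reading makes the conversion exactly consistent with the MD of the same
observation.

The meta-regression is

    y_i = x_i' β + u_i + e_i,   e_i ~ N(0, v_i),

with compound-symmetric random effects within studies: `Var(u_i) = τ²` and
`Corr(u_i, u_j) = ρ` for observations of the same study. The marginal
covariance `M = D + diag(v)` is block-diagonal by study. Variance
components maximize the restricted likelihood

    ll_REML = −½[(k−p) ln 2π + ln|M| + ln|X'M⁻¹X| + r'M⁻¹r],

β is the GLS solution at the optimum, and `cov(β) = (X'M⁻¹X)⁻¹`. (Software
that enables an `X'X` normalisation constant reports this likelihood plus
`½ ln|X'X|`; estimates are unaffected.)

## Estimation and numerical choices

* Optimization is over `(log τ², logit ρ)` with ρ restricted to [0, 1):
  negative within-study correlation of true effects has no substantive
  reading in study-clustered field data. Analytic gradients of both the ML
  and REML objectives are used (per-block traces and quadratic forms of
  the two compound-symmetry directions `(1−ρ)I + ρJ` and `τ²(J−I)`).
* A fixed, deterministic 5×5 start grid over (τ², ρ) is evaluated first;
  bounded quasi-Newton (L-BFGS-B, likelihood tolerance 1e-8, ≤500
  iterations) polishes the three best grid points. Fitting involves no
  randomness.
* Boundary handling: a τ̂² below 1e-10·mean(v) is snapped to exactly 0 and
  β refit there, so the τ²=0 constraint reproduces weighted least squares
  exactly; when the ρ optimum sits on the logit lower bound, ρ is fixed to
  exactly 0 and τ² re-profiled.
* Rows are internally sorted into a canonical order (study, then data
  values) before fitting, making estimates bit-identical under row
  permutation of the inputs.
* With one effect per study ρ is unidentifiable: it is reported as 0,
  flagged `rho_identifiable_ = False`, and dropped from the AIC parameter
  count.
* Likelihood-based comparison: REML likelihoods are not comparable across
  fixed-effects structures, so AIC is reported on both bases —
  `aic_ml_` (used for cross-moderator comparison and McFadden pseudo-R²,
  `1 − lnL_model/lnL_null` on ML values) and `aic_reml_` (traceable to
  REML-default software output). `q = p + 2` (β plus τ² and ρ), `p + 1`
  when ρ is unidentifiable.
* Moderator blocks are tested with Wald chi-square contrasts
  `β_s'(cov β_s)⁻¹β_s`; residual heterogeneity with
  `Q_E = Σ (y − Xβ_FE)²/v` at the fixed-effects (τ²=0) fit, chi-square
  with k−p df. p-values are upper-tail chi-square probabilities with no
  multiplicity adjustment.
* A pairwise correlation screen (|r| > 0.8, configurable) warns before
  fitting; exact rank deficiency aborts with the dependent columns named.

## Design matrix conventions

Practice indicators are treatment-coded against the conventional control
(a row with no modelled practice carries all zeros); crop is
treatment-coded against a reference crop (wheat by default); continuous
moderators (N rate, MAT, MAP, SOC, clay, pH) are centered and scaled to
unit sample variance. Centering is applied even though only unit variance
is strictly required: interaction terms are unstable without it and
coefficients remain back-transformable either way. The quadratic N-rate
term is squared on the raw scale first and then scaled as its own
variable. Interactions are elementwise products of the expanded columns,
in a deterministic column order.

The coefficient of variation behind SD imputation is pooled over all
reported (sd, mean) pairs from both arms by default — the largest sample
behind a single CV — with per-arm pooling available. Missing replicate
counts default to 3, the modal design of small agronomic trials. Missing
site covariates are not re-derived from coordinates; such rows are
rejected with a diagnostic so the artifact needs no external rasters.

## Upscaling

Predictions over a covariate grid use only the fixed effects: the ΔNUEr of
a scenario in a cell and crop is the contrast `(x_scen − x_base)'β`, its
standard error comes from `cov(β)` on the difference vector, and 95%
bounds use the 1.96 normal critical value (prediction intervals including
τ² are available behind a flag). A practice bundle is one design row with
several indicators set — its interactions then contribute jointly — not a
sum of separately predicted single-practice effects. Per-cell values are
crop-share-weighted over the crops grown in the cell (shares renormalized
over the modelled crops); cells growing none are skipped. Regional and
global summaries are cropland-area-weighted means renormalized over
available cells. Covariates outside the calibration range recorded at
scaling time trigger an extrapolation warning (clipping optional, off by
default). The MD metric is the recommended basis for upscaling — its scale
is NUEr percentage points — and a non-MD model triggers a warning.

## Synthetic data

The generator emulates the statistical structure the model assumes, not
any particular geography. Defaults describe a mid-sized synthesis and are
the conditions under which recovery is tested: 30 studies × 5 paired
observations; MD response; τ² = 4 (NUEr %)², ρ = 0.5; coefficients on
intercept, two practices (RFR, EE), crop, scaled N rate and SOC, and one
practice×SOC interaction; covariates uniform within the ranges of global
cereal trials (MAT −0.6–29 °C, MAP 45–2330 mm, SOC 2.7–80 g kg⁻¹, pH
4.5–8.5, clay 8.8–53 %); control NUEr uniform 20–60 %; group sampling SDs
uniform 3–8 NUEr % (CVs of roughly 0.1–0.25); replicates uniform on
{3,…,5}; 20 % of rows drop their SDs to exercise imputation. The N-rate
range, 30–350 kg N ha⁻¹, is the span typical of fertilized wheat, maize
and rice trials. The practice mix includes a class outside the default
model so that the design retains reference rows (a model containing every
practice present in the data plus an intercept is rank deficient).

Group means are drawn so the chosen metric equals the true effect plus
noise whose variance is exactly the analytic effect-size variance of the
emitted SDs and replicate counts. True coefficients are defined on a fixed
population scaling (the analytic mean and SD of each uniform covariate),
recorded in the emitted ground truth; recovery experiments reuse that
scaling so the coefficient truth is well defined, and run with fully
reported SDs so coverage tests the estimator rather than the imputation
heuristic. What passing recovery shows is that the estimator is calibrated
when the data match the model's assumptions; real compilations add
non-uniform covariates, correlated moderators, geographic clustering and
reporting biases that the generator does not emulate.

## Testing and problem sizes

The oracle for the REML optimizer is an exhaustive coarse-to-fine grid
search of an independently coded dense-matrix restricted likelihood,
searched over the full (τ², ρ ∈ [0, 0.999]) space; a second, external
cross-check fits the same data with metafor's `rma.mv` (nested
`~1|study/obs` random effects, which is the CS structure with
τ² = σ²₁+σ²₂, ρ = σ²₁/τ²). The Monte Carlo coverage experiment uses 2000
replicates of the default corpus — enough to shrink the binomial standard
error of a coverage proportion to ~0.5 % — and checks each coefficient's
95 % Wald interval coverage against the 93–97 % band and the mean τ̂²
against a 15 % bias bound. The acceptance script runs the same chain at
200 replicates and a 300-cell grid.

## Known limitations

* Only compound-symmetric random effects; no unstructured, heteroscedastic
  or autoregressive structures, and no robust (sandwich) variance
  estimators or publication-bias diagnostics.
* Wald intervals use normal critical values; with few studies they can be
  slightly liberal (no Knapp-Hartung-type adjustment).
* Cross-metric pooling of published estimates is refused rather than
  back-converted.
* Grid ingestion is tabular (CSV); raster extraction and map rendering are
  out of scope.
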