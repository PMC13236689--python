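# Methods

## The problem

Carbon accounting in bamboo plantations needs per-stem dry biomass for the
culm, the branches, the leaves and their total (aboveground biomass, AGB),
predicted from measurements that are cheap in the field — above all diameter
at breast height (DBH). When the three components and the total are each
fitted with their own allometric equation, the summed component predictions
do not equal the total prediction, which produces accounting gaps whenever
both levels must be reported. `culmfit` implements the standard remedy: a
compatible (additive) system of nonlinear equations estimated jointly by
seemingly unrelated regression (SUR), in which the total is *defined* as the
sum of the component equations.

## Dry-biomass derivation

Field data arrive as per-component total fresh weights plus oven-dried
subsamples. Component dry mass is the total fresh weight times the subsample
dry-to-fresh ratio. When a component has several subsamples (one per culm
third or crown layer), the ratio is pooled as Σdry/Σfresh — a mass-weighted
convention chosen over the mean of per-subsample ratios because it weights
each subsample by the material it represents and degenerates correctly to
the single-subsample case. AGB is the exact sum of the three component dry
masses; this identity is enforced at ingestion and carried through to the
model predictions.

## Independent power-law models

Each component and AGB can be modelled as y = a·x^b against a single
predictor x ∈ {DBH (cm), H (m), D²H (cm²·m)}. Residual spread grows roughly
linearly with stem size, so estimation uses weighted nonlinear least squares
with variance weights 1/x² (error sd ∝ x) on the original scale; no log
transform is used, avoiding retransformation bias. The optimiser is
Levenberg–Marquardt least squares with analytic Jacobians, seeded from a
log–log OLS fit plus four fixed multiplicative perturbations
(a×{1.5, 0.5}, b×{1.2, 0.8}); the start with the lowest weighted objective
wins, making the fit deterministic. Inner tolerances: `xtol=1e-10`,
`ftol=1e-12`, at most 1000 function evaluations per start.

Fit statistics (RMSE, adjusted R²) are reported on unweighted residuals in
kg so they are comparable across predictors and with field conventions.
Degenerate inputs are handled explicitly: constant y yields b ≈ 0 with an
undefined (NaN) adjusted R²; non-positive x or y is rejected.

### Predictor selection

Candidates are ranked by AICc. Because the fits minimise a weighted
criterion and the candidate predictors live on very different scales
(DBH ≈ 4, D²H ≈ 150), the selection AICc is computed from the full
likelihood of the heteroscedastic fitting model
y ~ N(a·x^b, σ²x²):

    AIC = 2k + n[ln(2π·SSEw/n) + 1] + 2Σ ln xᵢ,   AICc = AIC + 2k(k+1)/(n−k−1)

with SSEw the 1/x²-weighted residual sum of squares and k = 2 (a, b; the
error variance is not counted). The Σln xᵢ term is what makes the criterion
comparable across predictors; an unweighted-residual AICc contradicts the
estimation model, and a weighted-SSE AICc without that term mechanically
favours large-scale predictors. The generic reporting metrics
(`metrics.aic`/`metrics.aicc`) keep the plain least-squares form. Exact ties
break by the fixed order DBH < H < D²H. Each candidate also carries
bootstrap out-of-bag R²/RMSE/MAE for the final judgement.

### Confidence intervals

Parameter CIs are nonparametric case-resampling percentile intervals
(default B = 1000, 95%); replicate refits warm-start from the full-data
estimate, non-converged replicates are dropped and counted, and more than
20% failures marks the interval unreliable. In a 100-replicate simulation at
the default study conditions the interval for the culm exponent covers the
truth 95 times (nominal-range coverage; the acceptance suite recomputes
this).

## The compatible SUR system

The system estimates six parameters jointly:

    Bcu = a₁·DBH^b₁ + ε₁,  Bbr = a₂·DBH^b₂ + ε₂,  Ble = a₃·DBH^b₃ + ε₃,
    AGB ≡ a₁·DBH^b₁ + a₂·DBH^b₂ + a₃·DBH^b₃

by iterated feasible GLS:

1. **Seed** — independent weighted fits give starting values.
2. **Covariance** — residuals are scaled by 1/DBH (consistent with sd ∝ DBH)
   and the 3×3 cross-component covariance Σ̂ is estimated with denominator n
   (the ML convention; the denominator only rescales the objective and
   cannot move the optimum).
3. **Joint minimisation** — Σᵢ uᵢᵀΣ̂⁻¹uᵢ is minimised over all six
   parameters (whitened least squares with analytic Jacobians).

Stages 2–3 iterate until the maximum relative parameter change falls below
1e−8 or 50 cycles. If Σ̂ is numerically singular it is ridge-regularised
with λ = 1e−8·tr(Σ̂)/3 (a zero matrix — exactly noise-free data — falls
back to the identity, under which the already-attained optimum is
unchanged).

Only the three component equations enter Σ̂. Observed AGB is by
construction the exact sum of the observed components, so including a fourth
total equation would make the cross-equation covariance structurally
singular; deriving the total by summation realises direct total control
without a rank-deficient weight matrix. The payoff is exact additivity:
predicted AGB equals the component sum to machine precision at any diameter,
which the test suite checks at ≤1e−12 relative error over a 0.5–20 cm grid.
With Σ̂ fixed to the identity the joint criterion decouples into the three
independent weighted objectives — a reduction the tests verify to 1e−6 per
parameter.

System parameter CIs bootstrap the entire FGLS procedure (case resampling,
B = 1000, fixed seed).

## Bootstrap out-of-bag validation

Model families are compared by predictive rather than fitting performance:
B = 1000 resamples of size n with replacement; the family is refit on each
in-bag sample (the SUR family reruns all FGLS stages); the out-of-bag (OOB)
records — on average (1−1/n)ⁿ ≈ 36% of the data at n = 45 — are predicted;
R², RMSE, MAE and Bias% are computed on OOB observed-vs-predicted pairs and
aggregated as mean ± sd. Conventions the protocol fixes explicitly:

- OOB R² uses the OOB subset's own mean in the total sum of squares
  (standard out-of-sample R²).
- Iterations with fewer than 3 OOB records or zero OOB variance are skipped
  and counted, keeping B interpretable; >10% skips attaches a warning.
- One seeded generator drives everything, with per-iteration substreams
  derived from the iteration index, so increasing B never reshuffles earlier
  draws and identical seeds give byte-identical reports.
- Reported parameters always come from the full-data fit, never from
  bootstrap averages.

Bias% = (100/n)Σ(yᵢ−ŷᵢ)/yᵢ is retained without winsorising; it is
legitimately unstable for components with small observed masses (branches,
leaves), which is informative rather than a defect.

## Synthetic data generator

No raw culm dataset is distributed, so the generator produces samples with
the statistical structure the analysis assumes, calibrated to the published
study conditions:

- **Sample**: 45 culms, even mix of 2- and 3-year cohorts, assigned
  cyclically to three plots carrying slope 35°/25°/10° and
  semi-sunny/semi-shaded/semi-shaded aspects.
- **DBH**: truncated normals (lower bound 1.6 cm) with cohort means/sds
  6.23/1.03 and 3.09/0.91 cm.
- **Height**: H = c·DBH^d·exp(σ_h·z), σ_h = 0.08, with (c, d) ≈
  (2.00, 0.924) solved at run time from the two cohort (mean DBH, mean H)
  anchors — two equations, two unknowns; never hand-typed.
- **Biomass**: component dry mass = a_c·DBH^(b_c) + ε with the published
  compatible-system parameters as truth; ε is multivariate Gaussian with
  sd_c = s_c·DBH (the heteroscedasticity that motivates the 1/DBH² weights)
  and cross-component correlation 0.3 (a placeholder for the unknown field
  value, swept in tests). The slopes s_c are moment-matched at run time so
  that s_c·√E[DBH²] equals the published component RMSEs (0.498, 0.339,
  0.205 kg), with E[DBH²] taken over the truncated-normal mixture.
- **Floor**: component draws are truncated below at 0.01 kg to avoid
  non-physical values at small diameters — a generator artifact that
  slightly biases small-stem branch/leaf masses upward.
- **Back-fill**: per-component moisture content is drawn uniformly within
  the published observed ranges and fresh/subsample weights are derived from
  it, so generated tables round-trip through ingestion with AGB equal to the
  component sum exactly.

What the generator does *not* emulate: within-plot correlation, any real
dependence of growth on slope/aspect (the layout is bookkeeping only),
multi-year dynamics, measurement error in DBH/H, and multiplicative
(lognormal) biomass errors. Passing tests therefore demonstrate correctness
of the estimators under the assumed error model, not performance on real
field data. One consequence of the tight height link (σ_h = 0.08): H is
nearly as informative as DBH in synthetic data, so for the noisiest
component (branches, R² ≈ 0.5) the DBH-vs-H AICc ranking is within a few
units and seed-dependent, whereas culm, leaf and AGB select DBH decisively.

## Problem sizes used in the checks

The simulation-based checks run at the study scale (n = 45): 200 replicates
for parameter recovery (median exponents within 3% of truth, intercepts
within 10%), 100 replicates × B = 200 for CI coverage, and B = 1000 for the
OOB-fraction and validation summaries. The end-to-end pipeline tests use
smaller B so the suite stays quick; `scripts/acceptance.py` runs the full
B = 1000 validation.

## Known limitations

- The branch equation is intrinsically weak (R² ≈ 0.5 under the study
  conditions); additivity cannot repair a component's signal-to-noise.
- A single power law cannot represent a sum of three power laws exactly, so
  the separately fitted AGB model deviates from the component sum by up to a
  few percent even on noise-free data — this is precisely the discrepancy
  the compatible system eliminates.
- Percentile bootstrap CIs mildly undercover at n = 45; coverage is
  validated by simulation, not assumed.
- The generator's additive Gaussian error can produce draws near the 0.01 kg
  floor for small-diameter branches/leaves, inflating Bias% relative to a
  multiplicative-error world.
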