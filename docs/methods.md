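# Methods

## The model

Each image-derived phenotype (IDP) `y` — e.g. the mean cortical
thickness of one region, in mm — is modelled independently against
covariates `x = (age, sex, site)` in a healthy reference population.
A monotone warp `φ(·; γ)` makes residuals Gaussian in the transformed
space, and the warped observation follows a Bayesian linear model:

    φ(y_n) = wᵀ ϕ(x_n) + ε_n,   ε_n ~ N(0, σ²),   w ~ N(0, ω² I)

where `ϕ(x)` concatenates a cubic B-spline over age, linear covariates
(sex as 0/1), one-hot site dummies and an intercept.  The posterior
over weights is Gaussian with precision `A = σ⁻²ΦᵀΦ + ω⁻²I` and mean
`w̄ = σ⁻²A⁻¹Φᵀφ(y)`.  Hyper-parameters `(σ², ω², γ)` maximise the
warped marginal log-likelihood — the Gaussian evidence of `φ(y)` under
`N(0, σ²I + ω²ΦΦᵀ)` plus the Jacobian `Σ log φ′(y_n)`.

A subject's cross-sectional deviation is

    z = (φ(y) − w̄ᵀϕ(x)) / sqrt(ϕ(x)ᵀA⁻¹ϕ(x) + σ²),

standard normal in the reference population.

### The longitudinal change score

Cross-sectional centiles say nothing about how individuals move across
them.  The working assumption here is that a healthy subject's warped
residual decomposes as

    ε_i = η + ξ_i   (visit i),   η ~ N(0, σ_η²),  ξ_i iid N(0, σ_ξ²),

a subject-stable factor plus visit noise, with `σ² = σ_η² + σ_ξ²`:
healthy subjects approximately track their centile, and the observed
wobble is bounded by test-retest reliability.  The between-visit
difference then has variance `2σ_ξ²` plus model uncertainty, giving

    z-diff = ([φ(y⁽²⁾) − φ(y⁽¹⁾)] − w̄ᵀ[ϕ(x⁽²⁾) − ϕ(x⁽¹⁾)])
             / sqrt([Δϕ]ᵀA⁻¹[Δϕ] + 2σ_ξ²),

standard normal for healthy pairs.  For any stationary Gaussian
residual process the same formula holds with `2σ²(1 − ρ)` in place of
`2σ_ξ²`, where `ρ` is the lag correlation between the visits (the
η + ξ model is the special case `ρ = σ_η²/σ² ≥ 0`); an AR(1) process
with coefficient ζ gives `ρ = ζ^(T₂−T₁)`.  Only two visits are
supported; longer series should be scored as consecutive pairs.

The noise scale is estimated on a calibration subsample C of local
healthy-control pairs that is excluded from all evaluation:

    est = mean over C of [ (warped diff − expected diff)² − ΔϕᵀA⁻¹Δϕ ].

If this raw value exceeds the cross-sectional `2σ²`, the implied lag
correlation is negative and the centile-tracking assumption fails for
that IDP; the estimate carries a `tracking_violation` flag.  Finite-|C|
noise can push the raw value non-positive; it is then clamped to
`1e-8·2σ²` with a warning, and the raw value is always reported.  The
model-uncertainty term `ΔϕᵀA⁻¹Δϕ` is always kept in the denominator:
it is negligible for adult cohorts scored against large training sets
but grows in developmental or ageing ranges where `Δϕ` is not small.

Subtracting the two cross-sectional z-scores instead ("naive"
differencing) leaves null variance `2(1 − ρ)`: it over-flags healthy
subjects for `ρ < 0.5` (≈16.6% at ρ = 0 for θ = 0.05) and is blind to
change for `ρ → 1`.  It is implemented only as a comparison baseline.

### Site adaptation

A model pre-trained elsewhere has no dummy for a new scanner.
Adaptation computes standardized residuals of local healthy controls
under the site-agnostic basis `ϕ₀` (site block zeroed) and stores their
mean and SD; scoring at that site returns `(r − offset)/scale`.  The
pre-trained weights stay frozen and other sites are untouched.  Note
two consequences of the full one-hot + intercept design: the
intercept-minus-dummies direction is identified only by the prior, so
the `ϕ₀` predictive SD is `sqrt(σ² + ≈ω²/(S+1))`, and the stored offset
is therefore a warped-unit site shift divided by that SD.  Both
constants cancel in between-visit differences, which is why the
longitudinal path works even when adaptation is skipped.

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| `spline_degree`, interior knots | 3, 5 at age quantiles | — / years | boundary knots at training age min/max; out-of-range ages clamp to the boundary (logged) |
| warp family | `identity`; `sinh-arcsinh` optional | — | γ = (a, b): skew and tail weight; b > 0; standardization frozen at training mean/SD |
| `sigma2`, `omega2` | estimated | warped units² | L-BFGS-B in log-variance space, 5 seeded restarts, ftol 1e-6; σ² floored at 1e-8 |
| `theta` | 0.05 | — | two-sided standard-normal flagging thresholds |
| FDR level | 0.05 | — | Benjamini-Hochberg step-up across IDPs |
| `adapt_frac` / `calib_frac` | 0.4 / 0.3 | — | control split (remainder = evaluation controls), stratified by age tertile × sex, seeded |
| Euler threshold | 10 | — | subjects with a rescaled Euler number above it at either visit are removed entirely |
| `n_per_cell` | 10,000 | subjects | detection-rate grid; 1,000 is enough for smoke curves |
| visit interval | 1.1 | years | generator default, a typical clinical follow-up gap |

## The synthetic generator

`synthetic.CohortSpec` draws cohorts from the same observation model
the package fits: a smooth age/sex truth surface per IDP (degree-1
spline by default so hand checks stay feasible; a `lifespan` preset
adds cubic curvature), additive per-site offsets, and Gaussian
residuals — η + ξ pairs for longitudinal data, or a bivariate pair with
arbitrary lag correlation when `general_rho` is set.  Defaults: total
residual variance 1 split 0.9/0.1 (lag correlation 0.9, the level
implied by typical test-retest reliability of regional thickness),
uniform ages 18–65, balanced sexes.  Truth tables (η, ξ, ε, Δ per
subject) are emitted beside the data so tests never re-derive ground
truth.

What it deliberately does not emulate: spatial covariance between
regions, scanner drift within a study, non-Gaussian raw residuals
beyond what the warp family expresses, missing or unequal visit
intervals, and realistic mm-scale units (surfaces are in standardized
warped units).  Passing tests therefore demonstrate the statistical
machinery under its own assumptions, not robustness to real
acquisition artefacts.

## The simulation study

For each (Δ, ρ) cell, subjects get random covariates, residual pairs
from `N(0, σ²[[1, ρ], [ρ, 1]])`, and `+Δ` on the warped visit-2 value;
each is scored with z-diff (true noise scale `2σ²(1−ρ)`, isolating
score behaviour from estimator noise) and with naive differencing.
Neglecting the model term, both statistics are exactly Gaussian, so the
detection rate has a closed form used as an independent oracle.  The
reference model behind the grid is fitted on 20,000 synthetic subjects
with known σ² = ω² = 1, so its model-uncertainty term is negligible —
the regime of released pre-trained models.  Cell RNG streams are
derived from `(seed, Δ-key, ρ-key)`, so results are reproducible and
cell-parallelisable.

## Numerical choices

* `A⁻¹v` always via Cholesky (`solve_triangular`); `A⁻¹` is never
  formed; the model file stores the Cholesky factor.
* Evidence computed through the K×K precision (Woodbury), so cost is
  O(NK²) regardless of N.
* Degenerate inputs: empty design returns the prior; all-identical
  calibration pairs clamp the noise floor; duplicate adaptation
  controls (zero residual variance) are an error; θ = 1 flags everyone.
* Wilcoxon on all-zero score vectors returns p = 1 (no evidence of
  change) instead of erroring.
* All pipeline randomness derives from the single config seed; outputs
  carry no timestamps, making reruns byte-identical.

## Design choices where the design was open

* **Warp family**: two-parameter sinh-arcsinh composed with an affine
  standardization, plus the identity for exactly checkable algebra.
* **Site adaptation mechanism**: residual recentering/rescaling rather
  than posterior refitting with a new dummy column — the longitudinal
  use needs only correct differencing, and this keeps pre-trained
  weights frozen.
* **Control partitioning**: three disjoint sets (adaptation,
  calibration C, evaluation); C is never scored in any analysis.
* **Per-IDP independence**: one posterior per phenotype; no cross-IDP
  covariance is modelled.
* **Problem sizes**: 2,000 training subjects where hyper-parameters are
  estimated (recovery accuracy ~a few percent), 20,000 where the model
  plays the role of a pre-trained truth, 10,000 subjects per simulation
  cell (MC SE ≤ 0.5 percentage points on any rate).

## Known limitations

* Homoskedastic noise per IDP; no hierarchical site or subject models.
* The score quantifies change only, irrespective of initial position;
  joint position + change modelling is out of scope.
* With small |C| (tens of subjects) the noise estimate carries ~15–30%
  sampling error, which propagates into the variance of z-diff; the
  raw estimate and |C| are always reported so users can judge.
* Site adaptation assumes an additive site effect in warped space with
  at most a scale change; site-by-age interactions are not modelled.
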