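# Methods

## Model and fitting

The package works with the Poisson regression model y_i ~ Poisson(μ_i),
μ_i = exp(x_i′β), fit by Fisher scoring / IRLS:
β ← (X′ŴX)⁻¹ X′Ŵz with weights Ŵ = diag(μ̂) and working response
z_i = log μ̂_i + (y_i − μ̂_i)/μ̂_i.  Implementation choices:

* **Start values**: least-squares regression of log(y + 0.5) on the design
  (the +0.5 guards against log 0 on zero counts).
* **Convergence**: largest absolute coefficient change < 10⁻⁸ (the
  strictest common reading of "change between iterations"; deviance-based
  criteria declare convergence earlier on flat likelihoods).
* **Step-halving**: an IRLS step that would decrease the log-likelihood is
  halved, at most 10 times, before being accepted, so the accepted
  log-likelihood path is non-decreasing.  Non-convergence after
  `max_iterations` is an explicit error (or an explicit flag in the
  simulation loop) — never a silently returned iterate.
* **Residual scale**: σ̂² = Σ(y_i − μ̂_i)²/(n − p − 1) on the response scale
  (μ̂-based raw residuals).  This feeds the m_j = (σ̂²/α̂_j²)^{1/2}
  quantities in the ridge-parameter rules.
* **Canonical form**: X′ŴX = QΛQ′ with eigenvalues sorted descending and
  each eigenvector's first nonzero component made positive (reproducible
  tie-breaking); α̂ = Q′β̂.  A non-positive eigenvalue raises rather than
  silently regularizing.
* **Condition number**: λ_max/λ_min (the eigenvalue ratio, not its square
  root; values above ~30 on standardized designs are the usual alarm).
* **Standardization**: covariates are centered and scaled to unit column
  length (Σx² = 1), then an intercept column is appended; the per-column
  (center, scale) record supports mapping coefficients back to the raw
  scale.

## Estimators

All families are linear maps β̂ = H β̂_MLE built from S = X′ŴX and are
simultaneously diagonalized by Q, giving per-component shrinkage factors
h_j (see `estimators.canonical_factors`):

| family | h_j |
|---|---|
| MLE | 1 |
| PRE (ridge, k) | λ/(λ+k) |
| PLE (Liu, d) | (λ+d)/(λ+1) |
| PLTE (k, d) | (λ−d)/(λ+k) |
| PTPE (k, d) | (λ+kd)/(λ+k) |
| PHY (k, d) | λ(λ+d)/((λ+1)(λ+k)) |
| PSK (k, d) | λ(λ+k+d)/((λ+1)(λ+k)) |
| ILTE (k, f) | (λ+f(k))/(λ+k) · h\*_j |
| ILTE(PRE) | λ(λ+f(k))/(λ+k)² |
| PRTE (k, g) | λ(λ+g(k))/((λ+1)(λ+k)) |

The matrix path uses Cholesky solves of (S + cI); the canonical path uses
the h_j.  Both are exposed and tested against each other to 10⁻¹².
**The intercept is shrunk along with the slopes** — the matrix formulas act
on the full coefficient vector.  Some ridge traditions exempt the
intercept; this package does not, and the simulation design below removes
the question by fitting through the origin.

Admissibility: k ≥ 0 everywhere (k = 0 being the documented
reduction-to-MLE cases); 0 < d < 1 for PLE/PTPE/PHY, enforced as an error
for PTPE and as a warning for PLE/PHY (exploring outside the range is
legitimate in comparisons); d ∈ ℝ for PLTE/PSK.

## Risk

In canonical coordinates, with true canonical coefficients α,

* MMSE = Q [diag(h_j²/λ_j) + bb′] Q′, b_j = (h_j − 1)α_j;
* SMSE = tr(MMSE) = Σ h_j²/λ_j (asymptotic variance) + Σ (h_j−1)²α_j²
  (squared bias).

For ILTE/ILTE(PRE)/PRTE the scalar risk is additionally computed from the
explicit family-specific sums, and the trace identity against the general
h-form is a test invariant.  The derivative of the ridge-type risk in k is
implemented in closed form; its two factor-vanishing families of linear
rules g(k) — the integration-constant line g(k) = ck + (c−1)λ_j and the
component stationarity line with slope α_j²(λ_j+1)/(1+λ_jα_j²) — are the
basis of the g-rule catalogue.  (The two printed forms of the stationarity
line's intercept are algebraically identical; one is implemented.)

**Superiority check (ridge-type vs improved-Liu-type)**: for k > 0 the
difference MMSE(ILTE) − MMSE(PRTE), with the ILTE bias term dropped (a
conservative reduction), is Q diag(d_j) Q′ − bb′ with
d_j = (λ+f)²/(λ(λ+k)²) − λ(λ+g)²/((λ+1)²(λ+k)²).  It is pd iff diag(d) is
pd and the quadratic form b′diag(d)⁻¹b < 1.  The per-component interval
−λ − (λ+1)(λ+f)/λ < g < −λ + (λ+1)(λ+f)/λ is reported too, but note it
presumes λ + f(k) > 0: with f(k) < −λ_j the interval is empty while d_j can
still be positive (both terms are squares).  The pd test follows the
tolerance convention: a matrix is pd iff every eigenvalue of its
symmetrization exceeds 10⁻¹² (default).

## Biasing-parameter rules

All rules are pure functions of (λ, α̂, σ̂², n) and operate over **all**
canonical components (published statements of several rules index only
1..p, but the real-data k̂ values they print are reproduced only when the
leading factors count the full set of q = p+1 fitted coefficients; the
implementation follows the numbers).  With q = number of components:

* k̂ ridge (Kibria-type max rule): max_j |α̂_j|/σ̂, also used for PLTE I and
  PSK; spectrum-spread rules (λ₁ − 100λ_min)/99 (PLTE II) and the averaged
  PLTE III rule; ridge-type rules k̂ = (qλ_max − (q+1)λ_min)/n,
  qλ_max·α̂²_med/(n·α̂²_mean), q(λ_max − λ_min)/n,
  q·max(λ_jα̂_j²)/(n·α̂²_mean), plus the max-ratio and geometric-mean
  variants.  A rule that returns a non-positive k (possible for the
  spread rules on flat spectra) is floored at ε·λ_max with a warning,
  since all downstream formulas need k > 0.
* d̂ rules: the clipped Liu rule max(0, min((α̂_j²−1)/(1/λ_min + α̂²_max))),
  the ratio-of-sums Liu-type rule, the half-min rule
  ½·min λ_j/(1+λ_jα̂_j²), and the weighted PSK ratio.
* g(k)/f(k) constructors: g1(c) (needs c ∈ (0,1)), the four ridge-type
  lines (all with intercept (slope−1)·λ_min, so g(0) ≥ −λ_min whenever the
  slope is non-negative), the per-component stationarity line, the linear
  f for the MLE-based improved-Liu-type sweep and the quadratic
  f(k) = q₀(k+λ_min)² − (k+λ_min) for its ridge-based variant.
* Degenerate α̂_j = 0 components: m_j = +∞ (so 1/m_j = 0 drops out of max
  rules); the geometric-mean rule skips them with a warning.
* The Huang–Yang (K1,D1)/(K2,D2) selection methods are defined in an
  external reference and are **not shipped**; `register_phy_strategy`
  accepts a user-supplied `(inputs) -> (k, d)` callable, and the PHY
  estimator itself is available with any explicit (k, d).

## Monte Carlo design

`generate_design` draws x_ij = (1−ρ²)^{1/2} w_ij + ρ w_{i,p+1} with
standard-normal w, giving pairwise covariate correlation ρ².  Defaults are
the study conditions: n ∈ {50, 100, ...}, p ∈ {2, 4, 8, 12},
ρ ∈ {0.85, 0.9, 0.99, 0.999}, N = 2000 replications, columns centered and
scaled to unit length.  The true β is the unit-norm principal eigenvector
of X′X (first nonzero component positive); the intercept is identically
zero and **the scenario fits the model through the origin** (no intercept
column) by default.  Two deliberate choices deserve emphasis:

1. **Unit-length scaling** keeps the covariate spectrum O(1) regardless of
   n, which is what makes the EMSE essentially constant in n — the
   empirical signature this design reproduces.  Unscaled designs put the
   information eigenvalues on the n scale and change every spectrum-driven
   rule.  The scaling is toggleable (`standardize_design=False`).
2. **No intercept column** (`include_intercept=False`).  With a ones
   column, its information eigenvalue Σμ̂_i ≈ n dominates λ_max, the
   spread-based k̂ rules inflate by an order of magnitude, and the
   ridge-type estimators lose their advantage; fitting through the origin
   (the true intercept is exactly zero by construction) reproduces the
   published behaviour of every rule-driven estimator.  The
   estimated-intercept variant remains available via the toggle.

One design is drawn per scenario and held fixed; only the responses are
redrawn per replication (y_i ~ Poisson(exp(x_i′β))), each from its own
deterministic substream of the master seed, so a dropped replication does
not shift later draws.  Replications whose IRLS fit fails to converge (or
whose information matrix is numerically singular) are dropped and counted,
never imputed; a scenario with > 10% failures is flagged.  Biasing
parameters are re-estimated inside every replication.  The k-sweep mode
evaluates the ILTE / ILTE(PRE) / PRTE triplet with their prescribed
f/g rules on a grid k ∈ [0, 2] (step 0.1), sharing replications across k.

What the generator does *not* emulate: overdispersion, zero inflation,
covariate measurement error, non-normal covariate distributions, and
model misspecification.  Passing tests therefore certify the estimators'
behaviour under a correctly specified Poisson model with Gaussian
collinear covariates, not robustness beyond it.

## Bootstrap evaluation

`bootstrap_smse` case-resamples whole observations with replacement
(B = 10,000 by default), refits on every resample (rank-deficient or
non-convergent resamples are redrawn up to 20 times, then skipped and
counted; > 5% skips warn), and scores each estimator against the mean of
the bootstrap MLE estimates as the reference parameter:
SMSE = mean_b‖β̂_b − β_ref‖², with the variance part
mean_b‖β̂_b − β̄_b‖² reported separately (SMSE ≥ variance exactly).
Whether biasing parameters should be re-estimated per resample or frozen
at their full-data values is genuinely open; re-estimation is the default
(it reflects the whole pipeline's sampling variability) and freezing is a
config flag.

## Numerical conventions

* All pd solves via Cholesky of (S + cI); explicit inverses only for the
  exposed covariance and H matrices.
* pd tests: smallest eigenvalue of the symmetrized matrix > 10⁻¹².
* Linear predictors are clipped at ±700 inside IRLS purely to avoid
  floating overflow on divergent intermediate steps; step-halving rejects
  such steps anyway.
* Human-readable CLI tables print 4 decimals; JSON sidecars keep full
  precision.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` reproduce the Monte Carlo
comparison at (p = 2, n = 50) over 10–20 independent design realizations
with 500–2000 replications each, and the k-sweep at (n = 100, p = 4,
ρ = 0.99) with 300–500 replications per design — sizes chosen so the full
pipeline (designs, fits, rules, estimators, risk) is exercised end to end
while a complete run stays in the tens of seconds.  Published EMSE values
for these scenarios depend on the single unseeded design realization behind
each table row; medians over independent realizations reproduce the stable
cells to within ~±10–15% and the qualitative ordering (ridge-type rules
first) essentially always, while cells dominated by the realized smallest
eigenvalue (the MLE and barely-shrunk Liu-type cells at ρ ≥ 0.99) vary by
±50% and more across realizations and are not sharp reproduction targets.

## Known limitations

* No offsets/exposure, no dispersion modelling, no non-canonical links.
* Asymptotic (first-order) risk only; no exact finite-sample MSE.
* No jackknifed/almost-unbiased variants, no (stochastic-)restricted
  estimators, no cross-validated selection of k.
* The PSK d̂ rule follows its printed ratio formula; published real-data
  comparisons of PSK appear to use an unstated variant, so PSK comparisons
  should be read qualitatively.
* The aircraft-damage dataset used in the classic worked example is not
  shipped (externally sourced); the integration test for it activates only
  when the user supplies `tests/data/aircraft_damage.csv` with columns
  y, x1, x2, x3.
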