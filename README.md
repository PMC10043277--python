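# poisshrink

Shrinkage estimation for Poisson regression under multicollinearity.

## The problem

Count responses are routinely modelled by the Poisson regression model
y_i ~ Poisson(μ_i) with the canonical log link μ_i = exp(x_i′β), fit by
maximum likelihood through iteratively reweighted least squares (IRLS).
When the columns of the design matrix X are nearly linearly dependent, the
Fisher information X′ŴX (Ŵ = diag(μ̂)) has tiny eigenvalues, the
maximum-likelihood estimator (MLE) becomes wildly variable, and biased
shrinkage estimators trade a little bias for a large variance reduction.

`poisshrink` implements the family of such estimators built on the
information matrix S = X′ŴX — ridge (PRE), Liu (PLE), Liu-type (PLTE),
two-parameter (PTPE), the Huang–Yang-type (PHY) and
Sakallıoğlu–Kaçıranlar-type (PSK) combinations — together with the two
general one-rule classes that contain them:

* the improved Liu-type estimator
  **β̂_ILTE = (S + kI)⁻¹ (S + f(k)I) β\***, for any plug-in β\* and
  continuous rule f(k);
* the **Poisson ridge-type estimator (PRTE)**
  **β̂_PRTE = (S + I)⁻¹ (S + g(k)I) β̂_PRE(k)**, which shrinks the ridge
  estimator once more through a rule g(k).

With a linear rule g(k) = a·k + b the ridge-type class reduces to the MLE
(k = 0, b = 1), the ridge estimator (g ≡ 1), the Liu estimator (k = 0,
a = 0), the PHY estimator (a = 0) and the PSK estimator (a = 1).

The package provides, for audiences in biostatistics and epidemiological
count modelling:

* an IRLS Poisson GLM core exposing the canonical form (eigenvalues λ_j,
  canonical coefficients α̂_j = (Q′β̂)_j) and condition-number diagnostics;
* every estimator family above, as matrix formulas and as canonical
  shrinkage factors h_j with β̂ = Q diag(h) Q′ β̂_MLE;
* closed-form asymptotic risk: matrix mean squared error
  MMSE = Q[diag(h_j²/λ_j) + bb′]Q′ with b_j = (h_j − 1)α_j, scalar risk
  SMSE = tr(MMSE), the derivative of the ridge-type risk in k, and the
  superiority theorem comparing PRTE with ILTE through a
  positive-definiteness test (tolerance 10⁻¹²);
* a catalogue of data-driven biasing-parameter rules (k̂, d̂, and the
  g(k)/f(k) line constructors derived from the risk's stationarity
  conditions);
* a Monte Carlo engine for collinear designs
  x_ij = (1 − ρ²)^{1/2} w_ij + ρ w_{i,p+1} with estimated-MSE (EMSE)
  comparison over replications, and a k-sweep mode;
* a case-bootstrap SMSE evaluator for real datasets;
* a `poisshrink` command line (`fit`, `simulate`, `sweep`, `bootstrap`,
  `compare`, `fixture`).

## Worked example

A high-collinearity scenario (p = 2 covariates, n = 50, ρ = 0.99, so any two
covariates correlate at ρ² = 0.98), 2000 replications with responses redrawn
on a fixed design, true β the unit-norm principal eigenvector of X′X:

```sh
$ poisshrink simulate --n 50 --p 2 --rho 0.99 -N 2000 --seed 1
estimator    EMSE  rank
      MLE 34.8853    11
      PRE  0.5081     7
      PLE  0.4073     5
   PLTE I 16.1475     9
  PLTE II 16.2617    10
 PLTE III  0.7017     8
      PSK  0.4244     6
   PRTE I  0.3548     3
  PRTE II  0.3553     4
 PRTE III  0.3543     2
  PRTE IV  0.3516     1
```

The MLE's EMSE of 34.9 is the price of the near-singular information matrix:
on this design realization the fitted X′ŴX has eigenvalues ≈ (1.94, 0.027),
so the MLE's asymptotic variance along the weak direction alone is
1/0.027 ≈ 37.  Every shrinkage estimator improves on it by one
to two orders of magnitude, and the four ridge-type rules (PRTE I–IV), which
pick both k and the line g(k) from the fitted spectrum, occupy the top four
ranks — the qualitative finding the Monte Carlo harness is built to probe.

The same machinery runs on data from a file (`poisshrink fit data.csv -y y`
standardizes the covariates to unit column length, adds the intercept, and
prints each estimator's coefficients), and the library API mirrors the CLI:

```python
from poisshrink import (SimulationConfig, run_scenario)
res = run_scenario(SimulationConfig(n=50, p=2, rho=0.99, n_replications=2000, seed=1))
print(res.emse["MLE"], res.emse["PRTE IV"])   # 34.885... 0.3516...
```

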