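"""Poisson GLM core: IRLS fitting and the canonical quantities downstream code needs.

Everything in this package operates on a converged Poisson maximum-likelihood
fit: the Fisher information ``X'WX`` (with ``W = diag(mu_hat)``), its
eigendecomposition (the *canonical form*), the canonical coefficients
``alpha = Q' beta``, and the residual scale ``sigma2_hat``.  This module owns
those objects.

The model is the standard log-link Poisson regression

    y_i ~ Poisson(mu_i),   mu_i = exp(x_i' beta),

fit by iteratively reweighted least squares (Fisher scoring), with a
step-halving safeguard so the log-likelihood never decreases across accepted
iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import gammaln

__all__ = [
    "CountDataset",
    "PoissonFit",
    "CanonicalForm",
    "fit_poisson_mle",
    "canonical_decompose",
    "condition_number",
    "standardize",
    "NonConvergenceError",
]


class NonConvergenceError(RuntimeError):
    """IRLS failed to converge within the allotted iterations."""


@dataclass
class CountDataset:
    """A count-regression dataset: design matrix plus non-negative integer response.

    Parameters
    ----------
    design:
        ``n x (p+1)`` matrix; first column is the intercept column of ones when
        ``include_intercept`` is set.
    response:
        Length-``n`` vector of non-negative integer counts, or ``None`` for a
        design-only dataset (as produced by the simulation design generator
        before responses are drawn).
    standardized:
        True when every non-intercept column has been centered and scaled to
        unit length (sum of squares one).
    scaling_record:
        Per-column ``(center, scale)`` pairs applied during standardization,
        keyed by column name; empty for raw data.
    """

    design: np.ndarray
    response: np.ndarray | None = None
    include_intercept: bool = False
    standardized: bool = False
    column_names: list[str] = field(default_factory=list)
    scaling_record: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise ValueError("design must be a 2-D matrix")
        if self.response is not None:
            y = np.asarray(self.response)
            if y.shape != (self.design.shape[0],):
                raise ValueError("response length must match design rows")
            if np.any(y < 0) or not np.allclose(y, np.round(y)):
                raise ValueError("response entries must be non-negative integers")
            self.response = np.asarray(np.round(y), dtype=float)
        if not self.column_names:
            ncol = self.design.shape[1]
            names = [f"x{j}" for j in range(1, ncol + 1)]
            if self.include_intercept:
                names = ["intercept"] + names[:-1]
            self.column_names = names
        if self.standardized:
            cols = self.design[:, 1:] if self.include_intercept else self.design
            ss = np.sum(cols**2, axis=0)
            if cols.shape[1] and np.max(np.abs(ss - 1.0)) > 1e-8:
                raise ValueError("standardized flag set but columns are not unit-length")

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def p(self) -> int:
        """Number of covariates (excluding any intercept column)."""
        ncol = self.design.shape[1]
        return ncol - 1 if self.include_intercept else ncol

    def with_response(self, y: np.ndarray) -> "CountDataset":
        return replace(self, response=np.asarray(y, dtype=float))


@dataclass
class PoissonFit:
    """Converged IRLS state of a Poisson GLM."""

    beta_mle: np.ndarray
    mu_hat: np.ndarray
    weight_diag: np.ndarray
    working_response: np.ndarray
    xtwx: np.ndarray
    cov_mle: np.ndarray
    converged: bool
    iterations: int
    loglik: float
    sigma2_hat: float
    data: CountDataset | None = None

    def to_json_dict(self) -> dict:
        return {
            "coefficients": self.beta_mle.tolist(),
            "converged": self.converged,
            "iterations": self.iterations,
            "loglik": self.loglik,
            "sigma2_hat": self.sigma2_hat,
            "eigenvalues": np.sort(linalg.eigvalsh(self.xtwx))[::-1].tolist(),
            "condition_number": condition_number(self.xtwx),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_json_dict(), **kwargs)


@dataclass
class CanonicalForm:
    """Eigendecomposition of X'WX with canonical coefficients alpha = Q' beta_mle.

    Eigenvalues are sorted descending; each eigenvector's first nonzero entry
    is made positive so the decomposition is reproducible.  The scalar
    summaries (``lambda_min`` ... ``alpha2_mean``) are the quantities the
    biasing-parameter rules consume.
    """

    eigvals: np.ndarray
    eigvecs: np.ndarray
    alpha: np.ndarray

    @property
    def lambda_min(self) -> float:
        return float(self.eigvals[-1])

    @property
    def lambda_max(self) -> float:
        return float(self.eigvals[0])

    @property
    def alpha2(self) -> np.ndarray:
        return self.alpha**2

    @property
    def alpha2_min(self) -> float:
        return float(np.min(self.alpha2))

    @property
    def alpha2_max(self) -> float:
        return float(np.max(self.alpha2))

    @property
    def alpha2_med(self) -> float:
        return float(np.median(self.alpha2))

    @property
    def alpha2_mean(self) -> float:
        return float(np.mean(self.alpha2))


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Poisson log-likelihood sum(y*eta - exp(eta) - log(y!)).

    Overflow to -inf is deliberate: step-halving rejects such steps.
    """
    eta = X @ beta
    with np.errstate(over="ignore"):
        return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0)))


def _solve_weighted_ls(X: np.ndarray, w: np.ndarray, z: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    A = X.T @ Xw
    b = Xw.T @ z
    try:
        return linalg.solve(A, b, assume_a="pos")
    except linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_poisson_mle(
    data: CountDataset,
    tolerance: float = 1e-8,
    max_iterations: int = 100,
    on_failure: str = "raise",
) -> PoissonFit:
    """Fit the Poisson GLM by IRLS (Fisher scoring with the canonical log link).

    The iteration is ``beta <- (X'WX)^{-1} X'W z`` with weights
    ``W = diag(mu)`` and working response ``z_i = eta_i + (y_i - mu_i)/mu_i``.
    Starting values regress ``log(y + 0.5)`` on the design.  A step that would
    decrease the log-likelihood is halved (at most 10 times) before being
    accepted.  Convergence is declared when the largest absolute coefficient
    change falls below ``tolerance``.

    Parameters
    ----------
    on_failure:
        ``"raise"`` (default) raises :class:`NonConvergenceError` after
        ``max_iterations``; ``"return"`` returns the fit with
        ``converged=False`` so callers (e.g. the simulation loop) can count
        and drop it.
    """
    if data.response is None:
        raise ValueError("dataset has no response vector")
    X = data.design
    y = data.response
    n, ncol = X.shape
    if np.linalg.matrix_rank(X) < ncol:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if n <= ncol:
        raise ValueError(f"need n > p+1 (got n={n}, columns={ncol})")

    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    ll = poisson_loglik(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        mu = np.maximum(mu, 1e-300)
        z = eta + (y - mu) / mu
        beta_new = _solve_weighted_ls(X, mu, z)
        step = beta_new - beta
        # step-halving: accept only likelihood-non-decreasing updates
        scale = 1.0
        for _ in range(10):
            ll_new = poisson_loglik(beta + scale * step, X, y)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * (1 + abs(ll)):
                break
            scale *= 0.5
        beta_new = beta + scale * step
        ll = poisson_loglik(beta_new, X, y)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tolerance:
            converged = True
            break

    if not converged and on_failure == "raise":
        raise NonConvergenceError(
            f"IRLS did not converge in {max_iterations} iterations"
        )

    eta = X @ beta
    mu = np.exp(np.clip(eta, -700, 700))
    z = eta + (y - mu) / np.maximum(mu, 1e-300)
    xtwx = X.T @ (X * mu[:, None])
    try:
        cov = linalg.inv(xtwx)
    except linalg.LinAlgError:
        cov = np.linalg.pinv(xtwx)
    dof = n - ncol  # n - p - 1 with an intercept among the columns
    with np.errstate(over="ignore"):
        sigma2 = float(np.sum((y - mu) ** 2) / dof)
    return PoissonFit(
        beta_mle=beta,
        mu_hat=mu,
        weight_diag=mu,
        working_response=z,
        xtwx=xtwx,
        cov_mle=cov,
        converged=converged,
        iterations=it,
        loglik=ll,
        sigma2_hat=sigma2,
        data=data,
    )


def _fix_eigvec_signs(Q: np.ndarray) -> np.ndarray:
    Q = Q.copy()
    for j in range(Q.shape[1]):
        col = Q[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            Q[:, j] = -col
    return Q


def canonical_decompose(fit: PoissonFit) -> CanonicalForm:
    """Eigendecompose X'WX (descending eigenvalues) and rotate beta_mle.

    Raises ``LinAlgError`` if the information matrix is not numerically
    positive definite.
    """
    vals, vecs = linalg.eigh(fit.xtwx)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = _fix_eigvec_signs(vecs[:, order])
    if vals[-1] <= 0:
        raise np.linalg.LinAlgError(
            f"X'WX is not positive definite (min eigenvalue {vals[-1]:.3e})"
        )
    alpha = vecs.T @ fit.beta_mle
    return CanonicalForm(eigvals=vals, eigvecs=vecs, alpha=alpha)


def condition_number(matrix: np.ndarray) -> float:
    """lambda_max / lambda_min of a symmetric positive-definite matrix.

    The eigenvalue-ratio convention (not its square root) is used; values
    above ~30 are the usual multicollinearity alarm for standardized designs.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    vals = linalg.eigvalsh(matrix)
    if vals[0] <= 0:
        raise ValueError("matrix must be positive definite")
    return float(vals[-1] / vals[0])


def standardize(data: CountDataset) -> CountDataset:
    """Center each covariate and scale it to unit column length; add intercept.

    The returned dataset records the per-column ``(center, scale)`` pair so
    standardized-scale coefficients can be mapped back to the raw scale:
    ``beta_raw_j = beta_std_j / scale_j`` and
    ``beta_raw_0 = beta_std_0 - sum_j beta_std_j * center_j / scale_j``.
    """
    if data.include_intercept:
        raise ValueError("dataset already has an intercept column; standardize raw data")
    X = data.design
    centers = X.mean(axis=0)
    centered = X - centers
    scales = np.sqrt(np.sum(centered**2, axis=0))
    for j, s in enumerate(scales):
        if s < 1e-12:
            raise ValueError(f"column {data.column_names[j]!r} has zero variance")
    std = centered / scales
    design = np.column_stack([np.ones(data.n), std])
    record = {
        name: (float(c), float(s))
        for name, c, s in zip(data.column_names, centers, scales)
    }
    return CountDataset(
        design=design,
        response=None if data.response is None else data.response.copy(),
        include_intercept=True,
        standardized=True,
        column_names=["intercept"] + list(data.column_names),
        scaling_record=record,
    )


def destandardize_coefficients(beta_std: np.ndarray, dataset: CountDataset) -> np.ndarray:
    """Map coefficients fit on a standardized design back to the raw scale."""
    if not dataset.standardized or not dataset.include_intercept:
        raise ValueError("dataset is not a standardized+intercept dataset")
    names = dataset.column_names[1:]
    centers = np.array([dataset.scaling_record[nm][0] for nm in names])
    scales = np.array([dataset.scaling_record[nm][1] for nm in names])
    slopes = beta_std[1:] / scales
    intercept = beta_std[0] - np.sum(slopes * centers)
    return np.concatenate([[intercept], slopes])
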