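"""Asymptotic risk of the shrinkage families and the superiority machinery.

All estimators here are linear maps ``beta_hat = H beta_hat_MLE`` that are
diagonalized by the eigenvectors Q of the information matrix, so the risk is
computed in canonical coordinates.  With eigenvalues ``lambda_j``, shrinkage
factors ``h_j`` (see :func:`poisshrink.estimators.canonical_factors`) and true
canonical coefficients ``alpha_j``:

    MMSE  = Q [ diag(h_j^2 / lambda_j) + b b' ] Q',   b_j = (h_j - 1) alpha_j
    SMSE  = trace(MMSE) = sum_j h_j^2 / lambda_j  +  sum_j (h_j - 1)^2 alpha_j^2

i.e. an asymptotic variance part plus a squared-bias part.  For the
ridge-type family (g(k)-rule on top of the ridge estimator), the scalar risk
as a function of k is

    h(k) = sum_j lambda_j (lambda_j + g)^2 / ((lambda_j+1)^2 (lambda_j+k)^2)
         + sum_j ((g - k - 1) lambda_j - k)^2 alpha_j^2
           / ((lambda_j+1)^2 (lambda_j+k)^2),

whose derivative in k factors into a g-side and a bias-side term; each of the
two stationarity families of g-lines kills one factor (see the biasing
module).

The superiority theorem compares the ridge-type family against the general
improved-Liu-type family: for k > 0, if g(k) lies in the spectral interval

    -lambda_j - (lambda_j+1)(lambda_j+f(k))/lambda_j  <  g(k)
    <  -lambda_j + (lambda_j+1)(lambda_j+f(k))/lambda_j      for every j,

then the variance-difference matrix D is positive definite and the MMSE
difference (variance difference minus the ridge-type bias outer product) is
positive definite iff the quadratic form ``bias' D^-1 bias < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .estimators import GkRule, ShrinkageSpec, canonical_factors
from .glm_core import CanonicalForm

__all__ = [
    "RiskReport",
    "TheoremReport",
    "is_pd",
    "mmse_matrix",
    "smse",
    "smse_parts",
    "smse_derivative",
    "superiority_check",
    "smse_sweep_table",
]


def is_pd(matrix: np.ndarray, tolerance: float = 1e-12) -> bool:
    """Positive-definiteness test: every eigenvalue of the symmetrized matrix
    must exceed ``tolerance`` (an eigenvalue <= tolerance fails the test)."""
    M = np.asarray(matrix, dtype=float)
    M = 0.5 * (M + M.T)
    return bool(np.min(linalg.eigvalsh(M)) > tolerance)


@dataclass
class RiskReport:
    """Asymptotic risk of one estimator at a given truth."""

    estimator: ShrinkageSpec
    mmse: np.ndarray
    smse: float
    variance_part: float
    bias_sq_part: float
    bias_vector: np.ndarray
    canonical: bool  # True if mmse/bias are left in canonical coordinates

    def to_json_dict(self) -> dict:
        return {
            "family": self.estimator.family,
            "k": self.estimator.k,
            "d": self.estimator.d,
            "smse": self.smse,
            "variance_part": self.variance_part,
            "bias_sq_part": self.bias_sq_part,
            "bias_vector": self.bias_vector.tolist(),
            "mmse": self.mmse.tolist(),
        }


def _canonical_risk(spec: ShrinkageSpec, lam: np.ndarray, alpha: np.ndarray):
    h = canonical_factors(spec, lam)
    var = h**2 / lam
    bias = (h - 1.0) * alpha
    return h, var, bias


def mmse_matrix(
    spec: ShrinkageSpec,
    canon: CanonicalForm,
    truth: np.ndarray,
    rotate: bool = True,
) -> RiskReport:
    """Asymptotic matrix MSE of a shrinkage family at true canonical
    coefficients ``truth`` (the alpha vector; a plug-in estimate is fine).

    With ``rotate=True`` (default) the matrix and bias vector are returned in
    the original coordinate system (similarity transform by Q); otherwise in
    canonical coordinates.
    """
    alpha = np.asarray(truth, dtype=float)
    lam = canon.eigvals
    if alpha.shape != lam.shape:
        raise ValueError(
            f"truth has shape {alpha.shape}, expected {lam.shape}"
        )
    _, var, bias = _canonical_risk(spec, lam, alpha)
    M = np.diag(var) + np.outer(bias, bias)
    b = bias
    if rotate:
        Q = canon.eigvecs
        M = Q @ M @ Q.T
        b = Q @ bias
    return RiskReport(
        estimator=spec,
        mmse=M,
        smse=float(np.sum(var) + np.sum(bias**2)),
        variance_part=float(np.sum(var)),
        bias_sq_part=float(np.sum(bias**2)),
        bias_vector=b,
        canonical=not rotate,
    )


def smse_parts(spec: ShrinkageSpec, canon: CanonicalForm, truth: np.ndarray) -> tuple[float, float]:
    """(variance, squared bias) of the scalar risk, via the family-matched
    closed-form sums."""
    alpha = np.asarray(truth, dtype=float)
    lam = canon.eigvals
    k = spec.k
    if spec.family == "ILTE" and (spec.base is None or spec.base.family == "MLE"):
        f = float(spec.rule(k))
        var = np.sum((lam + f) ** 2 / (lam * (lam + k) ** 2))
        bias2 = np.sum((f - k) ** 2 * alpha**2 / (lam + k) ** 2)
    elif spec.family == "ILTE_PRE":
        f = float(spec.rule(k))
        var = np.sum((lam + f) ** 2 * lam / (lam + k) ** 4)
        bias2 = np.sum((f * lam - 2 * k * lam - k**2) ** 2 * alpha**2 / (lam + k) ** 4)
    elif spec.family == "PRTE":
        g = float(spec.rule(k))
        den = (lam + 1.0) ** 2 * (lam + k) ** 2
        var = np.sum(lam * (lam + g) ** 2 / den)
        bias2 = np.sum(((g - k - 1.0) * lam - k) ** 2 * alpha**2 / den)
    else:
        _, var_j, bias_j = _canonical_risk(spec, lam, alpha)
        var = np.sum(var_j)
        bias2 = np.sum(bias_j**2)
    return float(var), float(bias2)


def smse(spec: ShrinkageSpec, canon: CanonicalForm, truth: np.ndarray) -> float:
    """Scalar asymptotic MSE (equals trace of :func:`mmse_matrix`)."""
    var, bias2 = smse_parts(spec, canon, truth)
    return var + bias2


def smse_derivative(
    g_rule: GkRule, canon: CanonicalForm, truth: np.ndarray, k: float
) -> float:
    """d/dk of the ridge-type scalar risk h(k), in closed form:

        h'(k) = sum_j 2 lambda_j (lambda_j - g' lambda_j - g' k + g)
                * [alpha_j^2 ((k + 1 - g) lambda_j + k) - (lambda_j + g)]
                / ((lambda_j + 1)^2 (lambda_j + k)^3)
    """
    lam = canon.eigvals
    alpha = np.asarray(truth, dtype=float)
    g = float(g_rule(k))
    gp = float(g_rule.derivative(k))
    num = (
        2.0
        * lam
        * (lam - gp * lam - gp * k + g)
        * (alpha**2 * ((k + 1.0 - g) * lam + k) - (lam + g))
    )
    return float(np.sum(num / ((lam + 1.0) ** 2 * (lam + k) ** 3)))


@dataclass
class TheoremReport:
    """Outcome of the ridge-type vs improved-Liu-type superiority check at one k."""

    k: float
    f_rule: GkRule
    g_rule: GkRule
    interval_ok: bool
    d_matrix_pd: bool
    quadratic_form_value: float | None
    quadratic_form_ok: bool | None
    mmse_difference_pd: bool
    tolerance: float

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "interval_ok": self.interval_ok,
            "d_matrix_pd": self.d_matrix_pd,
            "quadratic_form_value": self.quadratic_form_value,
            "quadratic_form_ok": self.quadratic_form_ok,
            "mmse_difference_pd": self.mmse_difference_pd,
            "tolerance": self.tolerance,
        }


def superiority_check(
    f_rule: GkRule,
    g_rule: GkRule,
    canon: CanonicalForm,
    truth: np.ndarray,
    k: float,
    tolerance: float = 1e-12,
) -> TheoremReport:
    """Check superiority of the ridge-type estimator over the improved
    Liu-type estimator at biasing parameter ``k``.

    Evaluates (i) the per-component g(k) interval, (ii) positive definiteness
    of the variance-difference matrix D, (iii) the quadratic-form condition
    ``bias' D^-1 bias < 1``, and (iv) the direct eigenvalue check of the MMSE
    difference ``D - bias bias'`` (all in canonical coordinates; eigenvalues
    are invariant to the rotation by Q).
    """
    if k <= 0:
        raise ValueError("the superiority comparison requires k > 0")
    lam = canon.eigvals
    alpha = np.asarray(truth, dtype=float)
    f = float(f_rule(k))
    g = float(g_rule(k))

    # The printed per-component interval for g(k) presumes lam_j + f(k) > 0;
    # the operative pd condition on the variance-difference matrix D is
    # (lam+1)^2 (lam+f)^2 - lam^2 (lam+g)^2 > 0, which the interval implies.
    half_width = (lam + 1.0) * (lam + f) / lam
    interval_ok = bool(np.all((-lam - half_width < g) & (g < -lam + half_width)))

    d_diag = (lam + f) ** 2 / (lam * (lam + k) ** 2) - lam * (lam + g) ** 2 / (
        (lam + 1.0) ** 2 * (lam + k) ** 2
    )
    d_matrix_pd = bool(np.all(d_diag > tolerance))

    bias = ((g - k - 1.0) * lam - k) * alpha / ((lam + 1.0) * (lam + k))

    if d_matrix_pd:
        quadratic_form_value = float(np.sum(bias**2 / d_diag))
        quadratic_form_ok = quadratic_form_value < 1.0
    else:
        quadratic_form_value = None  # D singular/indefinite: quadratic form indeterminate
        quadratic_form_ok = None

    diff = np.diag(d_diag) - np.outer(bias, bias)
    mmse_difference_pd = is_pd(diff, tolerance)

    return TheoremReport(
        k=k,
        f_rule=f_rule,
        g_rule=g_rule,
        interval_ok=interval_ok,
        d_matrix_pd=d_matrix_pd,
        quadratic_form_value=quadratic_form_value,
        quadratic_form_ok=quadratic_form_ok,
        mmse_difference_pd=mmse_difference_pd,
        tolerance=tolerance,
    )


def smse_sweep_table(
    canon: CanonicalForm,
    truth: np.ndarray,
    k_grid: np.ndarray,
    f_rule_ilte: GkRule,
    f_rule_ilte_pre: GkRule,
    g_rule: GkRule,
) -> pd.DataFrame:
    """SMSE and variance of the improved-Liu-type pair and the ridge-type
    estimator over a k grid (the data behind variance/SMSE-vs-k curves)."""
    rows = []
    for k in np.asarray(k_grid, dtype=float):
        specs = {
            "ILTE": ShrinkageSpec("ILTE", k=k, rule=f_rule_ilte),
            "ILTE_PRE": ShrinkageSpec("ILTE_PRE", k=k, rule=f_rule_ilte_pre),
            "PRTE": ShrinkageSpec("PRTE", k=k, rule=g_rule),
        }
        row: dict[str, float] = {"k": k}
        for name, spec in specs.items():
            var, bias2 = smse_parts(spec, canon, truth)
            row[f"var_{name}"] = var
            row[f"smse_{name}"] = var + bias2
        rows.append(row)
    return pd.DataFrame(rows)
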