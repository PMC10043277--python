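"""Shrinkage estimator families for the Poisson GLM.

Every estimator here is a linear map of the maximum-likelihood estimate,
``beta_hat = H beta_hat_MLE``, built from the Fisher information
``S = X'WX``.  With ``k >= 0`` and ``d`` the biasing parameters and ``f(k)``,
``g(k)`` continuous rule functions, the families are

=========  ================================================================
MLE        beta_hat
PRE        (S + kI)^-1 S beta_hat                              (ridge)
PLE        (S + I)^-1 (S + dI) beta_hat                        (Liu)
PLTE       (S + kI)^-1 (S - dI) beta_hat                       (Liu-type)
PTPE       (S + kI)^-1 (S + kdI) beta_hat                      (two-parameter)
PHY        (S + I)^-1 (S + dI) (S + kI)^-1 S beta_hat
PSK        (S + I)^-1 (S + (k+d)I) beta_PRE(k)
ILTE       (S + kI)^-1 (S + f(k)I) beta*          (beta* = MLE by default)
ILTE_PRE   ILTE with beta* = beta_PRE(k)
PRTE       (S + I)^-1 (S + g(k)I) beta_PRE(k)                  (ridge-type)
=========  ================================================================

The ridge-type family (PRTE) contains the others as special cases of the
linear rule ``g(k) = a k + b``: ``g == 1`` gives PRE, ``k = 0, g(0) = 1``
gives MLE, ``a = 0`` gives PHY with ``d = b`` (and PLE at ``k = 0``), and
``a = 1`` gives PSK with ``d = b``.

Since all maps are rational functions of ``S`` they are simultaneously
diagonalized by its eigenvectors; :func:`canonical_factors` returns the
per-eigencomponent shrinkage multipliers ``h_j`` with
``alpha_hat_j -> h_j alpha_hat_j``, which is the representation the risk
module works in.

Note: the intercept is shrunk along with the slopes — the matrix formulas act
on the full (p+1)-vector (some ridge traditions exempt the intercept; this
package does not).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg

from .glm_core import CanonicalForm, PoissonFit, canonical_decompose

__all__ = [
    "FAMILIES",
    "GkRule",
    "ShrinkageSpec",
    "apply_shrinkage",
    "canonical_factors",
    "induced_map",
    "ilte",
    "prte",
]

FAMILIES = (
    "MLE",
    "PRE",
    "PLE",
    "PLTE",
    "PTPE",
    "PHY",
    "PSK",
    "ILTE",
    "ILTE_PRE",
    "PRTE",
)


@dataclass(frozen=True)
class GkRule:
    """A rule function f(k) or g(k) of the biasing parameter.

    ``form='linear'`` evaluates ``a*k + b``; ``form='custom'`` delegates to
    ``func`` (with ``deriv`` its derivative, required by the risk
    derivative machinery).  ``c`` records the integration constant of the
    first-family line ``g(k) = c*k + (c-1)*lambda_j`` when that is how the
    rule was built.
    """

    form: str = "linear"
    a: float = 0.0
    b: float = 1.0
    c: float | None = None
    provenance: str = "user"
    func: Callable[[float], float] | None = None
    deriv: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "custom"):
            raise ValueError(f"unknown rule form {self.form!r}")
        if self.form == "custom" and self.func is None:
            raise ValueError("custom rule requires func")
        if self.provenance == "g1" and not (self.c is not None and 0 < self.c < 1):
            raise ValueError("rule g1 requires integration constant c in (0, 1)")

    def __call__(self, k: float):
        if self.form == "linear":
            return self.a * np.asarray(k, dtype=float) + self.b
        return self.func(k)

    def derivative(self, k: float):
        if self.form == "linear":
            return self.a * np.ones_like(np.asarray(k, dtype=float))
        if self.deriv is None:
            raise ValueError("custom rule has no derivative")
        return self.deriv(k)

    @classmethod
    def constant(cls, value: float, provenance: str = "user") -> "GkRule":
        return cls(form="linear", a=0.0, b=float(value), provenance=provenance)

    @classmethod
    def linear(cls, a: float, b: float, provenance: str = "user", c: float | None = None) -> "GkRule":
        return cls(form="linear", a=float(a), b=float(b), provenance=provenance, c=c)


@dataclass(frozen=True)
class ShrinkageSpec:
    """Which estimator family to apply, with its biasing parameters.

    ``rule`` supplies f(k) for ILTE/ILTE_PRE or g(k) for PRTE.  ``base``
    optionally nests another spec as the plug-in estimator beta* of the
    general improved-Liu-type family (MLE when omitted; ILTE_PRE fixes it to
    PRE with the same k).
    """

    family: str
    k: float = 0.0
    d: float = 0.0
    rule: GkRule | None = None
    base: "ShrinkageSpec | None" = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.k < 0:
            raise ValueError("biasing parameter k must be >= 0")
        if self.family in ("PRE", "PLTE", "PTPE", "PHY", "PSK", "ILTE", "ILTE_PRE") and self.k == 0:
            # k = 0 is the documented reduction-to-MLE case, allowed silently
            pass
        if self.family == "PTPE" and not (0 <= self.d <= 1):
            raise ValueError("PTPE requires 0 < d < 1 (endpoints only as reductions)")
        if self.family in ("PLE", "PHY") and not (0 <= self.d <= 1):
            warnings.warn(
                f"{self.family} admissible range is 0 < d < 1; got d={self.d}",
                stacklevel=2,
            )
        if self.family in ("ILTE", "ILTE_PRE", "PRTE") and self.rule is None:
            raise ValueError(f"{self.family} requires a rule supplying f(k)/g(k)")


def canonical_factors(spec: ShrinkageSpec, eigvals: np.ndarray) -> np.ndarray:
    """Per-eigencomponent shrinkage multipliers h_j of the induced map.

    In canonical coordinates every family acts as
    ``alpha_hat -> diag(h) alpha_hat``; this is the single source of truth
    the matrix path (:func:`apply_shrinkage`) is tested against.
    """
    lam = np.asarray(eigvals, dtype=float)
    k, d = spec.k, spec.d
    fam = spec.family
    if fam == "MLE":
        return np.ones_like(lam)
    if fam == "PRE":
        return lam / (lam + k)
    if fam == "PLE":
        return (lam + d) / (lam + 1.0)
    if fam == "PLTE":
        return (lam - d) / (lam + k)
    if fam == "PTPE":
        return (lam + k * d) / (lam + k)
    if fam == "PHY":
        return (lam + d) * lam / ((lam + 1.0) * (lam + k))
    if fam == "PSK":
        return (lam + k + d) * lam / ((lam + 1.0) * (lam + k))
    if fam == "ILTE":
        f = float(spec.rule(k))
        base = spec.base or ShrinkageSpec("MLE")
        return (lam + f) / (lam + k) * canonical_factors(base, lam)
    if fam == "ILTE_PRE":
        f = float(spec.rule(k))
        return (lam + f) * lam / (lam + k) ** 2
    if fam == "PRTE":
        g = float(spec.rule(k))
        return (lam + g) * lam / ((lam + 1.0) * (lam + k))
    raise AssertionError(fam)


def induced_map(spec: ShrinkageSpec, fit: PoissonFit, canon: CanonicalForm | None = None) -> np.ndarray:
    """The matrix H with beta_hat_family = H beta_hat_MLE."""
    canon = canon or canonical_decompose(fit)
    h = canonical_factors(spec, canon.eigvals)
    return (canon.eigvecs * h) @ canon.eigvecs.T


def _solve_pd(S: np.ndarray, shift: float, rhs: np.ndarray) -> np.ndarray:
    """(S + shift*I)^-1 rhs through a symmetric-pd factorization."""
    A = S + shift * np.eye(S.shape[0])
    c, low = linalg.cho_factor(A)
    return linalg.cho_solve((c, low), rhs)


def apply_shrinkage(spec: ShrinkageSpec, fit: PoissonFit) -> np.ndarray:
    """Apply the family's matrix formula to the fitted MLE coefficients.

    All linear systems go through Cholesky factorizations of
    ``(X'WX + cI)``; no explicit inverse is formed.
    """
    S = fit.xtwx
    beta = fit.beta_mle
    k, d = spec.k, spec.d
    fam = spec.family
    if fam == "MLE":
        return beta.copy()
    if fam == "PRE":
        return _solve_pd(S, k, S @ beta)
    if fam == "PLE":
        return _solve_pd(S, 1.0, S @ beta + d * beta)
    if fam == "PLTE":
        return _solve_pd(S, k, S @ beta - d * beta)
    if fam == "PTPE":
        return _solve_pd(S, k, S @ beta + k * d * beta)
    if fam == "PHY":
        inner = _solve_pd(S, k, S @ beta)
        return _solve_pd(S, 1.0, S @ inner + d * inner)
    if fam == "PSK":
        pre = _solve_pd(S, k, S @ beta)
        return _solve_pd(S, 1.0, S @ pre + (k + d) * pre)
    if fam in ("ILTE", "ILTE_PRE"):
        return ilte(spec, fit)
    if fam == "PRTE":
        return prte(spec, fit)
    raise AssertionError(fam)


def ilte(spec: ShrinkageSpec, fit: PoissonFit) -> np.ndarray:
    """General improved Liu-type estimator (S+kI)^-1 (S+f(k)I) beta*.

    ``beta*`` is the plug-in given by ``spec.base`` (MLE when absent);
    ``ILTE_PRE`` fixes it to the ridge estimator with the same k.
    """
    if spec.family not in ("ILTE", "ILTE_PRE"):
        raise ValueError("spec.family must be ILTE or ILTE_PRE")
    if spec.rule is None:
        raise ValueError("ILTE requires a rule supplying f(k)")
    S = fit.xtwx
    k = spec.k
    f = float(spec.rule(k))
    if spec.family == "ILTE_PRE":
        base = ShrinkageSpec("PRE", k=k)
    else:
        base = spec.base or ShrinkageSpec("MLE")
    beta_star = apply_shrinkage(base, fit)
    return _solve_pd(S, k, S @ beta_star + f * beta_star)


def prte(spec: ShrinkageSpec, fit: PoissonFit) -> np.ndarray:
    """Ridge-type estimator (S+I)^-1 (S+g(k)I) beta_PRE(k)."""
    if spec.family != "PRTE":
        raise ValueError("spec.family must be PRTE")
    if spec.rule is None:
        raise ValueError("PRTE requires a rule supplying g(k)")
    S = fit.xtwx
    k = spec.k
    g = float(spec.rule(k))
    pre = _solve_pd(S, k, S @ fit.beta_mle)
    return _solve_pd(S, 1.0, S @ pre + g * pre)
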