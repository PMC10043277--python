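"""Shared fixtures: small deterministic datasets and synthetic fit objects."""

from __future__ import annotations

import numpy as np
import pytest

from poisshrink.glm_core import CanonicalForm, CountDataset, PoissonFit, canonical_decompose, fit_poisson_mle


def make_synthetic_fit(xtwx: np.ndarray, beta: np.ndarray) -> PoissonFit:
    """A PoissonFit with prescribed information matrix and coefficients, for
    exercising estimator/risk algebra without an IRLS run (synthetic)."""
    xtwx = np.asarray(xtwx, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = 50
    return PoissonFit(
        beta_mle=beta,
        mu_hat=np.ones(n),
        weight_diag=np.ones(n),
        working_response=np.zeros(n),
        xtwx=xtwx,
        cov_mle=np.linalg.inv(xtwx),
        converged=True,
        iterations=1,
        loglik=0.0,
        sigma2_hat=1.0,
    )


def random_pd_fit(rng: np.random.Generator, dim: int = 3) -> PoissonFit:
    A = rng.standard_normal((dim, dim))
    xtwx = A @ A.T + dim * np.eye(dim)
    beta = rng.standard_normal(dim)
    return make_synthetic_fit(xtwx, beta)


@pytest.fixture
def toy_dataset() -> CountDataset:
    """Fixed 6x2 design (intercept + one covariate) with a fixed response."""
    x = np.array([-0.5, -0.3, -0.1, 0.1, 0.3, 0.5])
    design = np.column_stack([np.ones(6), x])
    y = np.array([1, 2, 1, 3, 4, 6])
    return CountDataset(design=design, response=y, include_intercept=True)


@pytest.fixture
def toy_fit(toy_dataset) -> PoissonFit:
    return fit_poisson_mle(toy_dataset)


@pytest.fixture
def collinear_fit() -> tuple[PoissonFit, CanonicalForm]:
    """A realistic collinear Poisson fit (3 covariates, rho=0.95, n=80)."""
    from poisshrink.simulation import generate_design, true_beta

    ds = generate_design(80, 3, 0.95, seed=7)
    beta = true_beta(ds)
    rng = np.random.default_rng(11)
    y = rng.poisson(np.exp(ds.design @ beta))
    fit = fit_poisson_mle(ds.with_response(y))
    return fit, canonical_decompose(fit)
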