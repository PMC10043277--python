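"""Bootstrap scalar-MSE evaluation of shrinkage estimators on a real dataset.

Case bootstrap: whole observations are resampled with replacement, the model
is refit on every resample, and each estimator is applied (by default with
its biasing parameters re-estimated on that resample, reflecting the full
pipeline's variability; freezing them at the full-data values is a config
option).  The reference ("true") coefficient vector is the mean of the
maximum-likelihood estimates over the resamples, and for each estimator

    SMSE  = mean_b || beta_hat_b - beta_ref ||^2
    var   = mean_b || beta_hat_b - mean_b(beta_hat_b) ||^2

so SMSE = var + || mean_b(beta_hat_b) - beta_ref ||^2 >= var exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biasing import BiasingInputs
from .glm_core import CountDataset, canonical_decompose, fit_poisson_mle
from .simulation import Strategy, default_estimator_catalogue

__all__ = ["BootstrapConfig", "bootstrap_smse"]


@dataclass
class BootstrapConfig:
    n_resamples: int = 10_000
    seed: int = 0
    estimator_set: dict[str, Strategy] | None = None
    reestimate_biasing: bool = True
    max_retries: int = 20
    index_hook: "callable | None" = None  # testing hook: rep index -> row indices

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("need at least one bootstrap resample")


def bootstrap_smse(data: CountDataset, config: BootstrapConfig) -> pd.DataFrame:
    """Bootstrap SMSE table for ``data``.

    Returns one row per estimator with columns ``estimator``, per-coefficient
    bootstrap means ``mean_b0 ...``, ``variance`` and ``smse``.  Resamples on
    which the fit is rank-deficient or non-convergent are redrawn up to
    ``max_retries`` times, then skipped and counted (a warning fires if more
    than 5% are skipped).
    """
    if data.response is None:
        raise ValueError("bootstrap evaluation needs a dataset with responses")
    full_fit = fit_poisson_mle(data)  # raises if the full data cannot be fit
    catalogue = config.estimator_set or default_estimator_catalogue()

    frozen = None
    if not config.reestimate_biasing:
        canon0 = canonical_decompose(full_fit)
        frozen = BiasingInputs.from_fit(full_fit, canon0)

    rng = np.random.default_rng(config.seed)
    n = data.n
    estimates: dict[str, list[np.ndarray]] = {name: [] for name in catalogue}
    mle_estimates: list[np.ndarray] = []
    skipped = 0
    for b in range(config.n_resamples):
        fit = canon = None
        for _ in range(config.max_retries):
            if config.index_hook is not None:
                idx = np.asarray(config.index_hook(b))
            else:
                idx = rng.integers(0, n, size=n)
            sample = CountDataset(
                design=data.design[idx],
                response=data.response[idx],
                include_intercept=data.include_intercept,
                standardized=False,
                column_names=list(data.column_names),
            )
            try:
                fit = fit_poisson_mle(sample, on_failure="return")
                if not fit.converged:
                    fit = None
                    continue
                canon = canonical_decompose(fit)
                break
            except (np.linalg.LinAlgError, ValueError):
                fit = None
                if config.index_hook is not None:
                    break  # deterministic hook: retrying cannot help
        if fit is None:
            skipped += 1
            continue
        inputs = frozen if frozen is not None else BiasingInputs.from_fit(fit, canon)
        mle_estimates.append(fit.beta_mle)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, strat in catalogue.items():
                estimates[name].append(strat(fit, canon, inputs))

    if skipped > 0.05 * config.n_resamples:
        warnings.warn(
            f"{skipped}/{config.n_resamples} bootstrap resamples were skipped",
            stacklevel=2,
        )
    if not mle_estimates:
        raise RuntimeError("no usable bootstrap resamples")

    beta_ref = np.mean(mle_estimates, axis=0)
    rows = []
    for name, betas in estimates.items():
        B = np.asarray(betas)
        mean_b = B.mean(axis=0)
        var = float(np.mean(np.sum((B - mean_b) ** 2, axis=1)))
        smse = float(np.mean(np.sum((B - beta_ref) ** 2, axis=1)))
        row = {"estimator": name}
        row.update({f"mean_b{j}": mean_b[j] for j in range(mean_b.size)})
        row["variance"] = var
        row["smse"] = smse
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["beta_ref"] = beta_ref
    out.attrs["skipped"] = skipped
    return out
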