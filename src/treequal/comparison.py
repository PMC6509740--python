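"""Approximate leave-one-out cross-validation and paired model comparison.

LOO is computed by Pareto-smoothed importance sampling (PSIS) over the
pointwise log-likelihood of the binary sub-item rows — the unit the fitted
Bernoulli likelihood factorizes over.  Results are reported on the deviance
scale (-2 x elpd), the scale on which the comparison tables print LOO, and
the paired difference ΔLOO = LOO(model A) - LOO(model B) carries a standard
error computed from the pointwise differences, which requires both models
to have been fit to the identical observation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .inference import PosteriorFit

#: Pareto tail-shape value above which an observation's importance weights
#: are considered unreliable (established PSIS practice).
PARETO_K_WARN = 0.7

#: Minimum number of posterior draws for a stable generalized-Pareto tail fit.
MIN_DRAWS = 25


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fit.

    ``loo_deviance`` is -2 x ``elpd_loo``; ``pointwise_elpd`` (one entry per
    sub-item observation) sums to ``elpd_loo``; ``pareto_k`` holds the
    tail-shape diagnostic per observation.
    """

    elpd_loo: float
    se: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray
    obs_ids: np.ndarray
    warnings_: list

    @property
    def loo_deviance(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def deviance_se(self) -> float:
        return 2.0 * self.se

    @property
    def n_obs(self) -> int:
        return len(self.pointwise_elpd)

    def __str__(self) -> str:  # mirrors the "LOO (SE)" table convention
        return f"{self.loo_deviance:.2f} ({self.deviance_se:.2f})"


@dataclass
class ModelComparison:
    """Paired LOO comparison of two fits on identical observations.

    ``delta_loo`` is LOO(a) - LOO(b) on the deviance scale — with a = the
    unidimensional and b = the multidimensional model, positive values
    favor the multidimensional one.
    """

    loo_a: LooResult
    loo_b: LooResult
    delta_loo: float
    delta_se: float

    @property
    def favored(self) -> str:
        return "b" if self.delta_loo > 0 else "a"

    @property
    def decisive(self) -> bool:
        """Whether |ΔLOO| exceeds twice its standard error."""
        return abs(self.delta_loo) > 2.0 * self.delta_se

    def __str__(self) -> str:
        return (
            f"LOO(a) = {self.loo_a}, LOO(b) = {self.loo_b}, "
            f"dLOO = {self.delta_loo:.2f} ({self.delta_se:.2f})"
        )


def compute_loo(fit: PosteriorFit) -> LooResult:
    """PSIS-LOO from the pointwise log-likelihood stored on a fit.

    Importance ratios are tail-smoothed per observation by fitting a
    generalized Pareto distribution to the largest 20% of ratios; the
    expected log pointwise predictive density (elpd) comes from the
    smoothed weights and its standard error is
    sqrt(n x var(pointwise elpd)).
    """
    n_draws = fit.log_lik.shape[0] * fit.log_lik.shape[1]
    if n_draws < MIN_DRAWS:
        raise ValueError(
            f"{n_draws} posterior draws are too few for a stable Pareto tail fit "
            f"(need >= {MIN_DRAWS})"
        )
    if fit.log_lik.shape[-1] == 0:
        raise ValueError("fit has no observations (prior-only fit has no LOO)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(fit.idata, pointwise=True)
    pointwise = np.asarray(res.loo_i.values, float)
    pareto_k = np.asarray(res.pareto_k.values, float)
    flags: list[str] = []
    n_bad = int((pareto_k > PARETO_K_WARN).sum())
    if n_bad:
        flags.append(
            f"{n_bad} observation(s) with Pareto k > {PARETO_K_WARN}; "
            "their LOO contributions may be unreliable"
        )
    return LooResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        pointwise_elpd=pointwise,
        pareto_k=pareto_k,
        obs_ids=fit.obs_ids,
        warnings_=flags,
    )


def compare(fit_a: PosteriorFit, fit_b: PosteriorFit) -> ModelComparison:
    """Paired ΔLOO between two fits of the same observations.

    By the reporting convention, call with the unidimensional model as
    ``fit_a`` and the multidimensional one as ``fit_b`` so that positive
    ΔLOO favors the multidimensional model.

    Raises
    ------
    ValueError
        If the two fits do not share the identical sub-item rows in the
        same order (no silent alignment is attempted).
    """
    if len(fit_a.obs_ids) != len(fit_b.obs_ids) or not np.array_equal(fit_a.obs_ids, fit_b.obs_ids):
        raise ValueError("fits were not computed on the identical observation set")
    loo_a = compute_loo(fit_a)
    loo_b = compute_loo(fit_b)
    # deviance-scale pointwise difference; ΔLOO = dev(a) - dev(b)
    d = -2.0 * (loo_a.pointwise_elpd - loo_b.pointwise_elpd)
    n = len(d)
    delta = float(d.sum())
    delta_se = float(np.sqrt(n * d.var(ddof=0))) if n > 1 else 0.0
    return ModelComparison(loo_a=loo_a, loo_b=loo_b, delta_loo=delta, delta_se=delta_se)


def comparison_table(rows: list[tuple[str, LooResult]],
                     delta: ModelComparison | None = None) -> pd.DataFrame:
    """Tabulate LOO (SE) per model plus an optional ΔLOO (SE) line."""
    records = [
        {"model": name, "LOO": loo.loo_deviance, "SE": loo.deviance_se}
        for name, loo in rows
    ]
    out = pd.DataFrame(records)
    if delta is not None:
        out.attrs["delta_loo"] = delta.delta_loo
        out.attrs["delta_se"] = delta.delta_se
    return out
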