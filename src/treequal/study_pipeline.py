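"""End-to-end study analysis: splits, reliability, and model batteries.

Reproduces the analysis workflow on any rating table: inter-rater
reliability as ICC(2,2); within-person / within-item fluency median splits
(strictly-below coding); and the two model batteries — unidimensional vs.
node-multidimensional per data subset, and unidimensional vs. low/high-
fluency two-trait models per instruction and split method — each adjudicated
by paired PSIS-LOO on identical observation sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TreeSpec, validate_ratings
from .treeify import expand_to_subitems
from .inference import (
    PosteriorFit,
    PriorConfig,
    SamplerConfig,
    detect_noninformative_nodes,
    fit_model,
    omit_nodes,
    summarize_correlations,
)
from .comparison import ModelComparison, compare, compute_loo

logger = logging.getLogger("treequal")

SplitMethod = Literal["within_person", "within_item"]


@dataclass(frozen=True)
class SplitSpec:
    """How to dichotomize fluency: relative to the person's or the item's
    median, always within instruction, low = strictly below the median."""

    method: SplitMethod = "within_person"

    @property
    def group_columns(self) -> list[str]:
        if self.method == "within_person":
            return ["person_id", "instruction"]
        return ["item_id", "instruction"]


@dataclass
class AnalysisConfig:
    """Settings of a full study analysis."""

    tree: TreeSpec = field(default_factory=TreeSpec)
    priors: PriorConfig = field(default_factory=PriorConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    min_per_class: int = 5
    split_methods: tuple = ("within_person", "within_item")


def median_split(ratings: pd.DataFrame, spec: SplitSpec | None = None) -> pd.DataFrame:
    """Label every rating row low/high fluency by a strictly-below median split.

    The median is computed over the distinct ideational pools of the group —
    one fluency value per (person, item), not per rater row — separately per
    person (or item) and instruction.  A pool is ``low`` iff its fluency is
    strictly below the group median, so both raters' rows for the same pool
    always share a label and at most half of any group is labeled low.
    """
    spec = spec or SplitSpec()
    ratings = ratings.copy()
    pools = ratings.drop_duplicates(["person_id", "item_id"])
    med = pools.groupby(spec.group_columns, sort=False)["fluency"].median()
    if (pools.groupby(spec.group_columns, sort=False).size() == 0).any():  # pragma: no cover
        logger.info("empty split group skipped")
    keys = pd.MultiIndex.from_frame(ratings[spec.group_columns])
    group_median = med.reindex(keys).to_numpy()
    ratings["fluency_group"] = np.where(
        ratings["fluency"].to_numpy() < group_median, "low", "high"
    )
    return ratings


def icc_2_k(rating_matrix: np.ndarray, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    Parameters
    ----------
    rating_matrix
        Complete (n targets) x (k raters) matrix; every target must be rated
        by every rater (no imputation is attempted).

    Returns
    -------
    (estimate, (ci_low, ci_high))
        ICC(2,k) = (MS_T - MS_E) / (MS_T + (MS_R - MS_E)/n) with the
        confidence interval from the F-distribution method for
        absolute-agreement average measures (single-measure bounds stepped
        up by the Spearman-Brown relation).
    """
    x = np.asarray(rating_matrix, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D targets x raters matrix with k >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("rating matrix has missing cells; ICC(2,k) needs complete data")
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 targets")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # targets
    msc = ss_cols / (k - 1)          # raters
    mse = ss_err / ((n - 1) * (k - 1))

    icc2k = (msr - mse) / (msr + (msc - mse) / n)

    # CI: bounds for single-measure ICC(2,1) via Satterthwaite df, then
    # Spearman-Brown step-up (McGraw & Wong's ICC(A,k) interval)
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if 1.0 - icc2 < 1e-12:  # perfect agreement: the F interval degenerates
        return float(icc2k), (float(icc2k), float(icc2k))
    alpha = 1 - ci
    denom = n * (1 - icc2)
    a = k * icc2 / denom
    b = 1 + k * icc2 * (n - 1) / denom
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi1 = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    step_up = lambda r: r * k / (1 + (k - 1) * r)
    return float(icc2k), (float(step_up(lo1)), float(step_up(hi1)))


def pooled_rating_matrix(ratings: pd.DataFrame) -> np.ndarray:
    """Targets x raters matrix, one target per (person, item) ideational pool."""
    wide = ratings.pivot_table(index=["person_id", "item_id"], columns="rater_id",
                               values="rating", aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("not every pool was rated by every rater")
    return wide.to_numpy(float)


def _correlation_grid(fit: PosteriorFit, tree: TreeSpec) -> pd.DataFrame:
    """Lower-triangle node-correlation table with NA rows for omitted nodes."""
    summary = summarize_correlations(fit)
    all_nodes = list(tree.nodes)
    kept = {f"node_{r}": r for r in fit.nodes}
    grid = pd.DataFrame(index=[f"node_{r}" for r in all_nodes[1:]],
                        columns=[f"node_{r}" for r in all_nodes[:-1]], dtype=object)
    for _, row in summary.iterrows():
        a, b = sorted((kept[row["dim_a"]], kept[row["dim_b"]]))
        grid.loc[f"node_{b}", f"node_{a}"] = (
            f"{row['mean']:.2f} [{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
        )
    for j, col in enumerate(grid.columns):
        for i, idx in enumerate(grid.index):
            if i >= j and pd.isna(grid.loc[idx, col]):
                grid.loc[idx, col] = "NA"
            elif i < j:
                grid.loc[idx, col] = ""
    return grid


@dataclass
class BatteryBlock:
    """One subset's model pair: fits, LOO comparison, correlation summary."""

    subset: str
    comparison: ModelComparison | None
    correlations: pd.DataFrame | None
    omitted: list
    error: str | None = None


def run_node_dimensionality_battery(ratings: pd.DataFrame,
                                    config: AnalysisConfig | None = None) -> dict:
    """Unidimensional vs. node-multidimensional, for full / be-fluent / be-creative.

    Per subset: detect and omit non-informative (instruction, node) pairs,
    fit both latent structures on the identical remaining rows, compare by
    paired LOO, and tabulate node correlations (NA where a node was
    omitted).  A failing subset is logged and skipped, not fatal.
    """
    config = config or AnalysisConfig()
    ratings = validate_ratings(ratings, config.tree)
    blocks: list[BatteryBlock] = []
    subsets = [
        ("full", ratings),
        ("be_fluent", ratings[ratings["instruction"] == "be_fluent"]),
        ("be_creative", ratings[ratings["instruction"] == "be_creative"]),
    ]
    for name, subset in subsets:
        try:
            blocks.append(_node_block(name, subset, config))
        except Exception as exc:  # battery continues with remaining subsets
            logger.exception("subset %s failed", name)
            blocks.append(BatteryBlock(name, None, None, [], error=str(exc)))
    return {"battery": "node_dimensionality", "blocks": blocks}


def _node_block(name: str, subset: pd.DataFrame, config: AnalysisConfig) -> BatteryBlock:
    subitems = expand_to_subitems(subset, config.tree)
    flags = detect_noninformative_nodes(subitems, config.min_per_class, config.tree)
    omitted = list(map(tuple, flags.loc[flags["flagged"], ["instruction", "node"]].to_numpy()))
    kept = omit_nodes(subitems, flags)
    logger.info("subset %s: %d sub-items kept (%d omitted), omitted nodes %s",
                name, len(kept), len(subitems) - len(kept), omitted)
    fit_uni = fit_model(kept, "unidimensional", config.tree, config.priors, config.sampler)
    fit_multi = fit_model(kept, "node_multidimensional", config.tree, config.priors,
                          config.sampler)
    comp = compare(fit_uni, fit_multi)
    grid = _correlation_grid(fit_multi, config.tree)
    return BatteryBlock(name, comp, grid, omitted)


def run_fluency_split_battery(ratings: pd.DataFrame,
                              config: AnalysisConfig | None = None) -> dict:
    """Unidimensional vs. low/high-fluency traits, per instruction x split method.

    Within each instruction the non-informative nodes are omitted first;
    the low-high latent correlation is reported with its credible interval
    and the implied shared variance r^2 (squared posterior-mean correlation).
    """
    config = config or AnalysisConfig()
    ratings = validate_ratings(ratings, config.tree)
    blocks = []
    for instr in ("be_fluent", "be_creative"):
        subset = ratings[ratings["instruction"] == instr]
        for method in config.split_methods:
            name = f"{instr}/{method}"
            try:
                blocks.append(_fluency_block(name, subset, SplitSpec(method), config))
            except Exception as exc:
                logger.exception("block %s failed", name)
                blocks.append({"subset": name, "error": str(exc)})
    return {"battery": "fluency_split", "blocks": blocks}


def _fluency_block(name: str, subset: pd.DataFrame, spec: SplitSpec,
                   config: AnalysisConfig) -> dict:
    labeled = median_split(subset, spec)
    subitems = expand_to_subitems(labeled, config.tree)
    flags = detect_noninformative_nodes(subitems, config.min_per_class, config.tree)
    omitted = list(map(tuple, flags.loc[flags["flagged"], ["instruction", "node"]].to_numpy()))
    kept = omit_nodes(subitems, flags)
    fit_uni = fit_model(kept, "unidimensional", config.tree, config.priors, config.sampler)
    fit_split = fit_model(kept, "fluency_split", config.tree, config.priors, config.sampler)
    comp = compare(fit_uni, fit_split)
    corr = summarize_correlations(fit_split)
    r = float(corr["mean"].iloc[0])
    return {
        "subset": name,
        "comparison": comp,
        "correlation": corr,
        "shared_variance": round(r ** 2, 2),
        "omitted": omitted,
    }


def render_node_battery(report: dict) -> str:
    """Markdown rendering of a node-dimensionality battery report."""
    lines = ["# Node dimensionality: unidimensional vs. node-multidimensional", ""]
    for block in report["blocks"]:
        lines.append(f"## {block.subset}")
        if block.error:
            lines += [f"(failed: {block.error})", ""]
            continue
        comp = block.comparison
        lines += [
            "",
            "| model | LOO (SE) |",
            "| --- | --- |",
            f"| unidimensional | {comp.loo_a} |",
            f"| node-multidimensional | {comp.loo_b} |",
            f"| ΔLOO (SE) | {comp.delta_loo:.2f} ({comp.delta_se:.2f}) |",
            "",
            "Latent node correlations (posterior mean [95% CI]):",
            "",
            block.correlations.to_markdown(),
            "",
        ]
        if block.omitted:
            lines.append(f"Omitted (instruction, node) pairs: {block.omitted}")
            lines.append("")
    return "\n".join(lines)


def render_fluency_battery(report: dict) -> str:
    """Markdown rendering of a fluency-split battery report."""
    lines = ["# Fluency split: unidimensional vs. low/high-fluency traits", ""]
    for block in report["blocks"]:
        lines.append(f"## {block['subset']}")
        if "error" in block:
            lines += [f"(failed: {block['error']})", ""]
            continue
        comp = block["comparison"]
        corr = block["correlation"].iloc[0]
        lines += [
            "",
            "| model | LOO (SE) |",
            "| --- | --- |",
            f"| unidimensional | {comp.loo_a} |",
            f"| low vs. high fluency | {comp.loo_b} |",
            f"| ΔLOO (SE) | {comp.delta_loo:.2f} ({comp.delta_se:.2f}) |",
            "",
            f"corr(low, high) = {corr['mean']:.2f} "
            f"[{corr['ci_low']:.2f}, {corr['ci_high']:.2f}], "
            f"shared variance ≈ {block['shared_variance']:.0%}",
            "",
        ]
    return "\n".join(lines)
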