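import numpy as np
import pandas as pd
import pytest
from scipy import stats

from treequal import (
    PriorConfig,
    SamplerConfig,
    SyntheticConfig,
    TreeSpec,
    detect_noninformative_nodes,
    expand_to_subitems,
    fit_model,
    generate_study,
    omit_nodes,
    summarize_correlations,
)
from treequal.core_data import StudyDesign
from treequal.inference import IdentificationError

from conftest import random_rating_table


@pytest.fixture(scope="module")
def small_fit():
    """One short unidimensional fit reused by several structural checks."""
    table, _ = generate_study(SyntheticConfig(n_persons=40, seed=31))
    sub = expand_to_subitems(table)
    kept = omit_nodes(sub, detect_noninformative_nodes(sub))
    fit = fit_model(kept, "unidimensional",
                    sampler=SamplerConfig(warmup_draws=150, kept_draws=150, seed=5))
    return kept, fit


def test_fit_shapes_and_diagnostics(small_fit):
    kept, fit = small_fit
    n_cells = len(fit.cells)
    assert fit.posterior["beta"].shape == (2, 150, n_cells)
    assert fit.posterior["theta"].shape[2:] == (40, 1)
    assert fit.log_lik.shape == (2, 150, len(kept))
    assert np.isfinite(fit.log_lik).all()
    assert set(fit.rhat.index) == {"beta", "delta", "sigma", "corr", "theta"}
    assert (fit.obs_ids == np.array([
        f"{p}|{i}|{k}|{r}" for p, i, k, r in zip(
            kept["person_id"], kept["item_id"], kept["rater_id"], kept["node"])
    ])).all()


def test_fit_is_reproducible(small_fit):
    kept, fit = small_fit
    again = fit_model(kept, "unidimensional",
                      sampler=SamplerConfig(warmup_draws=150, kept_draws=150, seed=5))
    for name in fit.posterior:
        np.testing.assert_array_equal(fit.posterior[name], again.posterior[name])


def test_single_class_node_raises_identification_error():
    rng = np.random.default_rng(2)
    table = random_rating_table(rng, n_persons=15)
    table.loc[table["rating"] == 5, "rating"] = 4  # node 4 never passed
    sub = expand_to_subitems(table)
    with pytest.raises(IdentificationError, match="omit_nodes"):
        fit_model(sub, "unidimensional",
                  sampler=SamplerConfig(warmup_draws=50, kept_draws=50, seed=1))


def test_prior_only_fit_reproduces_priors():
    """With no data the posterior must coincide with the prior (two-sample
    KS at alpha = 0.01 on thinned draws, against direct prior samples)."""
    design = StudyDesign(persons=[f"p{i}" for i in range(30)],
                         items=[("i1", "be_fluent"), ("i2", "be_creative")],
                         raters=["r1", "r2"])
    empty = pd.DataFrame(columns=["person_id", "item_id", "rater_id", "instruction",
                                  "fluency", "fluency_group", "node", "outcome"])
    priors = PriorConfig()
    fit = fit_model(empty, "fluency_split", priors=priors, design=design,
                    sampler=SamplerConfig(warmup_draws=300, kept_draws=3000, seed=3))
    thin = slice(None, None, 10)  # draws are autocorrelated; KS needs near-iid

    beta = fit.stacked("beta")[thin, 0]
    assert abs(beta.mean()) < 3 * priors.beta_prior_scale / np.sqrt(len(beta))
    assert stats.ks_1samp(beta, stats.norm(0, priors.beta_prior_scale).cdf).pvalue > 0.01

    sigma = fit.stacked("sigma")[thin, 0]
    assert stats.ks_1samp(sigma, stats.halfnorm(0, priors.sd_prior).cdf).pvalue > 0.01

    # LKJ(1) on a 2x2 matrix: the off-diagonal correlation is uniform(-1, 1)
    corr = fit.stacked("corr")[thin, 0, 1]
    assert stats.ks_1samp(corr, stats.uniform(-1, 2).cdf).pvalue > 0.01


def test_unidimensional_recovery_of_latent_scale():
    """Data simulated at sigma = 1: posterior mean of sigma within +-0.2."""
    cfg = SyntheticConfig(n_persons=200, structure="unidimensional", theta_sd=1.0, seed=42)
    table, _ = generate_study(cfg)
    sub = expand_to_subitems(table)
    kept = omit_nodes(sub, detect_noninformative_nodes(sub))
    fit = fit_model(kept, "unidimensional", sampler=SamplerConfig(seed=6))
    assert fit.stacked("sigma").mean() == pytest.approx(1.0, abs=0.2)
    # rater leniency offset recovered with the right sign
    assert fit.stacked("delta")[:, 1].mean() == pytest.approx(-0.3, abs=0.15)


def test_summarize_correlations_pair_counts(small_fit):
    _, fit_uni = small_fit
    empty = summarize_correlations(fit_uni)
    assert len(empty) == 0 and "unidimensional" in empty.attrs["notice"]

    table, _ = generate_study(SyntheticConfig(n_persons=40, seed=32,
                                              structure="node_multidimensional"))
    sub = expand_to_subitems(table)
    kept = omit_nodes(sub, detect_noninformative_nodes(sub))
    fit = fit_model(kept, "node_multidimensional",
                    sampler=SamplerConfig(warmup_draws=100, kept_draws=100, seed=7))
    summary = summarize_correlations(fit)
    d = fit.n_dimensions
    assert len(summary) == d * (d - 1) // 2
    assert ((summary["ci_low"] <= summary["mean"]) & (summary["mean"] <= summary["ci_high"])).all()


def test_detect_noninformative_nodes_thresholds():
    rng = np.random.default_rng(11)
    table = random_rating_table(rng, n_persons=60)  # uniform ratings: all classes rich
    sub = expand_to_subitems(table)
    flags = detect_noninformative_nodes(sub, min_per_class=10)
    assert not flags["flagged"].any()
    assert not detect_noninformative_nodes(sub, min_per_class=0)["flagged"].any()
    # remove every top rating under one instruction: its node 4 loses a class
    starved = table.copy()
    fluent_top = (starved["instruction"] == "be_fluent") & (starved["rating"] == 5)
    starved.loc[fluent_top, "rating"] = 4
    flags = detect_noninformative_nodes(expand_to_subitems(starved), min_per_class=5)
    flagged = set(map(tuple, flags.loc[flags["flagged"], ["instruction", "node"]].to_numpy()))
    assert ("be_fluent", 4) in flagged


def test_omit_nodes_removes_exactly_flagged_rows():
    rng = np.random.default_rng(12)
    sub = expand_to_subitems(random_rating_table(rng))
    assert len(omit_nodes(sub, [])) == len(sub)
    kept = omit_nodes(sub, [("be_fluent", 4)])
    assert not ((kept["instruction"] == "be_fluent") & (kept["node"] == 4)).any()
    others = (sub["instruction"] != "be_fluent") | (sub["node"] != 4)
    assert len(kept) == int(others.sum())
    tree = TreeSpec()
    all_pairs = [(i, r) for i in ("be_fluent", "be_creative") for r in tree.nodes]
    assert len(omit_nodes(sub, all_pairs)) == 0
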