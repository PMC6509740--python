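import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from treequal import (
    DimensionMap,
    ModelParameters,
    StudyDesign,
    TreeSpec,
    category_probabilities,
    expand_to_subitems,
    log_likelihood,
    node_pass_probability,
    simulate_ratings,
)

from conftest import random_rating_table


def brute_force_category_probs(theta, beta, delta=0.0):
    """Independent oracle: enumerate every pass/fail path through the tree."""
    r = len(beta)
    p = [1.0 / (1.0 + np.exp(-(theta[i] + beta[i] + delta))) for i in range(r)]
    probs = np.zeros(r + 1)
    # weight every full outcome tuple over all R nodes; the rating depends
    # only on the prefix up to the first failure, so the hypothetical
    # outcomes of unreached nodes marginalize out across tuples
    for path in itertools.product([0, 1], repeat=r):
        weight = np.prod([p[i] if b else 1.0 - p[i] for i, b in enumerate(path)])
        rating = next((i + 1 for i, b in enumerate(path) if not b), r + 1)
        probs[rating - 1] += weight
    return probs


def test_pass_probability_values_and_monotonicity():
    assert node_pass_probability(0.0, 0.0, 0.0) == pytest.approx(0.5, abs=1e-15)
    # logistic(1 - 0.5 + 0.2) = logistic(0.7), high-precision reference
    assert node_pass_probability(1.0, -0.5, 0.2) == pytest.approx(
        1.0 / (1.0 + np.exp(-0.7)), abs=1e-12)
    grid = np.linspace(-30.0, 30.0, 121)
    probs = node_pass_probability(grid, 0.0)
    assert (np.diff(probs) >= 0).all() and probs[-1] > 1.0 - 1e-12
    with pytest.raises(ValueError, match="non-finite"):
        node_pass_probability(np.inf, 0.0)


def test_category_probabilities_match_path_enumeration():
    probs = category_probabilities(np.zeros(4), np.zeros(4))
    assert probs == pytest.approx([0.5, 0.25, 0.125, 0.0625, 0.0625], abs=1e-14)
    rng = np.random.default_rng(3)
    for _ in range(20):
        theta, beta = rng.normal(0, 1.5, (2, 4))
        delta = rng.normal(0, 0.5)
        probs = category_probabilities(theta, beta, delta)
        assert probs == pytest.approx(brute_force_category_probs(theta, beta, delta), abs=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    # failure certain at node 1 concentrates all mass on the lowest category
    assert category_probabilities([0, 0, 0, 0], [-60, 0, 0, 0])[0] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="equal length"):
        category_probabilities(np.zeros(3), np.zeros(4))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(-20, 20), min_size=1, max_size=8),
       st.floats(-5, 5), st.floats(0.1, 3.0))
def test_distribution_and_monotonicity_for_arbitrary_parameters(beta, delta, shift):
    """category_probabilities is a probability distribution for any finite
    parameters, and raising the latent trait moves mass to higher
    categories (stochastic dominance of the implied rating)."""
    beta = np.asarray(beta)
    theta = np.zeros_like(beta)
    probs = category_probabilities(theta, beta, delta)
    assert (probs >= 0).all()
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    higher = category_probabilities(theta + shift, beta, delta)
    # compare survivor functions: P(Y > m) must not decrease anywhere
    sf_low = 1.0 - np.cumsum(probs)[:-1]
    sf_high = 1.0 - np.cumsum(higher)[:-1]
    assert (sf_high >= sf_low - 1e-12).all()


def _uni_params(n_items, seed=0, delta=(0.0, -0.3)):
    rng = np.random.default_rng(seed)
    return ModelParameters(
        beta=rng.normal(0, 1, (n_items, 4)),
        delta=np.asarray(delta),
        theta_sd=[1.0],
        theta_corr=[[1.0]],
        structure="unidimensional",
    )


def test_loglik_equals_categorical_factorization():
    """Bernoulli sum over sub-items == sequential categorical likelihood."""
    rng = np.random.default_rng(4)
    table = random_rating_table(rng, n_persons=10, n_items=4)
    sub = expand_to_subitems(table)
    params = _uni_params(4, seed=1)
    dmap = DimensionMap.for_structure("unidimensional")
    persons = list(pd.unique(sub["person_id"]))
    theta = rng.normal(0, 1, (len(persons), 1))

    total, pointwise = log_likelihood(params, theta, sub, dmap)
    assert total == pytest.approx(pointwise.sum())
    assert len(pointwise) == len(sub)

    items = list(pd.unique(sub["item_id"]))
    raters = list(pd.unique(sub["rater_id"]))
    expected = 0.0
    for _, row in table.iterrows():
        th = np.full(4, theta[persons.index(row.person_id), 0])
        beta = params.beta[items.index(row.item_id)]
        delta = params.delta[raters.index(row.rater_id)]
        expected += np.log(category_probabilities(th, beta, delta)[row.rating - 1])
    assert total == pytest.approx(expected, abs=1e-10)


def test_loglik_simple_values():
    sub = expand_to_subitems(pd.DataFrame([dict(
        person_id="p", item_id="i", rater_id="r", instruction="be_fluent",
        fluency=1, rating=2)]))  # nodes: pass 1, fail 2
    params = ModelParameters(beta=np.zeros((1, 4)), delta=[0.0], theta_sd=[1.0],
                             theta_corr=[[1.0]])
    dmap = DimensionMap.for_structure("unidimensional")
    total, pointwise = log_likelihood(params, np.zeros((1, 1)), sub, dmap)
    assert pointwise == pytest.approx([np.log(0.5), np.log(0.5)])
    # all-pass data under an overwhelming predictor: log-likelihood -> 0
    total_sat, _ = log_likelihood(params, np.full((1, 1), 50.0), sub.iloc[:1], dmap)
    assert abs(total_sat) < 1e-12


def test_dimension_map_assignment():
    sub = pd.DataFrame({"node": [1, 2, 4], "fluency_group": ["low", "high", "low"]})
    assert DimensionMap.for_structure("unidimensional").assign(sub).tolist() == [0, 0, 0]
    nm = DimensionMap.for_structure("node_multidimensional", TreeSpec(5))
    assert nm.assign(sub).tolist() == [0, 1, 3]
    # retained-node maps re-index after omission
    nm2 = DimensionMap.for_structure("node_multidimensional", nodes=(2, 4))
    assert nm2.assign(sub.iloc[1:]).tolist() == [0, 1]
    with pytest.raises(ValueError, match="no latent dimension"):
        nm2.assign(sub)
    fs = DimensionMap.for_structure("fluency_split")
    assert fs.assign(sub).tolist() == [0, 1, 0]
    with pytest.raises(ValueError, match="median_split"):
        fs.assign(sub.assign(fluency_group="unassigned"))


def test_parameter_validation_and_json_roundtrip(tmp_path):
    with pytest.raises(ValueError, match="reference rater"):
        ModelParameters(np.zeros((2, 4)), [0.5, 0.0], [1.0], [[1.0]])
    with pytest.raises(ValueError, match="positive semi-definite"):
        ModelParameters(np.zeros((2, 2)), [0.0], [1.0, 1.0],
                        [[1.0, 1.5], [1.5, 1.0]], structure="fluency_split")
    with pytest.raises(ValueError, match="one dimension per node"):
        ModelParameters(np.zeros((2, 4)), [0.0], [1.0, 1.0], np.eye(2),
                        structure="node_multidimensional")
    params = _uni_params(3)
    path = tmp_path / "params.json"
    params.to_json(path)
    back = ModelParameters.from_json(path)
    np.testing.assert_allclose(back.beta, params.beta)
    assert back.structure == params.structure


def _design(n_persons=300, n_items=2, n_raters=1):
    return StudyDesign(
        persons=[f"p{i}" for i in range(n_persons)],
        items=[(f"i{j}", "be_fluent") for j in range(n_items)],
        raters=[f"r{k}" for k in range(n_raters)],
    )


def test_simulation_is_deterministic_and_respects_limits():
    design = _design(n_persons=40)
    params = _uni_params(2, delta=(0.0,))
    theta = np.random.default_rng(5).normal(0, 1, (40, 1))
    t1 = simulate_ratings(design, params, theta, seed=11)
    t2 = simulate_ratings(design, params, theta, seed=11)
    pd.testing.assert_frame_equal(t1, t2)
    # impossible nodes force every rating to the bottom category
    floor_params = ModelParameters(np.full((2, 4), -80.0), [0.0], [1.0], [[1.0]])
    t3 = simulate_ratings(design, floor_params, theta, seed=12)
    assert (t3["rating"] == 1).all()


def test_simulated_frequencies_match_category_probabilities():
    """Monte-Carlo check of the generative walk against the analytic pmf."""
    n = 10_000
    design = _design(n_persons=n, n_items=1)
    params = ModelParameters(np.zeros((1, 4)), [0.0], [1.0], [[1.0]])
    theta = np.zeros((n, 1))  # all-zero predictors
    table = simulate_ratings(design, params, theta, seed=13)
    freq = table["rating"].value_counts(normalize=True).sort_index().to_numpy()
    expected = np.array([0.5, 0.25, 0.125, 0.0625, 0.0625])
    se = np.sqrt(expected * (1 - expected) / n)
    assert (np.abs(freq - expected) < 3 * se).all()


def test_higher_trait_shifts_ratings_up():
    design = _design(n_persons=2000, n_items=1)
    params = ModelParameters(np.zeros((1, 4)), [0.0], [1.0], [[1.0]])
    low = simulate_ratings(design, params, np.full((2000, 1), -1.0), seed=14)
    high = simulate_ratings(design, params, np.full((2000, 1), 1.0), seed=14)
    assert high["rating"].mean() > low["rating"].mean() + 0.5
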