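import numpy as np
import pandas as pd
import pytest

from treequal import (
    AnalysisConfig,
    SamplerConfig,
    SyntheticConfig,
    generate_study,
    icc_2_k,
    median_split,
    run_fluency_split_battery,
    run_node_dimensionality_battery,
)
from treequal.study_pipeline import (
    SplitSpec,
    pooled_rating_matrix,
    render_fluency_battery,
    render_node_battery,
)

from conftest import random_rating_table


def one_person_items(fluencies, instruction="be_fluent"):
    rows = []
    for j, f in enumerate(fluencies):
        for rater in ("r1", "r2"):
            rows.append(dict(person_id="p1", item_id=f"i{j}", rater_id=rater,
                             instruction=instruction, fluency=f, rating=3))
    return pd.DataFrame(rows)


@pytest.mark.parametrize("fluencies, expected", [
    ([2, 3, 5, 7], ["low", "low", "high", "high"]),  # median 4, strictly below
    ([4, 4, 4, 4], ["high"] * 4),                     # ties are never "low"
    ([1, 9], ["low", "high"]),                        # median 5
])
def test_within_person_split_rule(fluencies, expected):
    labeled = median_split(one_person_items(fluencies), SplitSpec("within_person"))
    per_item = labeled.drop_duplicates("item_id").sort_values("item_id")
    assert per_item["fluency_group"].tolist() == expected


def test_within_item_split_and_instruction_separation():
    rows = []
    for p, f_fluent, f_creative in [("p1", 2, 9), ("p2", 6, 1), ("p3", 10, 5)]:
        for item, instr, f in [("a", "be_fluent", f_fluent), ("b", "be_creative", f_creative)]:
            rows.append(dict(person_id=p, item_id=item, rater_id="r1",
                             instruction=instr, fluency=f, rating=2))
    labeled = median_split(pd.DataFrame(rows), SplitSpec("within_item"))
    # item a median 6 -> {2: low, 6: high, 10: high}; item b median 5
    got = labeled.set_index(["person_id", "item_id"])["fluency_group"]
    assert got[("p1", "a")] == "low" and got[("p2", "a")] == "high"
    assert got[("p2", "b")] == "low" and got[("p3", "b")] == "high"


def test_split_properties_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(25):
        table = random_rating_table(rng, n_persons=12, n_items=6)
        for method in ("within_person", "within_item"):
            spec = SplitSpec(method)
            labeled = median_split(table, spec)
            # both raters of a pool share the label
            assert (labeled.groupby(["person_id", "item_id"])["fluency_group"]
                    .nunique() == 1).all()
            # strictly-below rule: at most half of each group is low
            pools = labeled.drop_duplicates(["person_id", "item_id"])
            frac_low = pools.groupby(spec.group_columns)["fluency_group"].agg(
                lambda g: (g == "low").mean())
            assert (frac_low <= 0.5).all()


def test_icc_identical_raters_is_one():
    x = np.column_stack([np.arange(10.0), np.arange(10.0)])
    est, (lo, hi) = icc_2_k(x)
    assert est == pytest.approx(1.0, abs=1e-12)
    assert hi <= 1.0 + 1e-9


def test_icc_independent_raters_near_zero():
    rng = np.random.default_rng(23)
    x = rng.normal(0, 1, (500, 2))
    est, _ = icc_2_k(x)
    assert abs(est) < 0.1


def test_icc_matches_independent_implementation():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(29)
    for _ in range(5):
        x = rng.normal(0, 1, (30, 2)) + rng.normal(0, 1, (30, 1))
        est, (lo, hi) = icc_2_k(x)
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": np.tile(["a", "b"], 30),
            "score": x.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="score").set_index("Type")
        assert est == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-10)
        ref_lo, ref_hi = ref.loc["ICC(A,k)", "CI95"]  # printed rounded to 2 dp
        assert lo == pytest.approx(ref_lo, abs=5.1e-3)
        assert hi == pytest.approx(ref_hi, abs=5.1e-3)


def test_icc_input_validation():
    with pytest.raises(ValueError, match="missing"):
        icc_2_k(np.array([[1.0, np.nan], [2.0, 2.0]]))
    with pytest.raises(ValueError, match="2 targets"):
        icc_2_k(np.array([[1.0, 2.0]]))
    with pytest.raises(ValueError, match="raters"):
        icc_2_k(np.array([[1.0], [2.0]]))


def test_pooled_rating_matrix(small_table):
    mat = pooled_rating_matrix(small_table)
    assert mat.shape == (4, 2)
    with pytest.raises(ValueError, match="every rater"):
        pooled_rating_matrix(small_table.iloc[1:])


@pytest.fixture(scope="module")
def battery_config():
    return AnalysisConfig(sampler=SamplerConfig(warmup_draws=150, kept_draws=150, seed=55))


@pytest.fixture(scope="module")
def battery_study():
    table, _ = generate_study(SyntheticConfig(n_persons=80, seed=66))
    return table


def test_node_battery_structure(battery_study, battery_config):
    report = run_node_dimensionality_battery(battery_study, battery_config)
    blocks = report["blocks"]
    assert [b.subset for b in blocks] == ["full", "be_fluent", "be_creative"]
    for block in blocks:
        assert block.error is None
        assert block.comparison.loo_a.n_obs == block.comparison.loo_b.n_obs
    # instruction-specific blocks omit their starved node and render it NA
    fluent = blocks[1]
    assert ("be_fluent", 4) in fluent.omitted
    assert (fluent.correlations.loc["node_4"] == "NA").any()
    creative = blocks[2]
    assert ("be_creative", 1) in creative.omitted
    assert creative.correlations.loc["node_2", "node_1"] == "NA"
    md = render_node_battery(report)
    assert md.count("## ") == 3 and "ΔLOO" in md


def test_fluency_battery_structure(battery_study, battery_config):
    report = run_fluency_split_battery(battery_study, battery_config)
    blocks = report["blocks"]
    assert len(blocks) == 4  # 2 instructions x 2 split methods
    names = {b["subset"] for b in blocks}
    assert names == {"be_fluent/within_person", "be_fluent/within_item",
                     "be_creative/within_person", "be_creative/within_item"}
    for block in blocks:
        assert "error" not in block
        r = float(block["correlation"]["mean"].iloc[0])
        assert block["shared_variance"] == pytest.approx(round(r ** 2, 2))
    md = render_fluency_battery(report)
    assert md.count("## ") == 4 and "shared variance" in md
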