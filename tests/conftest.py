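import warnings

import numpy as np
import pandas as pd
import pytest

from treequal import SamplerConfig, SyntheticConfig, generate_study

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def small_table() -> pd.DataFrame:
    """Hand-written 2-person, 2-item, 2-rater rating table."""
    rows = []
    ratings = {("p1", "aut_brick"): (6, [3, 2]), ("p1", "aut_rope"): (4, [5, 4]),
               ("p2", "aut_brick"): (9, [1, 2]), ("p2", "aut_rope"): (2, [4, 4])}
    for (person, item), (fluency, by_rater) in ratings.items():
        instr = "be_fluent" if item == "aut_brick" else "be_creative"
        for rater, rating in zip(["r1", "r2"], by_rater):
            rows.append(dict(person_id=person, item_id=item, rater_id=rater,
                             instruction=instr, fluency=fluency, rating=rating))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_study():
    """One default-configuration synthetic study (N = 249, 8 items, 2 raters)."""
    return generate_study(SyntheticConfig(seed=20240))


@pytest.fixture
def fast_sampler() -> SamplerConfig:
    """Short chains for structural tests where only shapes/plumbing matter."""
    return SamplerConfig(chains=2, warmup_draws=150, kept_draws=150, seed=99)


def random_rating_table(rng: np.random.Generator, n_persons=20, n_items=4,
                        n_raters=2, n_categories=5) -> pd.DataFrame:
    """Uniform-random valid rating table (no model structure)."""
    rows = []
    for p in range(n_persons):
        for i in range(n_items):
            instr = "be_fluent" if i < n_items // 2 else "be_creative"
            fluency = int(rng.integers(1, 20))
            for k in range(n_raters):
                rows.append(dict(
                    person_id=f"p{p}", item_id=f"i{i}", rater_id=f"r{k}",
                    instruction=instr, fluency=fluency,
                    rating=int(rng.integers(1, n_categories + 1)),
                ))
    return pd.DataFrame(rows)
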