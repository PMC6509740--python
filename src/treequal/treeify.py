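"""Dendrification: ordinal ratings <-> binary sub-items of the linear tree.

A rating of m on an M-point scale is recoded as the outcomes of the first
min(m, M-1) internal nodes of the linear response tree: the pool "passes"
(outcome 1) every node below m and "stops" (outcome 0) at node m; the top
category passes all M-1 nodes.  Nodes after the stop are structurally
missing and appear as absent rows, not as zeros — the sequential model's
Bernoulli factorization conditions only on nodes actually reached.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import RATING_COLUMNS, TreeSpec, validate_ratings

#: Columns of a sub-item table (plus ``fluency_group`` when present upstream).
SUBITEM_COLUMNS = [
    "source_row",
    "person_id",
    "item_id",
    "rater_id",
    "instruction",
    "fluency",
    "fluency_group",
    "node",
    "outcome",
]


class PatternError(ValueError):
    """A group of sub-item rows is not a legal linear-tree pattern."""


def expand_to_subitems(ratings: pd.DataFrame, tree: TreeSpec | None = None) -> pd.DataFrame:
    """Expand each rating into its observed binary sub-item rows.

    Parameters
    ----------
    ratings
        Validated rating table; an optional ``fluency_group`` column
        (from :func:`treequal.study_pipeline.median_split`) is carried along.
    tree
        Response tree (default 5 categories / 4 nodes).

    Returns
    -------
    pandas.DataFrame
        One row per observed node per rating with 1-based ``node``,
        binary ``outcome``, all covariates of the source row, and
        ``source_row`` identifying the originating rating row.
    """
    tree = tree or TreeSpec()
    has_group = "fluency_group" in ratings.columns
    groups = ratings["fluency_group"].to_numpy() if has_group else None
    ratings = validate_ratings(ratings, tree)

    m = ratings["rating"].to_numpy()
    n_obs = np.minimum(m, tree.n_nodes)  # nodes reached per rating
    src = np.repeat(np.arange(len(ratings)), n_obs)
    # within each rating: nodes 1..n_obs
    node = np.concatenate([np.arange(1, k + 1) for k in n_obs]) if len(m) else np.array([], int)
    outcome = (node < m[src]).astype(int)
    # top category passes every node, including the last one it reaches
    outcome[m[src] == tree.n_categories] = 1

    out = ratings.iloc[src].reset_index(drop=True)
    out.insert(0, "source_row", src)
    out["fluency_group"] = groups[src] if has_group else "unassigned"
    out["node"] = node
    out["outcome"] = outcome
    return out.loc[:, SUBITEM_COLUMNS]


def collapse_from_subitems(subitems: pd.DataFrame, tree: TreeSpec | None = None) -> pd.DataFrame:
    """Invert :func:`expand_to_subitems`, recovering one rating per group.

    Raises
    ------
    PatternError
        If a (person, item, rater) group is not a legal pattern: nodes must
        be 1..k contiguous, outcomes all 1 except an optional terminal 0.
    """
    tree = tree or TreeSpec()
    records = []
    keys = ["person_id", "item_id", "rater_id"]
    for key, grp in subitems.groupby(keys, sort=False):
        grp = grp.sort_values("node")
        nodes = grp["node"].to_numpy()
        y = grp["outcome"].to_numpy()
        if not np.array_equal(nodes, np.arange(1, len(nodes) + 1)):
            raise PatternError(f"non-contiguous nodes {nodes.tolist()} for group {key}")
        if np.any(y[:-1] == 0):
            raise PatternError(f"outcome 0 before the last observed node for group {key}")
        if y[-1] == 0:
            rating = int(nodes[-1])
        else:
            if len(nodes) != tree.n_nodes:
                raise PatternError(
                    f"all-pass pattern stops at node {nodes[-1]} (< {tree.n_nodes}) for group {key}"
                )
            rating = tree.n_categories
        rec = grp.iloc[0][["person_id", "item_id", "rater_id", "instruction", "fluency"]].to_dict()
        rec["rating"] = rating
        records.append(rec)
    out = pd.DataFrame.from_records(records, columns=RATING_COLUMNS)
    return validate_ratings(out, tree)
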