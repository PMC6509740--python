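"""Domain types and I/O for snapshot-rating tables.

The observed data live in a long-format :class:`pandas.DataFrame` with one
row per (person, item, rater) triple, carrying the task instruction, the
fluency count of the rated ideational pool, and a 5-point creative-quality
rating.  Functions here validate that schema and read/write it as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Column order of a rating table.
RATING_COLUMNS = ["person_id", "item_id", "rater_id", "instruction", "fluency", "rating"]

#: Recognised instruction labels.
INSTRUCTIONS = ("be_fluent", "be_creative")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates an invariant of the rating table."""


@dataclass(frozen=True)
class TreeSpec:
    """The linear response tree behind an M-point rating scale.

    An M-point ordinal rating is decomposed into ``n_nodes = M - 1``
    sequential binary decisions ("pass this category vs. stop here").
    """

    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("a response tree needs at least 2 categories")

    @property
    def n_nodes(self) -> int:
        return self.n_categories - 1

    @property
    def nodes(self) -> range:
        """1-based node indices Y*_1 ... Y*_R."""
        return range(1, self.n_nodes + 1)


@dataclass(frozen=True)
class StudyDesign:
    """Who rates what: persons x items (each with one instruction) x raters."""

    persons: tuple = ()
    items: tuple = ()  # sequence of (item_id, instruction)
    raters: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "persons", tuple(self.persons))
        object.__setattr__(self, "items", tuple((i, s) for i, s in self.items))
        object.__setattr__(self, "raters", tuple(self.raters))
        for item_id, instruction in self.items:
            if instruction not in INSTRUCTIONS:
                raise ValueError(f"unknown instruction {instruction!r} for item {item_id!r}")
        item_ids = [i for i, _ in self.items]
        if len(set(item_ids)) != len(item_ids):
            raise ValueError("duplicate item_id in design")

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_raters(self) -> int:
        return len(self.raters)


def validate_ratings(table: pd.DataFrame, tree: TreeSpec | None = None) -> pd.DataFrame:
    """Check a rating table against the schema and invariants.

    Parameters
    ----------
    table
        Long-format table with the columns in :data:`RATING_COLUMNS`.
    tree
        Response tree giving the number of categories M (default 5).

    Returns
    -------
    pandas.DataFrame
        The validated table with ``rating`` and ``fluency`` as integers.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If a rating is outside [1, M], a fluency is < 1, or a
        (person, item, rater) triple appears twice.
    """
    tree = tree or TreeSpec()
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    table = table.loc[:, RATING_COLUMNS].copy()
    for col in ("fluency", "rating"):
        try:
            table[col] = pd.to_numeric(table[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued") from exc

    bad = table.index[(table["rating"] < 1) | (table["rating"] > tree.n_categories)]
    if len(bad):
        raise ValidationError(
            f"rating outside [1, {tree.n_categories}] at row index {bad[0]}"
        )
    # a rated pool contains at least one idea
    bad = table.index[table["fluency"] < 1]
    if len(bad):
        raise ValidationError(f"fluency < 1 at row index {bad[0]}")
    bad_instr = set(table["instruction"]) - set(INSTRUCTIONS)
    if bad_instr:
        raise ValidationError(f"unknown instruction label(s): {sorted(bad_instr)}")
    dup = table.duplicated(subset=["person_id", "item_id", "rater_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate (person, item, rater) triple at row index {table.index[dup][0]}"
        )
    per_item = table.groupby("item_id", sort=False)["instruction"].nunique()
    if (per_item > 1).any():
        raise ValidationError(
            f"item {per_item.index[per_item > 1][0]!r} appears under two instructions"
        )
    return table


def read_ratings(path, tree: TreeSpec | None = None) -> pd.DataFrame:
    """Read a CSV rating table and validate it.

    Categorical levels of person/item/rater are kept in first-appearance
    order so that downstream indexing is stable across a write/read cycle.
    """
    table = pd.read_csv(path, dtype={"person_id": str, "item_id": str, "rater_id": str})
    return validate_ratings(table, tree)


def write_ratings(table: pd.DataFrame, path, tree: TreeSpec | None = None) -> None:
    """Validate and write a rating table as CSV (lossless round trip)."""
    validate_ratings(table, tree).to_csv(path, index=False)


def design_from_table(table: pd.DataFrame) -> StudyDesign:
    """Recover the study design (persons, items+instructions, raters) from data."""
    items = table.drop_duplicates("item_id")[["item_id", "instruction"]]
    return StudyDesign(
        persons=tuple(pd.unique(table["person_id"])),
        items=tuple(items.itertuples(index=False, name=None)),
        raters=tuple(pd.unique(table["rater_id"])),
    )
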