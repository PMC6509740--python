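"""Synthetic snapshot-rating studies.

Generates complete studies with the structure the analysis assumes: persons
with multivariate-normal latent creative-quality traits, alternate-uses items
split between be-fluent and be-creative instructions, two raters scoring the
same ideational pool through the sequential tree model, and
instruction-dependent fluency distributions (shifted Poisson, be-fluent
producing larger pools).  The default item thresholds reproduce the sparsity
pattern typical of these instructions: ratings of 5 are vanishingly rare
under be-fluent and ratings of 1 under be-creative, which starves the top
and bottom tree nodes of one outcome class in instruction-specific analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import StudyDesign, TreeSpec, write_ratings
from .tree_model import ModelParameters, Structure, simulate_ratings

# Node thresholds (easiness, logit scale) per instruction.  Chosen so that,
# with theta ~ N(0,1), the marginal rating distribution puts ~0.05% mass on
# 5 under be-fluent and on 1 under be-creative: at the default study size
# (1,992 ratings per instruction) roughly one such rating is expected, which
# leaves the corresponding node with a single observed outcome class.
DEFAULT_BETA_FLUENT = (0.8, -0.5, -1.8, -6.5)
DEFAULT_BETA_CREATIVE = (8.0, 1.5, 0.0, -1.5)

# Mild item easiness offsets so the four items per instruction differ.
DEFAULT_ITEM_OFFSETS = (0.3, 0.1, -0.1, -0.3)


def _compound_symmetric(d: int, rho: float) -> np.ndarray:
    c = np.full((d, d), float(rho))
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SyntheticConfig:
    """Study-design and generative parameters of a synthetic study."""

    n_persons: int = 249
    items_per_instruction: int = 4
    n_raters: int = 2
    n_categories: int = 5
    structure: Structure = "unidimensional"
    latent_corr: float = 0.7       # pairwise correlation (multidimensional structures)
    theta_sd: float = 1.0
    lambda_fluent: float = 10.0    # fluency ~ 1 + Poisson(lambda), per instruction
    lambda_creative: float = 6.0
    beta_fluent: tuple = DEFAULT_BETA_FLUENT
    beta_creative: tuple = DEFAULT_BETA_CREATIVE
    item_offsets: tuple = DEFAULT_ITEM_OFFSETS
    rater_offsets: tuple = (0.0, -0.3)
    fluency_coupling: float = 0.0  # log-rate shift of fluency per unit mean latent trait
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for synthetic studies")
        if len(self.rater_offsets) != self.n_raters:
            raise ValueError("need one rater offset per rater")
        if len(self.item_offsets) != self.items_per_instruction:
            raise ValueError("need one item offset per item within instruction")
        R = self.n_categories - 1
        if len(self.beta_fluent) != R or len(self.beta_creative) != R:
            raise ValueError(f"threshold profiles must have {R} nodes")

    @property
    def tree(self) -> TreeSpec:
        return TreeSpec(self.n_categories)

    @property
    def n_dimensions(self) -> int:
        return {"unidimensional": 1, "fluency_split": 2}.get(
            self.structure, self.n_categories - 1
        )

    def design(self) -> StudyDesign:
        width = len(str(self.n_persons))
        persons = tuple(f"p{i + 1:0{width}d}" for i in range(self.n_persons))
        items = tuple(
            (f"fluent_{j + 1}", "be_fluent") for j in range(self.items_per_instruction)
        ) + tuple(
            (f"creative_{j + 1}", "be_creative") for j in range(self.items_per_instruction)
        )
        raters = tuple(f"r{k + 1}" for k in range(self.n_raters))
        return StudyDesign(persons, items, raters)

    def parameters(self) -> ModelParameters:
        R = self.n_categories - 1
        rows = [np.asarray(self.beta_fluent) + off for off in self.item_offsets]
        rows += [np.asarray(self.beta_creative) + off for off in self.item_offsets]
        d = self.n_dimensions
        corr = _compound_symmetric(d, self.latent_corr) if d > 1 else np.eye(1)
        return ModelParameters(
            beta=np.vstack(rows),
            delta=np.asarray(self.rater_offsets, float),
            theta_sd=np.full(d, self.theta_sd),
            theta_corr=corr,
            structure=self.structure,
        )


@dataclass
class GroundTruth:
    """True generating quantities returned alongside a synthetic table."""

    config: SyntheticConfig
    params: ModelParameters
    theta: np.ndarray          # (P, D) true latent values
    fluency: np.ndarray        # (P, I) pool sizes
    fluency_group: np.ndarray | None = None  # (P, I) low/high labels, fluency_split only

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "params": {
                "beta": self.params.beta.tolist(),
                "delta": self.params.delta.tolist(),
                "theta_sd": self.params.theta_sd.tolist(),
                "theta_corr": self.params.theta_corr.tolist(),
                "structure": self.params.structure,
            },
            "theta": self.theta.tolist(),
            "fluency": self.fluency.tolist(),
            "fluency_group": None if self.fluency_group is None else self.fluency_group.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = SyntheticConfig(**payload["config"])
        params = ModelParameters(**payload["params"])
        fg = payload["fluency_group"]
        return cls(
            config=cfg,
            params=params,
            theta=np.asarray(payload["theta"], float),
            fluency=np.asarray(payload["fluency"], int),
            fluency_group=None if fg is None else np.asarray(fg, object),
        )


def generate_study(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one complete synthetic study.

    Latent vectors come from the configured multivariate normal; fluency
    counts from 1 + Poisson(lambda_instruction), optionally rate-modulated
    by the person's mean latent trait (``fluency_coupling``); ratings from
    the sequential tree model, both raters scoring the same pool with
    independent node-level noise.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design()
    params = config.parameters()
    P, I = design.n_persons, design.n_items

    cov = params.theta_cov
    if np.linalg.eigvalsh(cov).min() < -1e-10:
        raise ValueError("latent covariance is not positive semi-definite")
    theta = rng.multivariate_normal(np.zeros(params.n_dimensions), cov, size=P,
                                    method="cholesky")

    lam = np.array([
        config.lambda_fluent if instr == "be_fluent" else config.lambda_creative
        for _, instr in design.items
    ])
    log_shift = config.fluency_coupling * theta.mean(axis=1)
    rates = lam[None, :] * np.exp(log_shift)[:, None]
    fluency = 1 + rng.poisson(rates)

    fluency_group = None
    if config.structure == "fluency_split":
        fluency_group = _split_labels(design, fluency)

    sim_seed = int(rng.integers(0, 2**31 - 1))
    table = simulate_ratings(design, params, theta, seed=sim_seed,
                             fluency=fluency, fluency_group=fluency_group)
    truth = GroundTruth(config, params, theta, fluency, fluency_group)
    return table, truth


def _split_labels(design: StudyDesign, fluency: np.ndarray) -> np.ndarray:
    """Within-person, within-instruction strictly-below-median low/high labels."""
    instr = np.array([s for _, s in design.items])
    labels = np.empty(fluency.shape, dtype=object)
    for s in ("be_fluent", "be_creative"):
        cols = instr == s
        med = np.median(fluency[:, cols], axis=1, keepdims=True)
        labels[:, cols] = np.where(fluency[:, cols] < med, "low", "high")
    return labels


FIXTURE_NAMES = ("unidimensional", "node_multidimensional", "fluency_split", "sparse_nodes")


def fixture_config(name: str, seed: int) -> SyntheticConfig:
    """Canonical small-study configurations used by the test suite."""
    base = dict(seed=seed)
    if name == "unidimensional":
        return SyntheticConfig(structure="unidimensional", **base)
    if name == "node_multidimensional":
        return SyntheticConfig(structure="node_multidimensional", latent_corr=0.7, **base)
    if name == "fluency_split":
        return SyntheticConfig(structure="fluency_split", latent_corr=0.7, **base)
    if name == "sparse_nodes":
        # exaggerated sparsity: the top be-fluent and bottom be-creative
        # nodes receive (essentially) no minority-class observations
        return SyntheticConfig(
            structure="unidimensional",
            beta_fluent=(0.8, -0.5, -1.8, -9.0),
            beta_creative=(11.0, 1.5, 0.0, -1.5),
            **base,
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture_suite(out_dir, seed: int) -> dict[str, dict[str, Path]]:
    """Write the canonical fixture set (ratings CSV + ground-truth JSON).

    Regeneration with the same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    written: dict[str, dict[str, Path]] = {}
    for name, child in zip(FIXTURE_NAMES, ss.spawn(len(FIXTURE_NAMES))):
        cfg = fixture_config(name, seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        table, truth = generate_study(cfg)
        csv_path = out_dir / f"{name}.csv"
        json_path = out_dir / f"{name}.truth.json"
        write_ratings(table, csv_path)
        truth.to_json(json_path)
        written[name] = {"ratings": csv_path, "truth": json_path}
    return written
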