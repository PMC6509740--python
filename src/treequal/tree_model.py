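"""The sequential logistic node model.

Each internal node r of the linear response tree is a Bernoulli sub-item:

    P(pass node r) = logistic(theta_{p,d(r)} + beta_{i,r} + delta_k)

with theta the person's latent creative-quality trait on the dimension the
node maps to, beta an item-by-node easiness threshold, and delta a rater
fixed effect controlling rater leniency (reference rater fixed at 0).  This
is a Rasch-type tree: no discrimination parameters.  The category
distribution follows by walking the tree: stay at category m by failing
node m after passing nodes 1..m-1; the top category passes every node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core_data import RATING_COLUMNS, StudyDesign, TreeSpec

Structure = Literal["unidimensional", "node_multidimensional", "fluency_split"]

_FLUENCY_LEVELS = ("low", "high")


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError("correlation matrix must be positive semi-definite")
    return corr


@dataclass
class ModelParameters:
    """Parameters of one sequential tree model.

    Attributes
    ----------
    beta
        Item-by-node thresholds, shape (I, R), logit scale (easiness: added
        to theta, so larger beta means the node is easier to pass).
    delta
        Rater offsets, one per rater, logit scale; the first (reference)
        rater must be 0.
    theta_sd
        Latent standard deviation per dimension.
    theta_corr
        Correlation matrix among latent dimensions.
    structure
        Which latent structure the dimensions encode: one trait for the
        whole scale, one per tree node, or low-/high-fluency traits.
    """

    beta: np.ndarray
    delta: np.ndarray
    theta_sd: np.ndarray
    theta_corr: np.ndarray
    structure: Structure = "unidimensional"

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, float))
        self.delta = np.asarray(self.delta, float)
        self.theta_sd = np.atleast_1d(np.asarray(self.theta_sd, float))
        self.theta_corr = _check_corr(np.atleast_2d(self.theta_corr))
        if np.any(self.theta_sd <= 0):
            raise ValueError("latent standard deviations must be positive")
        if len(self.delta) and self.delta[0] != 0.0:
            raise ValueError("reference rater offset must be 0")
        d = self.n_dimensions
        if self.theta_sd.shape != (d,) or self.theta_corr.shape != (d, d):
            raise ValueError("theta_sd/theta_corr shape inconsistent")
        expected = {"unidimensional": 1, "fluency_split": 2}.get(self.structure)
        if expected is not None and d != expected:
            raise ValueError(f"{self.structure} structure requires {expected} dimension(s)")
        if self.structure == "node_multidimensional" and d != self.beta.shape[1]:
            raise ValueError("node_multidimensional requires one dimension per node")

    @property
    def n_items(self) -> int:
        return self.beta.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.beta.shape[1]

    @property
    def n_dimensions(self) -> int:
        return len(self.theta_sd)

    @property
    def theta_cov(self) -> np.ndarray:
        return self.theta_corr * np.outer(self.theta_sd, self.theta_sd)

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.tolist(),
            "delta": self.delta.tolist(),
            "theta_sd": self.theta_sd.tolist(),
            "theta_corr": self.theta_corr.tolist(),
            "structure": self.structure,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: payload[k] for k in ("beta", "delta", "theta_sd", "theta_corr", "structure")})


@dataclass(frozen=True)
class DimensionMap:
    """Rule assigning each sub-item row to a latent dimension index (0-based).

    For ``node_multidimensional`` the mapping runs over the *retained* nodes
    (``nodes``), so models refit after omitting non-informative nodes stay
    well-defined; for ``fluency_split`` dimension 0 is low-fluency and 1 is
    high-fluency.
    """

    structure: Structure
    nodes: tuple = ()  # retained 1-based node indices, node_multidimensional only

    @property
    def n_dimensions(self) -> int:
        if self.structure == "unidimensional":
            return 1
        if self.structure == "fluency_split":
            return 2
        return len(self.nodes)

    def dimension_labels(self) -> list[str]:
        if self.structure == "unidimensional":
            return ["theta"]
        if self.structure == "fluency_split":
            return ["low_fluency", "high_fluency"]
        return [f"node_{r}" for r in self.nodes]

    def assign(self, subitems: pd.DataFrame) -> np.ndarray:
        """Return the 0-based dimension index of every sub-item row."""
        if self.structure == "unidimensional":
            return np.zeros(len(subitems), dtype=int)
        if self.structure == "fluency_split":
            groups = subitems["fluency_group"].to_numpy()
            unknown = ~np.isin(groups, _FLUENCY_LEVELS)
            if unknown.any():
                raise ValueError(
                    "fluency_split structure needs a low/high fluency_group on every "
                    f"row; found {groups[unknown][0]!r} — run median_split first"
                )
            return (groups == "high").astype(int)
        lookup = {r: d for d, r in enumerate(self.nodes)}
        nodes = subitems["node"].to_numpy()
        try:
            return np.array([lookup[r] for r in nodes], dtype=int)
        except KeyError as exc:
            raise ValueError(f"sub-item at node {exc.args[0]} has no latent dimension") from exc

    @classmethod
    def for_structure(cls, structure: Structure, tree: TreeSpec | None = None,
                      nodes: tuple | None = None) -> "DimensionMap":
        if structure == "node_multidimensional":
            if nodes is None:
                tree = tree or TreeSpec()
                nodes = tuple(tree.nodes)
            return cls(structure, tuple(nodes))
        return cls(structure)


def node_pass_probability(theta, beta, delta=0.0):
    """P(pass a node) = logistic(theta + beta + delta); broadcasts over arrays."""
    eta = np.asarray(theta, float) + np.asarray(beta, float) + np.asarray(delta, float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    # numerically stable logistic
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def category_probabilities(theta_by_node, beta_by_node, delta=0.0) -> np.ndarray:
    """Distribution over the M rating categories implied by the node model.

    P(Y=m) = (1 - p_m) * prod_{r<m} p_r for m <= R and P(Y=M) = prod_r p_r,
    where p_r is the pass probability at node r.
    """
    theta_by_node = np.atleast_1d(np.asarray(theta_by_node, float))
    beta_by_node = np.atleast_1d(np.asarray(beta_by_node, float))
    if theta_by_node.shape != beta_by_node.shape:
        raise ValueError("theta_by_node and beta_by_node must have equal length")
    p = node_pass_probability(theta_by_node, beta_by_node, delta)
    reach = np.concatenate([[1.0], np.cumprod(p)])  # P(reach node m), reach[R] = P(top)
    probs = np.empty(len(p) + 1)
    probs[:-1] = reach[:-1] * (1.0 - p)
    probs[-1] = reach[-1]
    return probs


def _row_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bernoulli log-likelihood per row; log sigma(eta) if y=1 else log sigma(-eta)."""
    return -np.logaddexp(0.0, np.where(y == 1, -eta, eta))


def linear_predictor(params: ModelParameters, theta: np.ndarray,
                     subitems: pd.DataFrame, dmap: DimensionMap,
                     item_order: list | None = None,
                     rater_order: list | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-row linear predictor eta and outcome y for a sub-item table."""
    items = item_order if item_order is not None else list(pd.unique(subitems["item_id"]))
    raters = rater_order if rater_order is not None else list(pd.unique(subitems["rater_id"]))
    item_idx = pd.Categorical(subitems["item_id"], categories=items).codes
    rater_idx = pd.Categorical(subitems["rater_id"], categories=raters).codes
    if (item_idx < 0).any() or (rater_idx < 0).any():
        raise ValueError("sub-item row references an item/rater missing from the parameters")
    node_idx = subitems["node"].to_numpy() - 1
    dim_idx = dmap.assign(subitems)
    persons = pd.Categorical(
        subitems["person_id"], categories=pd.unique(subitems["person_id"])
    ).codes
    eta = (
        theta[persons, dim_idx]
        + params.beta[item_idx, node_idx]
        + params.delta[rater_idx]
    )
    return eta, subitems["outcome"].to_numpy()


def log_likelihood(params: ModelParameters, theta: np.ndarray,
                   subitems: pd.DataFrame, dmap: DimensionMap) -> tuple[float, np.ndarray]:
    """Bernoulli log-likelihood of a sub-item table.

    Parameters
    ----------
    theta
        Per-person latent values, shape (P, D), rows ordered by first
        appearance of ``person_id`` in ``subitems``.

    Returns
    -------
    total, pointwise
        The summed log-likelihood and the per-row vector (the pointwise
        unit used by LOO).
    """
    eta, y = linear_predictor(params, np.atleast_2d(np.asarray(theta, float)), subitems, dmap)
    pointwise = _row_loglik(eta, y)
    return float(pointwise.sum()), pointwise


def simulate_ratings(design: StudyDesign, params: ModelParameters,
                     theta: np.ndarray, seed, fluency=None,
                     fluency_group=None) -> pd.DataFrame:
    """Draw a rating table from the sequential model.

    Every (person, item, rater) walks the tree nodes 1..R and stops at the
    first failed node; passing all R nodes yields the top category.

    Parameters
    ----------
    theta
        True latent values, shape (P, D).
    fluency
        Optional (P, I) fluency counts to attach (default 1).
    fluency_group
        Optional (P, I) array of "low"/"high" labels; required when
        ``params.structure == "fluency_split"``.
    """
    rng = np.random.default_rng(seed)
    P, I, K = design.n_persons, design.n_items, design.n_raters
    R = params.n_nodes
    theta = np.atleast_2d(np.asarray(theta, float))
    if theta.shape[0] != P:
        raise ValueError("theta must have one row per person")

    if params.structure == "unidimensional":
        dim = np.zeros((P, I, R), dtype=int)
    elif params.structure == "node_multidimensional":
        dim = np.broadcast_to(np.arange(R), (P, I, R))
    else:
        if fluency_group is None:
            raise ValueError("fluency_split simulation needs fluency_group labels")
        dim = np.broadcast_to((np.asarray(fluency_group) == "high").astype(int)[:, :, None], (P, I, R))

    # linear predictor over (P, I, K, R)
    eta = theta[np.arange(P)[:, None, None], dim][:, :, None, :] \
        + params.beta[None, :, None, :] \
        + params.delta[None, None, :, None]
    p = 0.5 * (1.0 + np.tanh(0.5 * eta))
    passes = rng.random((P, I, K, R)) < p
    # rating = 1 + number of initial consecutive passes
    stopped = np.cumprod(passes, axis=-1)
    rating = 1 + stopped.sum(axis=-1)

    if fluency is None:
        fluency = np.ones((P, I), dtype=int)
    fluency = np.asarray(fluency)

    pi, ii, ki = np.meshgrid(np.arange(P), np.arange(I), np.arange(K), indexing="ij")
    table = pd.DataFrame({
        "person_id": np.asarray(design.persons, object)[pi.ravel()],
        "item_id": np.asarray([i for i, _ in design.items], object)[ii.ravel()],
        "rater_id": np.asarray(design.raters, object)[ki.ravel()],
        "instruction": np.asarray([s for _, s in design.items], object)[ii.ravel()],
        "fluency": fluency[pi.ravel(), ii.ravel()],
        "rating": rating.ravel(),
    })
    return table.loc[:, RATING_COLUMNS]
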