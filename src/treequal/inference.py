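"""Bayesian posterior sampling for the sequential tree models.

The sampler is a Polya-Gamma augmented Gibbs scheme written directly in
NumPy.  With omega_i ~ PG(1, eta_i) attached to every binary sub-item, the
logistic likelihood is conditionally Gaussian, so per sweep:

* each person's latent vector theta_p is an exact multivariate-normal draw
  (batched over persons),
* each item-by-node threshold beta_ir and each non-reference rater offset
  delta_k is an exact normal draw (rows partition by cell / rater),
* the latent covariance is updated by independence Metropolis-Hastings with
  an inverse-Wishart proposal matched to the current latent scatter (the
  accept step corrects for the half-normal scale / LKJ correlation prior),
* two families of interweaved moves operate on the marginal posterior to
  cross the theta-Sigma funnel and the theta-beta translation degeneracy:
  scalar ancillary moves that rescale one latent scale or re-rotate one
  correlation entry with the whitened residuals held fixed, and
  likelihood-invariant translations trading location between theta and the
  matching thresholds.

Proposal scales are tuned during warmup by Robbins-Monro adaptation toward
a target acceptance rate and then frozen, so kept draws come from a fixed
Markov kernel.  Latent means are fixed at zero and the first rater offset at
zero for identification.  Everything needed by PSIS-LOO (the pointwise
log-likelihood of every sub-item row at every kept draw) is stored on the
returned fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .core_data import StudyDesign, TreeSpec
from ._polya_gamma import sample_pg1
from .tree_model import DimensionMap, Structure, _row_loglik


class IdentificationError(ValueError):
    """A tree node has a single observed outcome class.

    The item thresholds of such a node are not identified by the data; run
    :func:`detect_noninformative_nodes` and :func:`omit_nodes` first.
    """


@dataclass(frozen=True)
class SamplerConfig:
    """Desk-scale MCMC settings (2 chains x 500 warmup + 500 kept draws)."""

    chains: int = 2
    warmup_draws: int = 500
    kept_draws: int = 500
    seed: int = 0
    target_accept: float = 0.35

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-R-hat")
        if self.warmup_draws <= 0 or self.kept_draws <= 0:
            raise ValueError("draw counts must be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors (the data sets none of these tightly)."""

    beta_prior_scale: float = 2.5
    delta_prior_scale: float = 2.5
    sd_prior: float = 2.0        # half-normal scale on latent SDs
    corr_prior_shape: float = 1.0  # LKJ concentration

    def __post_init__(self) -> None:
        for name in ("beta_prior_scale", "delta_prior_scale", "sd_prior", "corr_prior_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --------------------------------------------------------------------------
# latent covariance: half-normal scales x LKJ correlation, expressed on Sigma

def _sigma_log_prior(cov: np.ndarray, prec: np.ndarray, logdet: float,
                     priors: "PriorConfig") -> float:
    """Log prior density of the latent covariance, up to a constant.

    The prior is placed on the (scale, correlation) decomposition —
    half-normal(sd_prior) per scale, LKJ(corr_prior_shape) on the
    correlation matrix — and mapped to Sigma-space with the Jacobian of
    (sigma, C) -> Sigma, which is proportional to prod sigma_d^D.
    """
    sd2 = np.diag(cov)
    if np.any(sd2 <= 0):
        return -np.inf
    log_sd = 0.5 * np.log(sd2)
    d = cov.shape[0]
    log_det_corr = logdet - 2.0 * log_sd.sum()
    lp = float(np.sum(-sd2 / (2.0 * priors.sd_prior ** 2)))          # half-normal kernel
    lp += (priors.corr_prior_shape - 1.0) * log_det_corr             # LKJ kernel
    lp -= d * float(log_sd.sum())                                    # (sigma, C) -> Sigma Jacobian
    return lp


def _bartlett_wishart(rng: np.ndarray, nu: float, root: np.ndarray) -> np.ndarray:
    """One Wishart(nu, V) draw given any square root `root` with root@root.T = V."""
    d = root.shape[0]
    a = np.zeros((d, d))
    a[np.tril_indices(d, -1)] = rng.standard_normal(d * (d - 1) // 2)
    a[np.diag_indices(d)] = np.sqrt(rng.chisquare(nu - np.arange(d)))
    m = root @ a
    return m @ m.T


# --------------------------------------------------------------------------
# fit container

@dataclass
class PosteriorFit:
    """Posterior draws plus everything LOO and diagnostics need."""

    structure: Structure
    tree: TreeSpec
    dmap: DimensionMap
    persons: list
    items: list
    raters: list
    nodes: list                       # retained 1-based node indices
    cells: list                       # (item_id, node) per beta entry
    obs_ids: np.ndarray               # one id per sub-item row, order preserved
    posterior: dict                   # name -> array (chain, draw, ...)
    log_lik: np.ndarray               # (chain, draw, n_obs) float32
    sampler: SamplerConfig
    priors: PriorConfig
    accept_rates: pd.DataFrame | None = None
    warnings_: list = field(default_factory=list)

    @property
    def n_dimensions(self) -> int:
        return self.posterior["sigma"].shape[-1]

    @property
    def dimension_labels(self) -> list[str]:
        return self.dmap.dimension_labels()

    @cached_property
    def idata(self) -> az.InferenceData:
        dim_labels = self.dimension_labels
        coords = {
            "cell": [f"{i}:{r}" for i, r in self.cells],
            "rater": list(self.raters),
            "latent_dim": dim_labels,
            "latent_dim2": dim_labels,
            "person": list(self.persons),
            "obs": list(self.obs_ids),
        }
        dims = {
            "beta": ["cell"],
            "delta": ["rater"],
            "sigma": ["latent_dim"],
            "corr": ["latent_dim", "latent_dim2"],
            "theta": ["person", "latent_dim"],
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return az.from_dict(
                posterior=self.posterior,
                log_likelihood={"y": self.log_lik.astype(np.float64)},
                coords=coords,
                dims={**dims, "y": ["obs"]},
            )

    @cached_property
    def rhat(self) -> pd.Series:
        """Split-R-hat for every scalar parameter (max over elements per name)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.rhat(self.idata.posterior)
        return pd.Series({name: float(ds[name].max()) for name in ds.data_vars})

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def converged(self) -> bool:
        return self.max_rhat <= 1.05

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chain and draw axes merged."""
        arr = self.posterior[name]
        return arr.reshape(-1, *arr.shape[2:])

    def _row_indices(self, subitems: pd.DataFrame) -> tuple[np.ndarray, ...]:
        cell_lookup = {c: k for k, c in enumerate(self.cells)}
        person_lookup = {p: k for k, p in enumerate(self.persons)}
        rater_lookup = {r: k for k, r in enumerate(self.raters)}
        try:
            p_idx = np.array([person_lookup[p] for p in subitems["person_id"]])
            c_idx = np.array([cell_lookup[(i, r)] for i, r in
                              zip(subitems["item_id"], subitems["node"])])
            k_idx = np.array([rater_lookup[r] for r in subitems["rater_id"]])
        except KeyError as exc:
            raise ValueError(f"row references {exc.args[0]!r} unknown to this fit") from exc
        d_idx = self.dmap.assign(subitems)
        return p_idx, c_idx, k_idx, d_idx

    def log_predictive(self, subitems: pd.DataFrame) -> np.ndarray:
        """log posterior-predictive density of sub-item rows, one per row.

        Computes log mean over draws of the Bernoulli likelihood — the
        quantity exact leave-one-out cross-validation needs for held-out
        observations.
        """
        p_idx, c_idx, k_idx, d_idx = self._row_indices(subitems)
        y = subitems["outcome"].to_numpy()
        theta = self.stacked("theta")    # (S, P, D)
        beta = self.stacked("beta")      # (S, C)
        delta = self.stacked("delta")    # (S, K)
        eta = theta[:, p_idx, d_idx] + beta[:, c_idx] + delta[:, k_idx]
        ll = _row_loglik(eta, y[None, :])
        s = ll.shape[0]
        from scipy.special import logsumexp
        return logsumexp(ll, axis=0) - np.log(s)

    def to_json(self, path) -> None:
        """JSON draws file with named dimensions (portable fallback format)."""
        import json
        payload = {
            "structure": self.structure,
            "dims": {
                "cell": [f"{i}:{r}" for i, r in self.cells],
                "rater": list(map(str, self.raters)),
                "latent_dim": self.dimension_labels,
                "person": list(map(str, self.persons)),
            },
            "posterior": {k: v.tolist() for k, v in self.posterior.items() if k != "theta"},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# --------------------------------------------------------------------------
# data preparation

def _prepare(subitems: pd.DataFrame, structure: Structure, tree: TreeSpec,
             design: StudyDesign | None):
    if design is not None:
        persons = list(design.persons)
        items = [i for i, _ in design.items]
        raters = list(design.raters)
    else:
        if len(subitems) == 0:
            raise ValueError("empty sub-item table needs an explicit design (prior-only fit)")
        persons = list(pd.unique(subitems["person_id"]))
        items = list(pd.unique(subitems["item_id"]))
        raters = list(pd.unique(subitems["rater_id"]))

    if len(subitems):
        nodes = sorted(pd.unique(subitems["node"]).tolist())
    else:
        nodes = list(tree.nodes)
    cells = [(i, r) for i in items for r in nodes]

    dmap = DimensionMap.for_structure(structure, tree, nodes=tuple(nodes))

    if len(subitems):
        person_idx = pd.Categorical(subitems["person_id"], categories=persons).codes.astype(int)
        cell_lookup = {c: k for k, c in enumerate(cells)}
        cell_idx = np.array([cell_lookup[(i, r)] for i, r in
                             zip(subitems["item_id"], subitems["node"])])
        rater_idx = pd.Categorical(subitems["rater_id"], categories=raters).codes.astype(int)
        if (person_idx < 0).any() or (rater_idx < 0).any():
            raise ValueError("sub-item row references a person/rater missing from the design")
        dim_idx = dmap.assign(subitems)
        y = subitems["outcome"].to_numpy().astype(int)
        # identification pre-check, per retained node
        node_arr = subitems["node"].to_numpy()
        for r in nodes:
            y_r = y[node_arr == r]
            if len(y_r) and (y_r.min() == y_r.max()):
                raise IdentificationError(
                    f"node {r} has a single outcome class ({y_r[0]}); "
                    "use detect_noninformative_nodes/omit_nodes before fitting"
                )
        obs_ids = np.array([
            f"{p}|{i}|{k}|{r}" for p, i, k, r in zip(
                subitems["person_id"], subitems["item_id"],
                subitems["rater_id"], subitems["node"])
        ])
    else:
        person_idx = np.zeros(0, int)
        cell_idx = np.zeros(0, int)
        rater_idx = np.zeros(0, int)
        dim_idx = np.zeros(0, int)
        y = np.zeros(0, int)
        obs_ids = np.array([], dtype=str)

    return dict(
        persons=persons, items=items, raters=raters, nodes=nodes, cells=cells,
        dmap=dmap, person_idx=person_idx, cell_idx=cell_idx, rater_idx=rater_idx,
        dim_idx=dim_idx, y=y, obs_ids=obs_ids,
    )


# --------------------------------------------------------------------------
# one chain: Polya-Gamma augmented Gibbs with covariance interweaving

def _run_chain(prep: dict, priors: PriorConfig, sampler: SamplerConfig, seed) -> dict:
    rng = np.random.default_rng(seed)
    P = len(prep["persons"])
    C = len(prep["cells"])
    K = len(prep["raters"])
    D = prep["dmap"].n_dimensions
    person_idx, cell_idx, rater_idx, dim_idx, y = (
        prep["person_idx"], prep["cell_idx"], prep["rater_idx"], prep["dim_idx"], prep["y"]
    )
    n = len(y)
    sign = np.where(y == 1, -1.0, 1.0)
    kappa = y - 0.5
    pd_key = person_idx * D + dim_idx  # flattened (person, dim) bincount key
    dim_rows = np.arange(D)
    eye = np.eye(D)

    def rowll(eta):
        return -np.logaddexp(0.0, sign * eta)

    # state
    beta = np.zeros(C)
    delta = np.zeros(K)
    theta = 0.1 * rng.standard_normal((P, D))
    cov = np.eye(D)
    lam = np.eye(D)   # precision of the latent prior
    logdet = 0.0      # log |cov|

    # translation moves (theta_d + c, matching beta cells - c) leave the
    # likelihood invariant only when the cell partition refines the
    # dimension partition: all cells for one trait, node-r cells for the
    # node-r trait.  The low/high-fluency split crosses cells, so no move.
    cell_nodes = np.array([r for _, r in prep["cells"]])
    if prep["dmap"].structure == "unidimensional":
        trans_cells = [np.arange(C)]
    elif prep["dmap"].structure == "node_multidimensional":
        trans_cells = [np.flatnonzero(cell_nodes == r) for r in prep["nodes"]]
    else:
        trans_cells = None

    step_trans = np.full(D, np.log(0.1))
    step_scale = np.full(D, np.log(0.15))
    dim_pairs = [(i, j) for i in range(D - 1) for j in range(i + 1, D)]
    step_corr = np.full(len(dim_pairs), np.log(0.2))
    rows_by_dim = [np.flatnonzero(dim_idx == d) for d in range(D)]
    rows_from_dim = [np.flatnonzero(dim_idx >= d) for d in range(D)]
    target = sampler.target_accept

    n_iter = sampler.warmup_draws + sampler.kept_draws
    kept = sampler.kept_draws
    out_beta = np.empty((kept, C))
    out_delta = np.empty((kept, K))
    out_sigma = np.empty((kept, D))
    out_corr = np.empty((kept, D, D))
    out_theta = np.empty((kept, P, D), dtype=np.float32)
    out_ll = np.empty((kept, n), dtype=np.float32)
    acc_count = {"trans": 0.0, "cov_suff": 0.0, "cov_scale": 0.0, "cov_corr": 0.0}

    eta = theta[person_idx, dim_idx] + beta[cell_idx] + delta[rater_idx]
    ll_row = rowll(eta)

    for t in range(n_iter):
        adapt = t < sampler.warmup_draws
        kappa_t = (t + 10.0) ** -0.6 if adapt else 0.0

        # ---- Polya-Gamma augmentation: omega_i | eta_i exactly
        if n:
            omega = sample_pg1(rng, eta)

        # ---- theta | omega: exact multivariate-normal draw per person
        if n:
            offset = beta[cell_idx] + delta[rater_idx]
            w_pd = np.bincount(pd_key, weights=omega, minlength=P * D).reshape(P, D)
            r_pd = np.bincount(pd_key, weights=kappa - omega * offset,
                               minlength=P * D).reshape(P, D)
        else:
            w_pd = np.zeros((P, D))
            r_pd = np.zeros((P, D))
        prec = np.broadcast_to(lam, (P, D, D)).copy()
        prec[:, dim_rows, dim_rows] += w_pd
        cov_p = np.linalg.inv(prec)
        mean_p = np.einsum("pde,pe->pd", cov_p, r_pd)
        chol_p = np.linalg.cholesky(cov_p)
        theta = mean_p + np.einsum("pde,pe->pd", chol_p, rng.standard_normal((P, D)))

        # ---- beta | omega: exact normal draw per item-node cell
        if n:
            base = theta[person_idx, dim_idx] + delta[rater_idx]
            prec_c = np.bincount(cell_idx, weights=omega, minlength=C) \
                + priors.beta_prior_scale ** -2
            lin_c = np.bincount(cell_idx, weights=kappa - omega * base, minlength=C)
        else:
            prec_c = np.full(C, priors.beta_prior_scale ** -2)
            lin_c = np.zeros(C)
        beta = lin_c / prec_c + rng.standard_normal(C) / np.sqrt(prec_c)

        # ---- delta | omega: exact normal draw per non-reference rater
        if K > 1:
            if n:
                base = theta[person_idx, dim_idx] + beta[cell_idx]
                prec_k = np.bincount(rater_idx, weights=omega, minlength=K) \
                    + priors.delta_prior_scale ** -2
                lin_k = np.bincount(rater_idx, weights=kappa - omega * base, minlength=K)
            else:
                prec_k = np.full(K, priors.delta_prior_scale ** -2)
                lin_k = np.zeros(K)
            draw = lin_k / prec_k + rng.standard_normal(K) / np.sqrt(prec_k)
            delta = np.where(np.arange(K) == 0, 0.0, draw)

        if n:
            eta = theta[person_idx, dim_idx] + beta[cell_idx] + delta[rater_idx]
            ll_row = rowll(eta)

        # ---- latent covariance | theta: independence MH with an
        # inverse-Wishart proposal matched to the current latent scatter;
        # the accept step corrects for the half-normal/LKJ prior
        scatter = theta.T @ theta + 1e-8 * eye
        nu = P + D + 1.0
        l_scatter = cholesky(scatter, lower=True)
        root = solve_triangular(l_scatter, eye, lower=True).T  # root@root.T = inv(scatter)
        wish = _bartlett_wishart(rng, nu, root)
        try:
            l_wish = cholesky(wish, lower=True)
        except np.linalg.LinAlgError:
            l_wish = None
        if l_wish is not None:
            linv = solve_triangular(l_wish, eye, lower=True)
            lam_prop = wish                   # proposed precision
            cov_prop = linv.T @ linv          # its inverse
            logdet_prop = -2.0 * float(np.sum(np.log(np.diag(l_wish))))

            def _score(cv, pr, ld):
                # target: MVN likelihood of theta + prior; proposal: IW(nu, scatter)
                lik = -0.5 * P * ld - 0.5 * float(np.sum(pr * scatter))
                prop = -0.5 * (nu + D + 1) * ld - 0.5 * float(np.sum(scatter * pr))
                return lik + _sigma_log_prior(cv, pr, ld, priors) - prop

            acc_s = np.log(rng.random()) < _score(cov_prop, lam_prop, logdet_prop) \
                - _score(cov, lam, logdet)
            if acc_s:
                cov, lam, logdet = cov_prop, lam_prop, logdet_prop
            if t >= sampler.warmup_draws:
                acc_count["cov_suff"] += float(acc_s)

        # ---- translation move: theta_d + c, compensating beta cells - c;
        # likelihood-invariant, accepted on the prior ratio alone (valid on
        # the marginal posterior; omega is refreshed next sweep)
        if trans_cells is not None:
            for d in range(D):
                c_move = np.exp(step_trans[d]) * rng.standard_normal()
                cells_d = trans_cells[d]
                dp_theta = -(c_move * float((theta @ lam[:, d]).sum())
                             + 0.5 * P * c_move ** 2 * lam[d, d])
                dp_beta = float(np.sum(2 * beta[cells_d] * c_move - c_move ** 2)) / (
                    2 * priors.beta_prior_scale ** 2)
                acc_t = np.log(rng.random()) < dp_theta + dp_beta
                if acc_t:
                    theta[:, d] += c_move
                    beta[cells_d] -= c_move
                if adapt:
                    step_trans[d] += kappa_t * (float(acc_t) - target)
                if t >= sampler.warmup_draws:
                    acc_count["trans"] += float(acc_t) / D

        # ---- ancillary moves on the latent covariance: hold the whitened
        # residuals fixed and move one scale or one correlation at a time,
        # carrying theta along.  These scalar moves cross the theta-Sigma
        # funnel in exactly the directions the conditional updates above
        # leave slow — dimensions with few observations per person.  Two
        # rounds per sweep: each move costs only a partial likelihood pass
        # and the covariance is the slowest-mixing block of the posterior.
        sd = np.sqrt(np.diag(cov))
        corr_m = cov / np.outer(sd, sd)
        np.fill_diagonal(corr_m, 1.0)
        for _ in range(2):
            # scale moves: sigma_d and theta[:, d] rescale together
            for d in range(D):
                h = np.exp(step_scale[d]) * rng.standard_normal()
                ratio = np.exp(h)
                s_new = sd[d] * ratio
                rows_d = rows_by_dim[d]
                if rows_d.size:
                    eta_new = eta[rows_d] + (ratio - 1.0) * theta[person_idx[rows_d], d]
                    ll_new = -np.logaddexp(0.0, sign[rows_d] * eta_new)
                    dlik = float(ll_new.sum() - ll_row[rows_d].sum())
                else:
                    dlik = 0.0
                # half-normal prior on sigma with a log-scale proposal
                dprior = -(s_new ** 2 - sd[d] ** 2) / (2.0 * priors.sd_prior ** 2) + h
                acc_sc = np.log(rng.random()) < dlik + dprior
                if acc_sc:
                    theta[:, d] *= ratio
                    sd[d] = s_new
                    if rows_d.size:
                        eta[rows_d] = eta_new
                        ll_row[rows_d] = ll_new
                if adapt:
                    step_scale[d] += kappa_t * (float(acc_sc) - 0.44)
                if t >= sampler.warmup_draws:
                    acc_count["cov_scale"] += float(acc_sc) / (2 * D)

            # correlation moves: perturb one entry, re-rotate theta through
            # the new correlation Cholesky (whitened residuals fixed)
            if D > 1:
                l_corr = cholesky(corr_m, lower=True)
                for q, (i, j) in enumerate(dim_pairs):
                    c_new = corr_m[i, j] + np.exp(step_corr[q]) * rng.standard_normal()
                    acc_cr = False
                    if abs(c_new) < 1.0:
                        corr_new = corr_m.copy()
                        corr_new[i, j] = corr_new[j, i] = c_new
                        try:
                            l_new = cholesky(corr_new, lower=True)
                        except np.linalg.LinAlgError:
                            l_new = None
                        if l_new is not None:
                            # theta* = theta M^T with
                            # M = diag(sd) L_new L^-1 diag(1/sd); Cholesky
                            # rows before j are untouched, so only
                            # dimensions >= j move
                            rot = l_new @ solve_triangular(l_corr, eye, lower=True)
                            m_mat = (sd[:, None] * rot) / sd[None, :]
                            theta_star = theta @ m_mat.T
                            rows_a = rows_from_dim[j]
                            if rows_a.size:
                                eta_new = eta[rows_a] + (
                                    theta_star[person_idx[rows_a], dim_idx[rows_a]]
                                    - theta[person_idx[rows_a], dim_idx[rows_a]]
                                )
                                ll_new = -np.logaddexp(0.0, sign[rows_a] * eta_new)
                                dlik = float(ll_new.sum() - ll_row[rows_a].sum())
                            else:
                                dlik = 0.0
                            dprior = 2.0 * (priors.corr_prior_shape - 1.0) * float(
                                np.sum(np.log(np.diag(l_new) / np.diag(l_corr)))
                            )
                            acc_cr = np.log(rng.random()) < dlik + dprior
                            if acc_cr:
                                theta = theta_star
                                corr_m, l_corr = corr_new, l_new
                                if rows_a.size:
                                    eta[rows_a] = eta_new
                                    ll_row[rows_a] = ll_new
                    if adapt:
                        step_corr[q] += kappa_t * (float(acc_cr) - 0.44)
                    if t >= sampler.warmup_draws:
                        acc_count["cov_corr"] += float(acc_cr) / (2 * len(dim_pairs))

        # recompose covariance state for the next sweep
        cov = corr_m * np.outer(sd, sd)
        l_cov = cholesky(cov, lower=True)
        linv_c = solve_triangular(l_cov, eye, lower=True)
        lam = linv_c.T @ linv_c
        logdet = 2.0 * float(np.sum(np.log(np.diag(l_cov))))

        if t >= sampler.warmup_draws:
            j = t - sampler.warmup_draws
            out_beta[j] = beta
            out_delta[j] = delta
            out_sigma[j] = sd.copy()
            out_corr[j] = corr_m.copy()
            out_theta[j] = theta
            out_ll[j] = ll_row

    accept = {k: v / kept for k, v in acc_count.items()}
    return dict(beta=out_beta, delta=out_delta, sigma=out_sigma,
                corr=out_corr, theta=out_theta, log_lik=out_ll, accept=accept)


# public API

def fit_model(subitems: pd.DataFrame, structure: Structure = "unidimensional",
              tree: TreeSpec | None = None, priors: PriorConfig | None = None,
              sampler: SamplerConfig | None = None,
              design: StudyDesign | None = None) -> PosteriorFit:
    """Sample the posterior of one latent structure on a sub-item table.

    Parameters
    ----------
    subitems
        Dendrified table from :func:`treequal.treeify.expand_to_subitems`
        (with a ``fluency_group`` column for the ``fluency_split``
        structure).  An empty table with an explicit ``design`` yields a
        prior-only fit.
    structure
        ``unidimensional`` (one trait), ``node_multidimensional`` (one trait
        per retained tree node) or ``fluency_split`` (low/high-fluency traits).
    design
        Optional study design fixing the person/item/rater universe; by
        default these are taken from the data in first-appearance order.

    Returns
    -------
    PosteriorFit
        Draws, pointwise log-likelihood, and convergence diagnostics.
        Non-convergence (split-R-hat > 1.05) sets a warning flag on the fit
        rather than raising.
    """
    tree = tree or TreeSpec()
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    prep = _prepare(subitems, structure, tree, design)

    seeds = np.random.SeedSequence(sampler.seed).spawn(sampler.chains)
    chains = [_run_chain(prep, priors, sampler, s) for s in seeds]

    posterior = {
        name: np.stack([c[name] for c in chains])
        for name in ("beta", "delta", "sigma", "corr", "theta")
    }
    log_lik = np.stack([c["log_lik"] for c in chains])
    accept_rates = pd.DataFrame([c["accept"] for c in chains])

    fit = PosteriorFit(
        structure=structure, tree=tree, dmap=prep["dmap"],
        persons=prep["persons"], items=prep["items"], raters=prep["raters"],
        nodes=prep["nodes"], cells=prep["cells"], obs_ids=prep["obs_ids"],
        posterior=posterior, log_lik=log_lik, sampler=sampler, priors=priors,
        accept_rates=accept_rates,
    )
    if len(subitems) and not fit.converged:
        msg = f"split-R-hat {fit.max_rhat:.3f} exceeds 1.05; consider more draws"
        fit.warnings_.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return fit


def summarize_correlations(fit: PosteriorFit, ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central credible interval per latent-dimension pair.

    Returns an empty table (with a notice in ``attrs``) for unidimensional
    fits, and one row per unordered pair otherwise.
    """
    d = fit.n_dimensions
    labels = fit.dimension_labels
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    if d < 2:
        out = pd.DataFrame(columns=["dim_a", "dim_b", "mean", "ci_low", "ci_high"])
        out.attrs["notice"] = "unidimensional fit has no latent correlations"
        return out
    draws = fit.stacked("corr")
    rows = []
    for i in range(d - 1):
        for j in range(i + 1, d):
            r = draws[:, i, j]
            rows.append({
                "dim_a": labels[i], "dim_b": labels[j],
                "mean": float(r.mean()),
                "ci_low": float(np.quantile(r, lo_q)),
                "ci_high": float(np.quantile(r, hi_q)),
            })
    return pd.DataFrame(rows)


def detect_noninformative_nodes(subitems: pd.DataFrame, min_per_class: int = 5,
                                tree: TreeSpec | None = None) -> pd.DataFrame:
    """Count outcome classes per (instruction, node) and flag starved nodes.

    A node is flagged within an instruction when either outcome class has
    fewer than ``min_per_class`` observations there — the operational form
    of "not enough information": its thresholds would be prior-determined
    and their uncertainties unrealistically large.  Nodes entirely absent
    from an instruction are flagged too (both class counts are zero).
    """
    tree = tree or TreeSpec()
    instructions = list(pd.unique(subitems["instruction"]))
    rows = []
    for instr in instructions:
        sub = subitems[subitems["instruction"] == instr]
        for r in tree.nodes:
            y = sub.loc[sub["node"] == r, "outcome"]
            n_fail = int((y == 0).sum())
            n_pass = int((y == 1).sum())
            rows.append({
                "instruction": instr, "node": r,
                "n_fail": n_fail, "n_pass": n_pass,
                "flagged": min(n_fail, n_pass) < min_per_class,
            })
    return pd.DataFrame(rows)


def omit_nodes(subitems: pd.DataFrame, flagged) -> pd.DataFrame:
    """Drop all rows at flagged (instruction, node) pairs.

    ``flagged`` may be the frame from :func:`detect_noninformative_nodes`
    (only rows with ``flagged == True`` are used) or an iterable of
    (instruction, node) pairs.
    """
    if isinstance(flagged, pd.DataFrame):
        pairs = set(map(tuple, flagged.loc[flagged["flagged"], ["instruction", "node"]].to_numpy()))
    else:
        pairs = {(instr, int(r)) for instr, r in flagged}
    if not pairs:
        return subitems.copy()
    keys = list(zip(subitems["instruction"], subitems["node"]))
    keep = np.array([k not in pairs for k in keys])
    return subitems.loc[keep].reset_index(drop=True)
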