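"""Bayesian MCMC inference of the cell phylogeny and model parameters.

The posterior targets the tree topology, the 2J-1 branch lengths, the
relative deletion rate ``d``, the site-rate shape ``eta`` and the
read-count parameters ``t, nu, f, w1, w2, theta`` jointly, via
Metropolis-Hastings with a mixture of moves: per-branch and whole-tree
length scaling, narrow (NNI) and wide subtree exchanges, multiplier
random walks for positive scalars and logit random walks for
probabilities.  Likelihood caches (per-branch transition matrices and
the leaf read-count tensor) are invalidated selectively per move class,
so one iteration costs one pruning pass plus the touched cache.

Inference runs in two stages: stage 1 samples without acquisition bias
correction to localize parameters; stage 2 restarts from the stage-1
posterior medians with the wildtype-background correction enabled, and
final calls are made from stage-2 output.

Priors (package defaults, configurable): ``d ~ Exp(mean 0.1)``,
``eta ~ LogNormal(0, 1)``, ``t ~ LogNormal(log median coverage / 2, 1)``,
``nu ~ Exp(mean t)``, ``f ~ Beta(1, 99)``, ``w1, w2 ~ LogNormal(log 100, 1)``,
``theta ~ Beta(1, 9)``, branch lengths i.i.d. ``Exp(mean 0.1)`` with a
uniform prior over topologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotypes import N_STATES, build_rate_matrix, transition_probabilities
from .likelihood import (
    ModelParameters,
    branch_transition_tensor,
    conditioned_site_log_likelihoods,
    discrete_gamma_rates,
    pruning_site_log_likelihoods,
)
from .readcounts import (
    ReadCountDataset,
    ReadCountParams,
    estimate_size_factors,
    leaf_log_likelihood_tensor,
)
from .trees import CellPhylogeny, random_coalescent_tree, upgma_tree

__all__ = [
    "McmcConfig",
    "McmcResult",
    "run_mcmc",
    "two_stage_inference",
    "gelman_rubin",
    "maximum_clade_credibility_tree",
    "credible_interval",
]

_SCALARS = ("d", "eta", "t", "nu", "f", "w1", "w2", "theta_ado", "theta_ldo")


@dataclass
class McmcConfig:
    """Settings of one MCMC run."""

    iterations: int = 20000
    thinning: int = 20
    burn_in_fraction: float = 0.10
    seed: Optional[int] = None
    dropout_mode: str = "ado"
    n_rate_categories: int = 4
    use_acquisition_bias: bool = True
    start_tree: str = "upgma"  # or "random"
    prior_only: bool = False  # replace the likelihood by a constant (validation)
    jitter_start: float = 0.0  # lognormal sd used to disperse starting scalars
    # prior hyperparameters
    d_prior_mean: float = 0.1
    branch_prior_mean: float = 0.1  # initial value of the sampled branch mean
    # hierarchical branch prior: branch lengths are i.i.d. Exponential with a
    # sampled mean (LogNormal hyperprior), which adapts the shrinkage scale to
    # the data and avoids the tree-length inflation of a fixed diffuse mean
    hierarchical_branch_prior: bool = True
    branch_mean_hyper_sd: float = 2.0
    # proposal tuning: multiplier window per positive scalar, logit-walk
    # sd per probability; defaults chosen for roughly 0.2-0.5 acceptance
    branch_scale: float = 1.2
    scalar_scale: float = 0.4
    logit_scale: float = 0.6
    scalar_scales: dict = field(
        default_factory=lambda: {"d": 1.2, "eta": 1.2, "t": 0.06, "nu": 0.5,
                                 "w1": 1.0, "w2": 0.8}
    )
    logit_scales: dict = field(
        default_factory=lambda: {"f": 0.25, "theta_ado": 0.2, "theta_ldo": 0.5}
    )
    max_init_attempts: int = 20

    def __post_init__(self):
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.dropout_mode not in ("ado", "ldo"):
            raise ValueError("dropout_mode must be 'ado' or 'ldo'")


@dataclass
class McmcResult:
    """Thinned samples of one chain."""

    samples: pd.DataFrame  # one row per retained sample
    trees: list  # CellPhylogeny per retained sample
    acceptance: dict[str, float]
    config: McmcConfig

    def burn_in_cut(self) -> int:
        return int(math.floor(self.config.burn_in_fraction * len(self.samples)))

    def posterior(self) -> pd.DataFrame:
        """Samples with the burn-in fraction discarded."""
        return self.samples.iloc[self.burn_in_cut():]

    def posterior_trees(self) -> list:
        return self.trees[self.burn_in_cut():]

    def posterior_median_params(self) -> ModelParameters:
        post = self.posterior()
        med = post[list(_SCALARS)].median()
        return ModelParameters(
            d=float(med["d"]),
            eta=float(med["eta"]),
            n_rate_categories=self.config.n_rate_categories,
            mode=self.config.dropout_mode,
            read=ReadCountParams(
                t=float(med["t"]),
                nu=float(med["nu"]),
                f=float(med["f"]),
                w1=float(med["w1"]),
                w2=float(med["w2"]),
                theta_ado=float(med["theta_ado"]),
                theta_ldo=float(med["theta_ldo"]),
            ),
        )


def credible_interval(samples: pd.DataFrame, name: str, level: float = 0.9) -> tuple[float, float]:
    """Central credible interval of one scalar from posterior samples."""
    lo = (1.0 - level) / 2.0
    q = samples[name].quantile([lo, 1.0 - lo])
    return float(q.iloc[0]), float(q.iloc[1])


# ---------------------------------------------------------------------------
# priors


def _log_prior_scalars(p: dict[str, float], cfg: McmcConfig, log_t0: float, mode: str) -> float:
    d, eta, t, nu, f = p["d"], p["eta"], p["t"], p["nu"], p["f"]
    w1, w2, tha, thl = p["w1"], p["w2"], p["theta_ado"], p["theta_ldo"]
    if min(d, eta, t, nu, w1, w2) < 0 or not (0 < f < 1):
        return -np.inf
    if not (0 <= tha < 1) or not (0 <= thl < 1) or tha + thl >= 1:
        return -np.inf
    lp = -d / cfg.d_prior_mean - math.log(cfg.d_prior_mean)
    lp += _lognormal_logpdf(eta, 0.0, 1.0)
    lp += _lognormal_logpdf(t, log_t0, 1.0)
    lp += -nu / t - math.log(t)
    lp += math.log(99.0) + 98.0 * math.log1p(-f)  # Beta(1, 99)
    lp += _lognormal_logpdf(w1, math.log(100.0), 1.0)
    lp += _lognormal_logpdf(w2, math.log(100.0), 1.0)
    lp += math.log(9.0) + 8.0 * math.log1p(-tha)  # Beta(1, 9)
    if mode == "ldo":
        lp += math.log(9.0) + 8.0 * math.log1p(-thl)
    return lp


def _lognormal_logpdf(x: float, mu: float, sd: float) -> float:
    if x <= 0:
        return -np.inf
    z = (math.log(x) - mu) / sd
    return -0.5 * z * z - math.log(x * sd) - 0.5 * math.log(2.0 * math.pi)


def _log_prior_branches(lengths: np.ndarray, root: int, mean: float) -> float:
    b = lengths[:root]
    return float(-b.sum() / mean - b.size * math.log(mean))


# ---------------------------------------------------------------------------
# chain state with caches


class _Chain:
    def __init__(
        self,
        data: ReadCountDataset,
        cfg: McmcConfig,
        rng: np.random.Generator,
        init_params: Optional[ModelParameters] = None,
        init_tree: Optional[CellPhylogeny] = None,
    ):
        self.data = data
        self.cfg = cfg
        self.rng = rng
        self.h = cfg.n_rate_categories
        self.mode = cfg.dropout_mode
        nz = data.coverage[data.coverage > 0]
        self.log_t0 = math.log(max(np.median(nz) / 2.0, 1e-3)) if nz.size else 0.0
        self.size_factors = estimate_size_factors(data.coverage)
        self.I_prime = data.background_site_count if cfg.use_acquisition_bias else 0
        self.branch_mean = cfg.branch_prior_mean

        for attempt in range(cfg.max_init_attempts):
            self.params = self._init_params(init_params)
            self.tree = (init_tree or self._init_tree()).copy()
            self._full_refresh()
            if np.isfinite(self.log_posterior()):
                break
            init_tree = None  # retry with a fresh random tree
        else:
            raise RuntimeError("could not find a starting state with finite posterior")

    # -- initialization -------------------------------------------------
    def _init_params(self, given: Optional[ModelParameters]) -> ModelParameters:
        if given is not None:
            p = replace(given, mode=self.mode, n_rate_categories=self.h)
        else:
            t0 = math.exp(self.log_t0)
            p = ModelParameters(
                d=self.cfg.d_prior_mean,
                eta=1.0,
                n_rate_categories=self.h,
                mode=self.mode,
                read=ReadCountParams(
                    t=t0, nu=t0, f=1e-3, w1=100.0, w2=100.0,
                    theta_ado=0.1, theta_ldo=0.05 if self.mode == "ldo" else 0.0,
                ),
            )
        if self.cfg.jitter_start > 0:
            j = lambda x: float(x * self.rng.lognormal(0.0, self.cfg.jitter_start))
            u = lambda x: float(min(max(x * self.rng.lognormal(0.0, self.cfg.jitter_start), 1e-5), 0.5))
            p = p.with_(
                d=j(p.d), eta=j(p.eta), t=j(p.read.t), nu=j(p.read.nu),
                f=u(p.read.f), w1=j(p.read.w1), w2=j(p.read.w2),
                theta_ado=u(p.read.theta_ado),
                theta_ldo=u(p.read.theta_ldo) if self.mode == "ldo" else 0.0,
            )
        return replace(p, read=replace(p.read, size_factors=self.size_factors))

    def _init_tree(self) -> CellPhylogeny:
        J = self.data.n_cells
        if self.cfg.start_tree == "random" or self.cfg.prior_only:
            return random_coalescent_tree(
                J, self.rng, height=0.5 * self.cfg.branch_prior_mean,
                leaf_names=self.data.cell_names,
            )
        leaf_log = leaf_log_likelihood_tensor(self.data, self.params.read, self.mode)
        # probability that two cells carry different genotypes at a site,
        # from per-cell normalized leaf likelihoods (soft distances)
        P = np.exp(leaf_log - leaf_log.max(axis=2, keepdims=True))
        P /= P.sum(axis=2, keepdims=True)
        D = np.zeros((J, J))
        for a in range(J):
            for b in range(a + 1, J):
                agree = (P[:, a, :] * P[:, b, :]).sum(axis=1)
                D[a, b] = D[b, a] = np.mean(1.0 - agree)
        D *= max(self.data.n_sites, 1) / max(
            self.data.n_sites + self.data.background_site_count, 1
        )  # rescale per-candidate-site distance to per-genome-site
        D = np.maximum(D, 1e-8)
        height = D.max() / 2.0
        tree = upgma_tree(D, leaf_names=self.data.cell_names, trunk_length=height)
        # distances overestimate mutational branch lengths (dropout noise);
        # profile a global scale at the initial parameters before sampling
        Q = build_rate_matrix(self.params.d)
        rates = discrete_gamma_rates(self.params.eta, self.h)
        best, best_ll = 1.0, -np.inf
        for scale in (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0):
            scaled = tree.branch_lengths[:, None] * scale * rates[None, :]
            R = transition_probabilities(Q, scaled)
            R[tree.root] = np.eye(N_STATES)
            ll = float(pruning_site_log_likelihoods(leaf_log, tree, R).sum())
            if ll > best_ll:
                best, best_ll = scale, ll
        tree.branch_lengths[: tree.root] *= best
        return tree

    # -- caches ----------------------------------------------------------
    def _full_refresh(self) -> None:
        self.Q = build_rate_matrix(self.params.d)
        self.rates = discrete_gamma_rates(self.params.eta, self.h)
        self.leaf_log = (
            np.zeros((self.data.n_sites, self.data.n_cells, N_STATES))
            if self.cfg.prior_only
            else leaf_log_likelihood_tensor(self.data, self.params.read, self.mode)
        )
        self.R = self._transition_tensor(self.tree.branch_lengths)
        self._recompute_likelihood()
        self.log_prior = self._log_prior()

    def _transition_tensor(self, lengths: np.ndarray) -> np.ndarray:
        scaled = lengths[:, None] * self.rates[None, :]
        R = transition_probabilities(self.Q, scaled)
        R[self.tree.root] = np.eye(N_STATES)
        return R

    def _branch_R(self, beta: float) -> np.ndarray:
        return transition_probabilities(self.Q, beta * self.rates)

    def _recompute_likelihood(self) -> None:
        if self.cfg.prior_only:
            self.site_ll = np.zeros(self.data.n_sites)
            self.bg_ll = 0.0
            self.log_likelihood = 0.0
            return
        if self.I_prime:
            # fuse the all-wildtype background configuration into the same
            # pruning pass as a trailing pseudo-site
            if not hasattr(self, "_bg_leaf"):
                self._bg_leaf = np.full((1, self.data.n_cells, N_STATES), -np.inf)
                self._bg_leaf[:, :, 0] = 0.0
            ext = np.concatenate([self.leaf_log, self._bg_leaf], axis=0)
            vals = pruning_site_log_likelihoods(ext, self.tree, self.R)
            self.bg_ll = float(vals[-1])
            A = vals[:-1]
            B = self.bg_ll + self.leaf_log[:, :, 0].sum(axis=1)
            delta = np.minimum(B - A, -1e-12)
            self.site_ll = A + np.log1p(-np.exp(delta))
        else:
            self.bg_ll = 0.0
            self.site_ll = pruning_site_log_likelihoods(self.leaf_log, self.tree, self.R)
        self.log_likelihood = float(self.site_ll.sum() + self.I_prime * self.bg_ll)

    def _background_ll(self, tree: CellPhylogeny, R: np.ndarray) -> float:
        leaf_log = np.full((1, tree.n_leaves, N_STATES), -np.inf)
        leaf_log[:, :, 0] = 0.0
        return float(pruning_site_log_likelihoods(leaf_log, tree, R)[0])

    def _log_prior(self) -> float:
        p = self.scalar_dict()
        lp = _log_prior_scalars(p, self.cfg, self.log_t0, self.mode)
        lp += _log_prior_branches(
            self.tree.branch_lengths, self.tree.root, self.branch_mean
        )
        if self.cfg.hierarchical_branch_prior:
            lp += _lognormal_logpdf(
                self.branch_mean,
                math.log(self.cfg.branch_prior_mean),
                self.cfg.branch_mean_hyper_sd,
            )
        return lp

    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior

    def scalar_dict(self) -> dict[str, float]:
        r = self.params.read
        return {
            "d": self.params.d, "eta": self.params.eta, "t": r.t, "nu": r.nu,
            "f": r.f, "w1": r.w1, "w2": r.w2,
            "theta_ado": r.theta_ado, "theta_ldo": r.theta_ldo,
        }

    # -- moves -----------------------------------------------------------
    def move_branch(self) -> bool:
        v = int(self.rng.integers(0, self.tree.root))  # any non-root node
        m = math.exp(self.cfg.branch_scale * (self.rng.random() - 0.5))
        old_len = self.tree.branch_lengths[v]
        old_R_v = self.R[v].copy()
        old = (self.site_ll, self.bg_ll, self.log_likelihood, self.log_prior)
        self.tree.branch_lengths[v] = old_len * m
        self.R[v] = self._branch_R(self.tree.branch_lengths[v])
        self._recompute_likelihood()
        self.log_prior = self._log_prior()
        if self._accept(old[2] + old[3], math.log(m)):
            return True
        self.tree.branch_lengths[v] = old_len
        self.R[v] = old_R_v
        self.site_ll, self.bg_ll, self.log_likelihood, self.log_prior = old
        return False

    def move_scale_all(self) -> bool:
        m = math.exp(self.cfg.branch_scale * (self.rng.random() - 0.5))
        old_lengths = self.tree.branch_lengths.copy()
        old_R = self.R
        old = (self.site_ll, self.bg_ll, self.log_likelihood, self.log_prior)
        self.tree.branch_lengths[: self.tree.root] *= m
        self.R = self._transition_tensor(self.tree.branch_lengths)
        self._recompute_likelihood()
        self.log_prior = self._log_prior()
        if self._accept(old[2] + old[3], self.tree.root * math.log(m)):
            return True
        self.tree.branch_lengths = old_lengths
        self.R = old_R
        self.site_ll, self.bg_ll, self.log_likelihood, self.log_prior = old
        return False

    def _try_topology(self, new_parent: np.ndarray) -> bool:
        old_parent = self.tree.parent
        old = (self.site_ll, self.bg_ll, self.log_likelihood)
        self.tree.parent = new_parent
        try:
            self.tree._validate()
        except ValueError:
            self.tree.parent = old_parent
            return False
        self._recompute_likelihood()
        if self._accept(old[2] + self.log_prior, 0.0):
            return True
        self.tree.parent = old_parent
        self.site_ll, self.bg_ll, self.log_likelihood = old
        return False

    def move_narrow_exchange(self) -> bool:
        tree = self.tree
        J = tree.n_leaves
        mrca = tree.mrca
        # choose an internal node v below the MRCA; swap one of its
        # children with its sibling
        candidates = [v for v in range(J, tree.root) if v != mrca]
        if not candidates:
            return False
        v = int(self.rng.choice(candidates))
        p = tree.parent[v]
        ch = tree.children()
        sib = [c for c in ch[p] if c != v][0]
        c = int(self.rng.choice(ch[v]))
        new_parent = tree.parent.copy()
        new_parent[sib] = v
        new_parent[c] = p
        return self._try_topology(new_parent)

    def move_wide_exchange(self) -> bool:
        tree = self.tree
        mrca = tree.mrca
        nodes = [v for v in range(tree.root) if v != mrca]
        a, b = self.rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(a)], nodes[int(b)]
        if tree.parent[a] == tree.parent[b]:
            return False
        # reject if one is an ancestor of the other
        for x, y in ((a, b), (b, a)):
            u = tree.parent[y]
            while u != -1:
                if u == x:
                    return False
                u = tree.parent[u]
        new_parent = tree.parent.copy()
        new_parent[a], new_parent[b] = tree.parent[b], tree.parent[a]
        return self._try_topology(new_parent)

    def move_scalar(self, name: str) -> bool:
        p = self.scalar_dict()
        if name in ("f", "theta_ado", "theta_ldo"):
            x = p[name]
            x = min(max(x, 1e-12), 1 - 1e-12)
            sd = self.cfg.logit_scales.get(name, self.cfg.logit_scale)
            z = math.log(x / (1 - x)) + self.rng.normal(0.0, sd)
            new = 1.0 / (1.0 + math.exp(-z))
            log_hastings = math.log(new * (1 - new)) - math.log(x * (1 - x))
        else:
            lam = self.cfg.scalar_scales.get(name, self.cfg.scalar_scale)
            m = math.exp(lam * (self.rng.random() - 0.5))
            new = p[name] * m
            log_hastings = math.log(m)
        old_params = self.params
        old_Q, old_rates, old_R, old_leaf = self.Q, self.rates, self.R, self.leaf_log
        old = (self.site_ll, self.bg_ll, self.log_likelihood, self.log_prior)
        self.params = self.params.with_(**{name: new})
        try:
            if name == "d":
                self.Q = build_rate_matrix(self.params.d)
                self.R = self._transition_tensor(self.tree.branch_lengths)
            elif name == "eta":
                self.rates = discrete_gamma_rates(self.params.eta, self.h)
                self.R = self._transition_tensor(self.tree.branch_lengths)
            elif not self.cfg.prior_only:
                self.leaf_log = leaf_log_likelihood_tensor(
                    self.data, self.params.read, self.mode
                )
            self._recompute_likelihood()
            self.log_prior = self._log_prior()
            ok = np.isfinite(self.log_posterior())
        except (ValueError, FloatingPointError):
            ok = False
        if ok and self._accept(old[2] + old[3], log_hastings):
            return True
        self.params = old_params
        self.Q, self.rates, self.R, self.leaf_log = old_Q, old_rates, old_R, old_leaf
        self.site_ll, self.bg_ll, self.log_likelihood, self.log_prior = old
        return False

    def move_branch_mean(self) -> bool:
        """Update the sampled mean of the branch-length prior (prior-only move)."""
        if not self.cfg.hierarchical_branch_prior:
            return False
        m = math.exp(1.5 * (self.rng.random() - 0.5))
        old_bm, old_lp = self.branch_mean, self.log_prior
        self.branch_mean = old_bm * m
        self.log_prior = self._log_prior()
        if self._accept(self.log_likelihood + old_lp, math.log(m)):
            return True
        self.branch_mean, self.log_prior = old_bm, old_lp
        return False

    def _accept(self, old_post: float, log_hastings: float) -> bool:
        new_post = self.log_posterior()
        if not np.isfinite(new_post):
            return False
        log_ratio = new_post - old_post + log_hastings
        return log_ratio >= 0 or self.rng.random() < math.exp(log_ratio)


def _move_schedule(mode: str) -> list[tuple[str, float]]:
    moves = [
        ("branch", 0.28),
        ("branch_mean", 0.05),
        ("scale_all", 0.05),
        ("narrow", 0.14),
        ("wide", 0.05),
        ("d", 0.08),
        ("eta", 0.04),
        ("t", 0.07),
        ("nu", 0.05),
        ("f", 0.07),
        ("w1", 0.04),
        ("w2", 0.04),
        ("theta_ado", 0.06),
    ]
    if mode == "ldo":
        moves.append(("theta_ldo", 0.05))
    return moves


def run_mcmc(
    data: ReadCountDataset,
    config: McmcConfig,
    init_params: Optional[ModelParameters] = None,
    init_tree: Optional[CellPhylogeny] = None,
) -> McmcResult:
    """Run one Metropolis-Hastings chain and return thinned samples."""
    if data.n_cells < 3:
        raise ValueError("need at least 3 cells for topology inference")
    rng = np.random.default_rng(config.seed)
    chain = _Chain(data, config, rng, init_params, init_tree)
    moves = _move_schedule(config.dropout_mode)
    names = [m for m, _ in moves]
    weights = np.array([w for _, w in moves])
    weights = weights / weights.sum()
    tried = {m: 0 for m in names}
    accepted = {m: 0 for m in names}
    rows = []
    trees: list[CellPhylogeny] = []

    def record(it: int) -> None:
        row = {"iteration": it, "log_posterior": chain.log_posterior(),
               "log_likelihood": chain.log_likelihood,
               "tree_length": chain.tree.total_length(),
               "branch_prior_mean": chain.branch_mean}
        row.update(chain.scalar_dict())
        rows.append(row)
        trees.append(chain.tree.copy())

    record(0)
    for it in range(1, config.iterations + 1):
        m = names[int(rng.choice(len(names), p=weights))]
        tried[m] += 1
        if m == "branch":
            ok = chain.move_branch()
        elif m == "branch_mean":
            ok = chain.move_branch_mean()
        elif m == "scale_all":
            ok = chain.move_scale_all()
        elif m == "narrow":
            ok = chain.move_narrow_exchange()
        elif m == "wide":
            ok = chain.move_wide_exchange()
        else:
            ok = chain.move_scalar(m)
        accepted[m] += ok
        if it % config.thinning == 0:
            record(it)
    acc = {m: (accepted[m] / tried[m] if tried[m] else np.nan) for m in names}
    return McmcResult(pd.DataFrame(rows), trees, acc, config)


def two_stage_inference(
    data: ReadCountDataset, config: McmcConfig
) -> tuple[McmcResult, McmcResult, dict]:
    """Stage 1 (no acquisition bias correction) then stage 2 (corrected).

    Stage 2 restarts from the stage-1 posterior-median scalars and the
    stage-1 maximum clade credibility tree.
    """
    cfg1 = replace(config, use_acquisition_bias=False)
    res1 = run_mcmc(data, cfg1)
    mcc1, _ = maximum_clade_credibility_tree(res1.posterior_trees())
    cfg2 = replace(config, use_acquisition_bias=True,
                   seed=None if config.seed is None else config.seed + 1)
    res2 = run_mcmc(data, cfg2, init_params=res1.posterior_median_params(), init_tree=mcc1)
    mcc2, support = maximum_clade_credibility_tree(res2.posterior_trees())
    summary = {
        "params": res2.posterior_median_params(),
        "mcc_tree": mcc2,
        "clade_support": support,
        "stage1_median_tree_length": float(res1.posterior()["tree_length"].median()),
        "stage2_median_tree_length": float(res2.posterior()["tree_length"].median()),
    }
    return res1, res2, summary


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor of post-burn-in scalar traces.

    The classic between/within-variance PSRF for M >= 2 equal-length
    chains; values close to 1 indicate convergence.
    """
    arr = np.asarray([np.asarray(c, dtype=float) for c in chains])
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two equal-length chains")
    m, n = arr.shape
    if n < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def _clades(tree: CellPhylogeny) -> dict[frozenset, int]:
    """Map clade (frozenset of leaf indices) -> defining node, internals only."""
    out = {}
    children = tree.children()
    leafsets: dict[int, frozenset] = {}
    for v in tree.postorder():
        if v < tree.n_leaves:
            leafsets[v] = frozenset([v])
        else:
            leafsets[v] = frozenset().union(*(leafsets[c] for c in children[v]))
            if v != tree.root:
                out[leafsets[v]] = v
    return out


def maximum_clade_credibility_tree(
    trees: Sequence[CellPhylogeny],
) -> tuple[CellPhylogeny, dict[frozenset, float]]:
    """The sampled tree maximizing the product of clade posterior frequencies.

    Returns the winning tree with branch lengths replaced by per-clade
    means over the samples containing each clade (leaf branches and the
    trunk averaged over all samples), plus the clade support map.
    """
    if not trees:
        raise ValueError("no trees to summarize")
    n = len(trees)
    freq: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    leaf_lengths = np.zeros((n, trees[0].n_leaves))
    trunk_lengths = np.zeros(n)
    for k, tr in enumerate(trees):
        for clade, v in _clades(tr).items():
            freq[clade] = freq.get(clade, 0) + 1
            lengths.setdefault(clade, []).append(float(tr.branch_lengths[v]))
        leaf_lengths[k] = tr.branch_lengths[: tr.n_leaves]
        trunk_lengths[k] = tr.branch_lengths[tr.mrca]
    best, best_score = None, -np.inf
    for tr in trees:
        score = sum(math.log(freq[c] / n) for c in _clades(tr))
        if score > best_score:
            best, best_score = tr, score
    mcc = best.copy()
    support: dict[frozenset, float] = {}
    for clade, v in _clades(mcc).items():
        support[clade] = freq[clade] / n
        mcc.branch_lengths[v] = float(np.mean(lengths[clade]))
    mcc.branch_lengths[: mcc.n_leaves] = leaf_lengths.mean(axis=0)
    mcc.branch_lengths[mcc.mrca] = trunk_lengths.mean()
    return mcc, support
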