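"""Phylogenetic likelihood of read counts over the 7-state genotype space.

The genotype configuration at a site evolves down the cell phylogeny
from a wildtype (0/0) root under the deletion-aware rate matrix, with
among-site rate variation modeled by a mean-one discrete Gamma mixture.
The likelihood of the leaf data is computed by Felsenstein pruning with
per-node rescaling; leaves carry 7-vectors of read-count likelihoods
``P(D_ij | g)`` from :mod:`scphylodel.readcounts`.

Because only candidate *variant* sites enter the data, branch lengths
would be overestimated without an ascertainment term; the acquisition
bias correction augments the likelihood with ``I'`` background sites
constrained to be wildtype in all cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaincinv, gammainc, logsumexp

from .genotypes import N_STATES, build_rate_matrix, transition_probabilities
from .readcounts import ReadCountDataset, ReadCountParams, leaf_log_likelihood_tensor
from .trees import CellPhylogeny

__all__ = [
    "ModelParameters",
    "discrete_gamma_rates",
    "branch_transition_tensor",
    "site_log_likelihood",
    "pruning_site_log_likelihoods",
    "dataset_log_likelihood",
    "acquisition_bias_corrected_log_likelihood",
    "conditioned_site_log_likelihoods",
    "background_site_log_likelihood",
]


@dataclass
class ModelParameters:
    """All continuous model parameters plus the dropout mode."""

    d: float = 0.1  # relative deletion rate
    eta: float = 1.0  # Gamma shape of site-rate variation
    n_rate_categories: int = 4
    mode: str = "ado"
    read: ReadCountParams = field(default_factory=ReadCountParams)

    def with_(self, **kw) -> "ModelParameters":
        read_kw = {k: v for k, v in kw.items() if hasattr(ReadCountParams, "__dataclass_fields__") and k in ReadCountParams.__dataclass_fields__}
        own_kw = {k: v for k, v in kw.items() if k not in read_kw}
        read = replace(self.read, **read_kw) if read_kw else self.read
        return replace(self, read=read, **own_kw)


def discrete_gamma_rates(eta: float, h: int = 4) -> np.ndarray:
    """Mean-one discrete Gamma rates with ``h`` equal-probability bins.

    Rates are the conditional means of a Gamma(eta, eta) distribution
    within each bin (so the category mean is exactly 1), following the
    "mean" discretization.
    """
    if eta <= 0:
        raise ValueError("Gamma shape must be positive")
    h = int(h)
    if h < 1:
        raise ValueError("need at least one rate category")
    if h == 1:
        return np.ones(1)
    edges = gammaincinv(eta, np.linspace(0.0, 1.0, h + 1))  # quantiles of Gamma(eta, 1)
    # E[X; X in bin] for X ~ Gamma(eta, eta): mean 1 overall
    upper = gammainc(eta + 1.0, edges)
    rates = h * np.diff(upper)
    return rates


def branch_transition_tensor(
    tree: CellPhylogeny, d: float, eta: float, h: int = 4
) -> np.ndarray:
    """Transition matrices R(beta_v * r_c) for every node v and category c.

    Returns an array of shape ``(2J, h, 7, 7)``; the root slot is the
    identity (no branch above the root).
    """
    Q = build_rate_matrix(d)
    rates = discrete_gamma_rates(eta, h)
    scaled = tree.branch_lengths[:, None] * rates[None, :]  # (2J, h)
    R = transition_probabilities(Q, scaled)
    R[tree.root] = np.eye(N_STATES)
    return R


def pruning_site_log_likelihoods(
    leaf_log_ll: np.ndarray, tree: CellPhylogeny, R: np.ndarray
) -> np.ndarray:
    """Per-site log-likelihoods by post-order pruning.

    Parameters
    ----------
    leaf_log_ll : (I, J, 7) array
        Log read-count likelihoods at the leaves.
    tree : CellPhylogeny
    R : (2J, h, 7, 7) array
        Per-branch, per-rate-category transition matrices.

    The root genotype is clamped to wildtype; categories have uniform
    weight.  Partial likelihoods are rescaled per node, with the log
    scalers accumulated, to avoid underflow.
    """
    I, J, K = leaf_log_ll.shape
    if J != tree.n_leaves or K != N_STATES:
        raise ValueError("leaf likelihood tensor does not match the tree")
    h = R.shape[1]
    children = tree.children()
    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros((I, h))
    with np.errstate(invalid="ignore"):
        for v in tree.postorder():
            if v < J:
                m = leaf_log_ll[:, v, :].max(axis=1)  # (I,)
                if np.any(~np.isfinite(m)):
                    warnings.warn("all-zero leaf likelihood vector; site likelihood is 0")
                    m = np.where(np.isfinite(m), m, 0.0)
                P = np.exp(leaf_log_ll[:, v, :] - m[:, None])
                partial[v] = np.broadcast_to(P[:, None, :], (I, h, K)).copy()
                log_scale += m[:, None]
            else:
                L = np.ones((I, h, K))
                for c in children[v]:
                    L = L * np.einsum("hgs,ihs->ihg", R[c], partial.pop(c))
                if v != tree.root:
                    m = L.max(axis=2)
                    nz = m > 0
                    L = np.where(nz[:, :, None], L / np.where(nz, m, 1.0)[:, :, None], 0.0)
                    log_scale += np.where(nz, np.log(np.where(nz, m, 1.0)), -np.inf)
                partial[v] = L
    root_val = partial[tree.root][:, :, 0]  # genotype clamped to 0/0
    with np.errstate(divide="ignore"):
        ll = logsumexp(np.log(root_val) + log_scale, axis=1) - np.log(h)
    return ll


def site_log_likelihood(
    leaf_vectors: np.ndarray,
    tree: CellPhylogeny,
    Q: np.ndarray,
    eta: float = 1.0,
    h: int = 4,
) -> float:
    """Log-likelihood of one site from linear-scale 7-vectors per leaf."""
    leaf_vectors = np.asarray(leaf_vectors, dtype=float)
    if np.any(leaf_vectors < 0):
        raise ValueError("leaf likelihood vectors must be non-negative")
    rates = discrete_gamma_rates(eta, h)
    scaled = tree.branch_lengths[:, None] * rates[None, :]
    R = transition_probabilities(Q, scaled)
    R[tree.root] = np.eye(N_STATES)
    with np.errstate(divide="ignore"):
        leaf_log = np.log(leaf_vectors)[None, :, :]
    return float(pruning_site_log_likelihoods(leaf_log, tree, R)[0])


def dataset_log_likelihood(
    data: ReadCountDataset, tree: CellPhylogeny, params: ModelParameters
) -> float:
    """Total log-likelihood of all candidate variant sites (no correction)."""
    leaf_log = leaf_log_likelihood_tensor(data, params.read, params.mode)
    R = branch_transition_tensor(tree, params.d, params.eta, params.n_rate_categories)
    return float(pruning_site_log_likelihoods(leaf_log, tree, R).sum())


def background_site_log_likelihood(
    tree: CellPhylogeny, params: ModelParameters
) -> float:
    """Log-probability that a site stays wildtype in every sequenced cell."""
    leaf_log = np.full((1, tree.n_leaves, N_STATES), -np.inf)
    leaf_log[:, :, 0] = 0.0
    R = branch_transition_tensor(tree, params.d, params.eta, params.n_rate_categories)
    return float(pruning_site_log_likelihoods(leaf_log, tree, R)[0])


def conditioned_site_log_likelihoods(
    leaf_log: np.ndarray, tree: CellPhylogeny, R: np.ndarray, bg_ll: float
) -> np.ndarray:
    """Per-site log-likelihoods conditioned on the site being a candidate.

    Candidate variant sites are, by the acquisition scheme, exactly the
    sites whose leaf genotypes are not all wildtype; the matching
    per-site term is ``P(D_i) - P(D_i, all leaves 0/0)`` where the
    subtracted part factorizes into the wildtype-configuration prior
    (``bg_ll``, from the tree) times the wildtype leaf likelihoods.
    Without the subtraction, weak deletion-only sites can be "explained
    away" as wildtype, biasing the deletion rate downward.
    """
    A = pruning_site_log_likelihoods(leaf_log, tree, R)
    B = bg_ll + leaf_log[:, :, 0].sum(axis=1)
    delta = np.minimum(B - A, -1e-12)  # P(D, all-WT) <= P(D) up to roundoff
    return A + np.log1p(-np.exp(delta))


def acquisition_bias_corrected_log_likelihood(
    data: ReadCountDataset,
    tree: CellPhylogeny,
    params: ModelParameters,
    background_sites: int | None = None,
) -> float:
    """Ascertainment-aware log-likelihood of variant plus background sites.

    Background sites contribute ``I' * log P(all leaves wildtype)``;
    when background information is present, the variant-site terms are
    additionally conditioned on the site having been discovered
    (:func:`conditioned_site_log_likelihoods`).  ``background_sites``
    defaults to the count recorded in the dataset; with 0 background
    sites this reduces exactly to :func:`dataset_log_likelihood`.
    """
    I_prime = data.background_site_count if background_sites is None else background_sites
    if I_prime < 0:
        raise ValueError("background site count must be >= 0")
    if I_prime == 0:
        return dataset_log_likelihood(data, tree, params)
    leaf_log = leaf_log_likelihood_tensor(data, params.read, params.mode)
    R = branch_transition_tensor(tree, params.d, params.eta, params.n_rate_categories)
    bg_leaf = np.full((1, tree.n_leaves, N_STATES), -np.inf)
    bg_leaf[:, :, 0] = 0.0
    bg = float(pruning_site_log_likelihoods(bg_leaf, tree, R)[0])
    sites = conditioned_site_log_likelihoods(leaf_log, tree, R, bg)
    return float(sites.sum() + I_prime * bg)
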