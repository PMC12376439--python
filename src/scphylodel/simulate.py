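"""Generative counterpart of the model, for benchmarking.

The simulator draws a random cell phylogeny with a trunk, evolves
7-state genotypes site-independently along it under the deletion-aware
rate matrix (with discrete-Gamma site rates), and emits read counts
through the same dropout / coverage / nucleotide models the likelihood
uses.  Sites with at least one non-wildtype leaf genotype become the
candidate variant sites of the emitted dataset — mirroring the
ascertainment of real variant-calling input — and the remaining sites
are counted as wildtype background for acquisition bias correction.

Optional corruptions inject copy-number aberrations (coverage driven by
a copy number other than 2) and doublets (a second cell's reads added
to a library), both of which violate the model's assumptions on
purpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genotypes import ALLELE_COUNTS, GENOTYPE_LABELS, GENOTYPE_INDEX, N_STATES
from .likelihood import branch_transition_tensor, discrete_gamma_rates
from .readcounts import (
    ReadCountDataset,
    ReadCountParams,
    allele_count_distribution,
    observed_genotype_distribution,
    _freq_vector,
    _FREQ_CLASS,
    _W_CLASS,
)
from .trees import CellPhylogeny, random_coalescent_tree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "COVERAGE_PRESETS",
    "simulate_tree",
    "simulate_genotypes",
    "simulate_reads",
    "simulate_dataset",
    "inject_cnas",
    "inject_doublets",
]

#: (mean allelic coverage t, allelic-coverage variance nu) per quality preset.
#: High and medium quality share a high mean and differ in coverage variance
#: (low vs medium); low quality has low mean and high variance.
COVERAGE_PRESETS: dict[str, tuple[float, float]] = {
    "high": (20.0, 2.0),
    "medium": (20.0, 10.0),
    "low": (5.0, 50.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``mutation_rate`` is the per-site somatic mutation rate; together
    with ``height_scale`` it sets the tree height in expected mutations
    per site (``mutation_rate * height_scale``), so the benchmark grid
    {1e-6, 8e-6, 3e-5} spans sparse to dense mutation loads on a
    ``genome_sites``-site genome.
    """

    n_cells: int = 20
    genome_sites: int = 10000
    mutation_rate: float = 8e-6
    deletion_rate: float = 0.1  # relative to the mutation rate
    coverage_quality: str = "medium"
    dropout_mode: str = "ado"
    theta_ado: float = 0.2
    theta_ldo: float = 0.05  # only active in LDO mode
    f: float = 1e-3
    w1: float = 100.0
    w2: float = 10.0
    eps: float = 1e-6
    eta: float = 1.0
    n_rate_categories: int = 4
    height_scale: float = 1000.0
    trunk_mean_fraction: float = 1.0
    rate_jitter_sd: float = 0.3
    size_factor_sd: float = 0.25
    cna_fraction: float = 0.0
    doublet_fraction: float = 0.0
    seed: Optional[int] = None
    # explicit overrides of the coverage preset (e.g. noise-floor studies)
    coverage_mean: Optional[float] = None
    coverage_variance: Optional[float] = None

    def __post_init__(self):
        if self.coverage_quality not in COVERAGE_PRESETS:
            raise ValueError(f"coverage_quality must be one of {sorted(COVERAGE_PRESETS)}")
        if not (0 <= self.cna_fraction <= 1):
            raise ValueError("cna_fraction must lie in [0, 1]")
        if not (0 <= self.doublet_fraction <= 0.5):
            raise ValueError("doublet_fraction must lie in [0, 0.5]")

    @property
    def coverage_mean_var(self) -> tuple[float, float]:
        t, nu = COVERAGE_PRESETS[self.coverage_quality]
        if self.coverage_mean is not None:
            t = self.coverage_mean
        if self.coverage_variance is not None:
            nu = self.coverage_variance
        return t, nu

    def read_params(self, size_factors: Optional[np.ndarray] = None) -> ReadCountParams:
        t, nu = self.coverage_mean_var
        return ReadCountParams(
            t=t,
            nu=nu,
            f=self.f,
            w1=self.w1,
            w2=self.w2,
            eps=self.eps,
            theta_ado=self.theta_ado,
            theta_ldo=self.theta_ldo if self.dropout_mode == "ldo" else 0.0,
            size_factors=size_factors,
        )


@dataclass
class GroundTruth:
    """Provenance of one simulated dataset (candidate sites only)."""

    tree: CellPhylogeny
    node_genotypes: np.ndarray  # (I, 2J) state indices for candidate sites
    alpha: np.ndarray  # (I, J) sequenced-allele counts at the leaves
    size_factors: np.ndarray  # (J,)
    site_rate_category: np.ndarray  # (I,)
    candidate_index: np.ndarray  # positions of candidate sites in the genome
    background_site_count: int
    cna_sites: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    cna_copy_number: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    doublet_cells: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    doublet_partners: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def leaf_genotypes(self) -> np.ndarray:
        return self.node_genotypes[:, : self.tree.n_leaves]


def simulate_tree(n_cells: int, rng: np.random.Generator, config: Optional[SimulationConfig] = None) -> CellPhylogeny:
    """Random coalescent tree with a trunk, scaled to mutation units."""
    cfg = config or SimulationConfig(n_cells=n_cells)
    height = cfg.mutation_rate * cfg.height_scale
    return random_coalescent_tree(
        n_cells,
        rng,
        height=height,
        trunk_mean_fraction=cfg.trunk_mean_fraction,
        rate_jitter_sd=cfg.rate_jitter_sd,
    )


def simulate_genotypes(
    tree: CellPhylogeny,
    d: float,
    n_sites: int,
    rng: np.random.Generator,
    eta: float = 1.0,
    n_rate_categories: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve genotype states down the tree at every site.

    Returns ``(states, categories)`` where ``states`` is an
    ``(n_sites, 2J)`` array of genotype indices (root fixed to 0/0) and
    ``categories`` the per-site discrete-Gamma rate category.
    """
    R = branch_transition_tensor(tree, d, eta, n_rate_categories)
    cats = rng.integers(0, n_rate_categories, size=n_sites)
    states = np.zeros((n_sites, tree.n_nodes), dtype=np.int8)
    states[:, tree.root] = 0
    for v in reversed(tree.postorder()):  # pre-order: parents before children
        if v == tree.root:
            continue
        pstate = states[:, tree.parent[v]]
        out = np.empty(n_sites, dtype=np.int8)
        for k in range(n_rate_categories):
            for g in range(N_STATES):
                mask = (cats == k) & (pstate == g)
                n = int(mask.sum())
                if n:
                    out[mask] = rng.choice(N_STATES, size=n, p=R[v, k, g])
        states[:, v] = out
    return states, cats


def _sample_alpha(states: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Sequenced-allele count per (site, cell), given true leaf genotypes."""
    theta_ldo = cfg.theta_ldo if cfg.dropout_mode == "ldo" else 0.0
    alpha = np.empty(states.shape, dtype=np.int8)
    u = rng.random(states.shape)
    for g in range(N_STATES):
        mask = states == g
        if not mask.any():
            continue
        dist = allele_count_distribution(
            GENOTYPE_LABELS[g], cfg.dropout_mode, cfg.theta_ado, theta_ldo
        )
        alphas = np.array(sorted(dist, reverse=True))
        cum = np.cumsum([dist[a] for a in alphas])
        alpha[mask] = alphas[np.searchsorted(cum, u[mask], side="right").clip(0, len(alphas) - 1)]
    return alpha


def _sample_observed_genotype(
    states: np.ndarray, alpha: np.ndarray, mode: str, rng: np.random.Generator
) -> np.ndarray:
    obs = np.empty(states.shape, dtype=np.int8)
    u = rng.random(states.shape)
    for g in range(N_STATES):
        for a in range(3):
            mask = (states == g) & (alpha == a)
            if not mask.any():
                continue
            dist = observed_genotype_distribution(GENOTYPE_LABELS[g], int(a), mode)
            labels = list(dist)
            cum = np.cumsum([dist[lb] for lb in labels])
            idx = np.searchsorted(cum, u[mask], side="right").clip(0, len(labels) - 1)
            obs[mask] = np.array([GENOTYPE_INDEX[lb] for lb in labels], dtype=np.int8)[idx]
    return obs


def _sample_coverage(
    alpha_eff: np.ndarray, size_factors: np.ndarray, t: float, nu: float, eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial coverage; ``alpha_eff`` may be fractional (CNAs)."""
    I, J = alpha_eff.shape
    cov = np.zeros((I, J), dtype=np.int64)
    for j in range(J):
        s = size_factors[j]
        a = alpha_eff[:, j]
        mu = a * t * s + eps
        var = mu + a**2 * nu * s**2
        pois = var <= mu
        if pois.any():
            cov[pois, j] = rng.poisson(mu[pois])
        if (~pois).any():
            m, v = mu[~pois], var[~pois]
            r = m**2 / (v - m)
            p = m / v
            cov[~pois, j] = rng.negative_binomial(r, p)
    return cov


def _sample_alt_counts(
    obs: np.ndarray, cov: np.ndarray, f: float, w1: float, w2: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-Multinomial alternative counts, sorted descending."""
    I, J = obs.shape
    alt = np.zeros((I, J, 3), dtype=np.int64)
    flat_obs = obs.ravel()
    flat_cov = cov.ravel()
    flat_alt = alt.reshape(-1, 3)
    for label in ("0/0", "0/1", "1/1", "1/1'", "0/-", "1/-"):
        g = GENOTYPE_INDEX[label]
        mask = (flat_obs == g) & (flat_cov > 0)
        n = int(mask.sum())
        if not n:
            continue
        w = w1 if _W_CLASS[label] == 1 else w2
        a = w * _freq_vector(_FREQ_CLASS[label], f)
        probs = rng.dirichlet(a, size=n)
        draws = rng.multinomial(flat_cov[mask], probs)
        flat_alt[mask] = -np.sort(-draws[:, :3], axis=1)
    return alt


def simulate_reads(
    leaf_states: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator,
    size_factors: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Emit (coverage, alt_counts, alpha, size_factors) for leaf genotypes."""
    I, J = leaf_states.shape
    if size_factors is None:
        size_factors = np.exp(rng.normal(0.0, cfg.size_factor_sd, size=J))
        size_factors /= np.exp(np.mean(np.log(size_factors)))
    t, nu = cfg.coverage_mean_var
    alpha = _sample_alpha(leaf_states, cfg, rng)
    obs = _sample_observed_genotype(leaf_states, alpha, cfg.dropout_mode, rng)
    cov = _sample_coverage(alpha.astype(float), size_factors, t, nu, cfg.eps, rng)
    alt = _sample_alt_counts(obs, cov, cfg.f, cfg.w1, cfg.w2, rng)
    return cov, alt, alpha, size_factors


def simulate_dataset(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ReadCountDataset, GroundTruth]:
    """Full forward simulation: tree, genotypes, ascertainment, reads.

    Candidate variant sites are those whose true leaf genotypes contain
    anything other than wildtype; all other genome sites are counted as
    background (``I'``).  Optional CNA / doublet corruption is applied
    at the end.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_cells, rng, cfg)
    states, cats = simulate_genotypes(
        tree, cfg.deletion_rate, cfg.genome_sites, rng, cfg.eta, cfg.n_rate_categories
    )
    leaf_states = states[:, : cfg.n_cells]
    variant = (leaf_states != 0).any(axis=1)
    idx = np.where(variant)[0]
    background = int(cfg.genome_sites - idx.size)
    cov, alt, alpha, size_factors = simulate_reads(leaf_states[idx], cfg, rng)
    data = ReadCountDataset(
        cov,
        alt,
        cell_names=[f"cell{j + 1}" for j in range(cfg.n_cells)],
        pos=idx + 1,
        background_site_count=background,
    )
    truth = GroundTruth(
        tree=tree,
        node_genotypes=states[idx],
        alpha=alpha,
        size_factors=size_factors,
        site_rate_category=cats[idx],
        candidate_index=idx,
        background_site_count=background,
    )
    if cfg.cna_fraction > 0:
        data, truth = inject_cnas(data, truth, cfg.cna_fraction, cfg, rng)
    if cfg.doublet_fraction > 0:
        data, truth = inject_doublets(data, truth, cfg.doublet_fraction, cfg, rng)
    return data, truth


def inject_cnas(
    data: ReadCountDataset,
    truth: GroundTruth,
    fraction: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ReadCountDataset, GroundTruth]:
    """Drive coverage at a fraction of sites by a copy number n != 2.

    Copy numbers are uniform on {0..10} \\ {2}; the coverage model for
    an affected site is driven by ``alpha * n / 2`` instead of
    ``alpha``, and the nucleotide counts are redrawn at the new
    coverage.  Truth genotype labels are preserved.
    """
    I = data.n_sites
    n_aff = int(round(fraction * I))
    sites = rng.choice(I, size=n_aff, replace=False)
    choices = np.array([n for n in range(11) if n != 2])
    copy_number = rng.choice(choices, size=n_aff)
    cov = data.coverage.copy()
    alt = data.alt_counts.copy()
    t, nu = cfg.coverage_mean_var
    leaf_states = truth.leaf_genotypes
    alpha_eff = truth.alpha[sites].astype(float) * (copy_number[:, None] / 2.0)
    new_cov = _sample_coverage(alpha_eff, truth.size_factors, t, nu, cfg.eps, rng)
    obs = _sample_observed_genotype(
        leaf_states[sites], truth.alpha[sites], cfg.dropout_mode, rng
    )
    new_alt = _sample_alt_counts(obs, new_cov, cfg.f, cfg.w1, cfg.w2, rng)
    cov[sites] = new_cov
    alt[sites] = new_alt
    new_data = replace(data, coverage=cov, alt_counts=alt)
    new_truth = replace(truth, cna_sites=np.sort(sites), cna_copy_number=copy_number[np.argsort(sites)])
    return new_data, new_truth


def inject_doublets(
    data: ReadCountDataset,
    truth: GroundTruth,
    fraction: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[ReadCountDataset, GroundTruth]:
    """Mix a fraction of cells with an independently re-sequenced partner.

    For each doublet, a random partner cell's reads are re-simulated
    from the partner's true genotypes and added to the host's coverage
    and (rank-wise, since alternative counts are anonymous) alternative
    counts.  The host's truth labels are kept, treating the admixture
    as noise.
    """
    J = data.n_cells
    n_dbl = int(round(fraction * J))
    hosts = rng.choice(J, size=n_dbl, replace=False)
    partners = np.empty(n_dbl, dtype=np.int64)
    cov = data.coverage.copy()
    alt = data.alt_counts.copy()
    leaf_states = truth.leaf_genotypes
    for k, jh in enumerate(hosts):
        jp = int(rng.choice([j for j in range(J) if j != jh]))
        partners[k] = jp
        pcov, palt, _, _ = simulate_reads(
            leaf_states[:, [jp]], cfg, rng, size_factors=truth.size_factors[[jp]]
        )
        cov[:, jh] += pcov[:, 0]
        alt[:, jh] = -np.sort(-(alt[:, jh] + palt[:, 0]), axis=1)
    new_data = replace(data, coverage=cov, alt_counts=alt)
    order = np.argsort(hosts)
    new_truth = replace(truth, doublet_cells=hosts[order], doublet_partners=partners[order])
    return new_data, new_truth
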