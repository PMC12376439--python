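"""Pruning likelihood, discrete-Gamma rates and acquisition bias tests."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from conftest import brute_force_site_likelihood
from scphylodel.genotypes import GENOTYPE_INDEX, N_STATES, build_rate_matrix
from scphylodel.likelihood import (
    ModelParameters,
    acquisition_bias_corrected_log_likelihood,
    background_site_log_likelihood,
    dataset_log_likelihood,
    discrete_gamma_rates,
    site_log_likelihood,
)
from scphylodel.readcounts import ReadCountDataset, ReadCountParams
from scphylodel.trees import CellPhylogeny, random_coalescent_tree


# -- discrete Gamma ----------------------------------------------------


def test_single_category_rate_is_one():
    assert discrete_gamma_rates(3.7, 1) == pytest.approx([1.0])


@pytest.mark.parametrize("eta,h", [(0.1, 4), (0.5, 4), (1.0, 3), (2.0, 8), (100.0, 4)])
def test_rates_have_mean_one(eta, h):
    rates = discrete_gamma_rates(eta, h)
    assert rates.size == h
    assert (rates > 0).all()
    assert rates.mean() == pytest.approx(1.0, abs=1e-10)


def test_large_shape_concentrates_at_one():
    assert np.all(np.abs(discrete_gamma_rates(100.0, 4) - 1.0) < 0.2)


def test_rates_match_numerical_quantile_integration():
    eta, h = 0.7, 4
    rates = discrete_gamma_rates(eta, h)
    dist = gamma_dist(a=eta, scale=1.0 / eta)
    edges = dist.ppf(np.linspace(0, 1, h + 1))
    for k in range(h):
        num, _ = quad(lambda x: x * dist.pdf(x), edges[k],
                      edges[k + 1] if np.isfinite(edges[k + 1]) else np.inf)
        assert rates[k] == pytest.approx(num * h, rel=1e-6)


def test_invalid_gamma_arguments_raise():
    with pytest.raises(ValueError):
        discrete_gamma_rates(0.0, 4)
    with pytest.raises(ValueError):
        discrete_gamma_rates(1.0, 0)


# -- pruning vs exhaustive enumeration --------------------------------


def test_wildtype_indicators_and_zero_branches_give_probability_one(tree2):
    tree2.branch_lengths[:] = 0.0
    leaf = np.zeros((2, N_STATES))
    leaf[:, GENOTYPE_INDEX["0/0"]] = 1.0
    ll = site_log_likelihood(leaf, tree2, build_rate_matrix(0.1))
    assert ll == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_pruning_equals_enumeration_three_leaves(tree3, seed):
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(0.2)
    leaf = rng.random((3, N_STATES))
    tree3.branch_lengths[: tree3.root] = rng.exponential(0.5, size=tree3.root)
    ll = site_log_likelihood(leaf, tree3, Q, eta=0.8, h=2)
    oracle = brute_force_site_likelihood(leaf, tree3, Q, eta=0.8, h=2)
    assert ll == pytest.approx(oracle, abs=1e-10)


@pytest.mark.parametrize("seed", range(12))
def test_pruning_equals_enumeration_random_trees_up_to_four_leaves(seed):
    rng = np.random.default_rng(100 + seed)
    J = int(rng.integers(2, 5))
    tree = random_coalescent_tree(J, rng, height=float(rng.uniform(0.1, 2.0)))
    Q = build_rate_matrix(float(rng.uniform(0, 1)))
    leaf = rng.random((J, N_STATES))
    eta = float(rng.uniform(0.2, 3.0))
    ll = site_log_likelihood(leaf, tree, Q, eta=eta, h=2)
    oracle = brute_force_site_likelihood(leaf, tree, Q, eta=eta, h=2)
    assert ll == pytest.approx(oracle, abs=1e-10)


def test_likelihood_invariant_under_child_permutation(tree3, rng):
    Q = build_rate_matrix(0.3)
    leaf = rng.random((3, N_STATES))
    ll = site_log_likelihood(leaf, tree3, Q)
    # relabel: swap the two children of node 3 (leaves 0 and 1)
    swapped = CellPhylogeny(tree3.parent, tree3.branch_lengths[[1, 0, 2, 3, 4, 5]])
    ll_swapped = site_log_likelihood(leaf[[1, 0, 2]], swapped, Q)
    assert ll == pytest.approx(ll_swapped, abs=1e-12)


def test_all_zero_leaf_vector_warns_and_returns_neg_inf(tree2):
    leaf = np.ones((2, N_STATES))
    leaf[0] = 0.0
    with pytest.warns(UserWarning):
        ll = site_log_likelihood(leaf, tree2, build_rate_matrix(0.1))
    assert ll == -np.inf


# -- dataset likelihood ------------------------------------------------


def _random_dataset(rng, I=5, J=3):
    cov = rng.integers(1, 25, size=(I, J))
    alt = np.zeros((I, J, 3), dtype=int)
    for i in range(I):
        for j in range(J):
            alt[i, j] = np.sort(rng.multinomial(cov[i, j], [0.3, 0.1, 0.02, 0.58])[:3])[::-1]
    return ReadCountDataset(cov, alt)


def test_dataset_likelihood_matches_per_site_oracle(tree3, rng):
    data = _random_dataset(rng)
    params = ModelParameters(d=0.2, eta=0.9, n_rate_categories=2,
                             read=ReadCountParams(t=6.0, nu=2.0, theta_ado=0.1))
    total = dataset_log_likelihood(data, tree3, params)
    from scphylodel.readcounts import leaf_log_likelihood_tensor

    leaf_log = leaf_log_likelihood_tensor(data, params.read, params.mode)
    Q = build_rate_matrix(params.d)
    oracle = sum(
        brute_force_site_likelihood(np.exp(leaf_log[i]), tree3, Q, params.eta, 2)
        for i in range(data.n_sites)
    )
    assert total == pytest.approx(oracle, abs=1e-8)


def test_concatenating_a_dataset_doubles_its_likelihood(tree3, rng):
    data = _random_dataset(rng)
    doubled = ReadCountDataset(
        np.vstack([data.coverage] * 2), np.vstack([data.alt_counts] * 2)
    )
    params = ModelParameters(read=ReadCountParams(t=6.0, nu=2.0))
    assert dataset_log_likelihood(doubled, tree3, params) == pytest.approx(
        2 * dataset_log_likelihood(data, tree3, params), rel=1e-12
    )


# -- acquisition bias correction ---------------------------------------


def test_zero_background_sites_reduce_to_uncorrected(tree3, rng):
    data = _random_dataset(rng)
    params = ModelParameters(read=ReadCountParams(t=6.0, nu=2.0))
    assert acquisition_bias_corrected_log_likelihood(
        data, tree3, params, background_sites=0
    ) == dataset_log_likelihood(data, tree3, params)


def test_background_term_additivity(tree3, rng):
    data = _random_dataset(rng)
    params = ModelParameters(read=ReadCountParams(t=6.0, nu=2.0))
    one = background_site_log_likelihood(tree3, params)
    ll10 = acquisition_bias_corrected_log_likelihood(data, tree3, params, background_sites=10)
    ll20 = acquisition_bias_corrected_log_likelihood(data, tree3, params, background_sites=20)
    # each extra background site adds exactly one wildtype-site term
    assert ll20 - ll10 == pytest.approx(10 * one, rel=1e-9)
    # discovery conditioning can only lower the variant-site likelihood
    assert ll10 - 10 * one <= dataset_log_likelihood(data, tree3, params) + 1e-9
    with pytest.raises(ValueError):
        acquisition_bias_corrected_log_likelihood(data, tree3, params, background_sites=-1)


def test_correction_shrinks_the_preferred_tree_scale():
    # on ascertained data, profile the likelihood over a global branch
    # scale: the corrected optimum must sit at a smaller total length
    from scphylodel.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_cells=4, genome_sites=3000, mutation_rate=3e-5,
                           deletion_rate=0.2, coverage_quality="high",
                           theta_ado=0.0, rate_jitter_sd=0.0, seed=9)
    data, truth = simulate_dataset(cfg)
    t, nu = cfg.coverage_mean_var
    params = ModelParameters(
        d=0.2, read=ReadCountParams(t=t, nu=nu, f=cfg.f, w1=cfg.w1, w2=cfg.w2,
                                    theta_ado=1e-6)
    )
    scales = np.linspace(0.25, 4.0, 16)

    def profile(corrected):
        out = []
        for s in scales:
            tr = truth.tree.copy()
            tr.branch_lengths[: tr.root] *= s
            if corrected:
                out.append(acquisition_bias_corrected_log_likelihood(data, tr, params))
            else:
                out.append(dataset_log_likelihood(data, tr, params))
        return scales[int(np.argmax(out))]

    assert profile(corrected=True) < profile(corrected=False)
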