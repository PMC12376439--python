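"""Read-count model tests: size factors, coverage, dropout, nucleotide pmf."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import dirichlet_multinomial

from scphylodel.genotypes import ALLELE_COUNTS, GENOTYPE_INDEX, GENOTYPE_LABELS
from scphylodel.readcounts import (
    ReadCountDataset,
    ReadCountParams,
    allele_count_distribution,
    coverage_log_pmf,
    estimate_size_factors,
    leaf_likelihoods,
    nucleotide_log_pmf,
    observed_genotype_distribution,
    _freq_vector,
    _FREQ_CLASS,
    _W_CLASS,
)


# -- size factors ------------------------------------------------------


def test_size_factors_identical_coverage_is_one():
    cov = np.full((5, 4), 13)
    assert np.allclose(estimate_size_factors(cov), 1.0)


def test_size_factors_doubled_cell():
    cov = np.array([[10, 20], [4, 8], [30, 60]])
    s = estimate_size_factors(cov)
    assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_zero_coverage_sites_excluded():
    # cell 0 has zero coverage at site 1; its median uses sites 0 and 2 only
    cov = np.array([[10, 10], [0, 50], [10, 10]])
    s = estimate_size_factors(cov)
    assert s[0] == pytest.approx(1.0)


def test_size_factors_all_zero_cell_raises():
    cov = np.array([[10, 0], [5, 0]])
    with pytest.raises(ValueError, match="cell 1"):
        estimate_size_factors(cov)


# -- coverage model ----------------------------------------------------


def test_coverage_pmf_moments_by_direct_summation():
    params = ReadCountParams(t=10.0, nu=4.0)
    c = np.arange(0, 2001)
    logp = coverage_log_pmf(c, 2, params, 1.0)
    p = np.exp(logp)
    mu = 2 * 10.0 + params.eps
    var = mu + 4 * 4.0
    assert p.sum() == pytest.approx(1.0, abs=1e-6)
    assert (p * c).sum() == pytest.approx(mu, abs=1e-6)
    assert (p * c**2).sum() - ((p * c).sum()) ** 2 == pytest.approx(var, abs=1e-4)


def test_coverage_pmf_zero_alleles_is_poisson_at_epsilon():
    params = ReadCountParams()
    c = np.arange(0, 10)
    p = np.exp(coverage_log_pmf(c, 0, params, 1.0))
    assert (p * c).sum() == pytest.approx(1e-6, rel=1e-3)
    assert p[0] == pytest.approx(np.exp(-1e-6))


def test_coverage_pmf_poisson_limit_when_nu_zero():
    params = ReadCountParams(t=5.0, nu=0.0)
    c = np.arange(0, 200)
    p = np.exp(coverage_log_pmf(c, 1, params, 1.0))
    assert p.sum() == pytest.approx(1.0, abs=1e-8)
    assert (p * c).sum() == pytest.approx(5.0 + 1e-6, rel=1e-6)


def test_nb_reparameterization_round_trip():
    mu, var = 14.0, 50.0
    p, r = mu / var, mu**2 / (var - mu)
    assert r * (1 - p) / p == pytest.approx(mu)
    assert r * (1 - p) / p**2 == pytest.approx(var)


# -- dropout tables ----------------------------------------------------


def test_observed_genotype_examples():
    assert observed_genotype_distribution("0/1", 1, "ado") == {"0/-": 0.5, "1/-": 0.5}
    assert observed_genotype_distribution("0/0", 2, "ado") == {"0/0": 1.0}
    assert observed_genotype_distribution("0/0", 2, "ldo") == {"0/0": 1.0}
    assert observed_genotype_distribution("1/1'", 0, "ldo") == {"-": 1.0}
    assert observed_genotype_distribution("1/1'", 1, "ado") == {"1/-": 1.0}


def test_observed_genotype_rows_sum_to_one_both_modes():
    for mode in ("ado", "ldo"):
        for g in GENOTYPE_LABELS:
            ell = ALLELE_COUNTS[GENOTYPE_INDEX[g]]
            alphas = range(ell + 1) if mode == "ldo" else range(max(ell - 1, 0), ell + 1)
            for a in alphas:
                dist = observed_genotype_distribution(g, a, mode)
                assert sum(dist.values()) == pytest.approx(1.0)


def test_observed_genotype_alpha_exceeding_alleles_raises():
    with pytest.raises(ValueError):
        observed_genotype_distribution("0/-", 2, "ado")
    with pytest.raises(ValueError):
        observed_genotype_distribution("-", 1, "ldo")


def test_allele_count_distribution_degenerate_without_dropout():
    for g in GENOTYPE_LABELS:
        dist = allele_count_distribution(g, "ado", 0.0, 0.0)
        assert dist == {int(ALLELE_COUNTS[GENOTYPE_INDEX[g]]): 1.0}


def test_allele_count_distribution_modes():
    # ADO mode: diploid genotypes never lose both alleles
    assert 0 not in allele_count_distribution("0/1", "ado", 0.3, 0.0)
    # LDO mode: diploid genotypes support alpha in {2, 1, 0}
    dist = allele_count_distribution("0/0", "ldo", 0.2, 0.1)
    assert set(dist) == {2, 1, 0}
    assert dist[0] == pytest.approx(0.1) and dist[1] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        allele_count_distribution("0/0", "ldo", 0.6, 0.5)


def test_compound_dropout_distribution_is_normalized():
    # sum over (alpha, g') of P(alpha|g) P(g'|g, alpha) is 1 for every g
    for mode, tha, thl in (("ado", 0.25, 0.0), ("ldo", 0.2, 0.1)):
        for g in GENOTYPE_LABELS:
            tot = 0.0
            for a, pa in allele_count_distribution(g, mode, tha, thl).items():
                tot += pa * sum(observed_genotype_distribution(g, a, mode).values())
            assert tot == pytest.approx(1.0)


# -- nucleotide model --------------------------------------------------


def test_nucleotide_pmf_deleted_genotype_is_one():
    assert nucleotide_log_pmf(np.array([3, 1, 0]), 10, "-", 0.01, 20, 20) == 0.0


def test_nucleotide_pmf_sums_to_one_by_enumeration():
    c = 4
    for g_obs, w in (("0/0", 20.0), ("0/1", 7.0), ("1/1'", 5.0)):
        tot = []
        for m1 in range(c + 1):
            for m2 in range(c + 1 - m1):
                for m3 in range(c + 1 - m1 - m2):
                    tot.append(
                        nucleotide_log_pmf(np.array([m1, m2, m3]), c, g_obs, 0.01, w, w)
                    )
        assert np.exp(logsumexp(tot)) == pytest.approx(1.0, abs=1e-10)


def test_nucleotide_pmf_matches_scipy_dirichlet_multinomial(rng):
    for label in ("0/0", "0/1", "1/1", "1/1'"):
        f, w1, w2 = 0.013, 31.0, 9.0
        w = w1 if _W_CLASS[label] == 1 else w2
        a = w * _freq_vector(_FREQ_CLASS[label], f)
        c = 25
        m = np.array([7, 5, 3])
        counts = np.array([*m, c - m.sum()])
        expected = dirichlet_multinomial.logpmf(counts, a, c)
        assert nucleotide_log_pmf(m, c, label, f, w1, w2) == pytest.approx(expected)


def test_nucleotide_pmf_heterozygous_expected_alt_fraction_half():
    # for g' = 0/1 at f -> 0 the expected top-alternative frequency is 1/2
    v = _freq_vector(2, 1e-9)
    assert v[0] == pytest.approx(0.5, abs=1e-9)
    assert v.sum() == pytest.approx(1.0)


def test_nucleotide_pmf_minor_alternative_permutation_invariance():
    # f1/f3 genotypes assign equal frequencies to the minor alternatives
    for label in ("0/0", "1/1", "0/-", "1/-"):
        a = nucleotide_log_pmf(np.array([5, 2, 1]), 12, label, 0.02, 15, 15)
        b = nucleotide_log_pmf(np.array([5, 1, 2]), 12, label, 0.02, 15, 15)
        assert a == pytest.approx(b)


def test_nucleotide_pmf_counts_exceeding_coverage_raise():
    with pytest.raises(ValueError):
        nucleotide_log_pmf(np.array([3, 2, 1]), 4, "0/0", 0.01, 10, 10)


# -- leaf likelihoods --------------------------------------------------


def _toy_dataset(c, m, J=1):
    cov = np.full((1, J), c)
    alt = np.tile(np.asarray(m), (1, J, 1))
    return ReadCountDataset(cov, alt)


def test_leaf_likelihood_reduces_to_single_term_without_dropout():
    data = _toy_dataset(12, [2, 0, 0])
    params = ReadCountParams(t=6.0, nu=2.0, theta_ado=0.0)
    vec = leaf_likelihoods(0, 0, data, params)
    expected = np.exp(
        nucleotide_log_pmf(np.array([2, 0, 0]), 12, "0/0", params.f, params.w1, params.w2)
        + coverage_log_pmf(12, 2, params)
    )
    assert vec[GENOTYPE_INDEX["0/0"]] == pytest.approx(expected, rel=1e-12)


def test_leaf_likelihood_deleted_state_is_coverage_only():
    data = _toy_dataset(3, [1, 0, 0])
    params = ReadCountParams(theta_ado=0.15)
    vec = leaf_likelihoods(0, 0, data, params)
    assert vec[GENOTYPE_INDEX["-"]] == pytest.approx(
        np.exp(coverage_log_pmf(3, 0, params)), rel=1e-12
    )
    assert ((vec > 0) & (vec <= 1)).all()


@pytest.mark.parametrize("mode,tha,thl", [("ado", 0.2, 0.0), ("ldo", 0.15, 0.08)])
def test_leaf_likelihood_matches_hand_expanded_double_sum(mode, tha, thl):
    data = _toy_dataset(9, [4, 1, 0])
    params = ReadCountParams(t=5.0, nu=3.0, f=0.01, w1=25, w2=8,
                             theta_ado=tha, theta_ldo=thl)
    vec = leaf_likelihoods(0, 0, data, params, mode)
    for g in GENOTYPE_LABELS:
        tot = 0.0
        for a, pa in allele_count_distribution(g, mode, tha, thl).items():
            cov_term = np.exp(coverage_log_pmf(9, a, params))
            for g_obs, pg in observed_genotype_distribution(g, a, mode).items():
                nuc = np.exp(
                    nucleotide_log_pmf(np.array([4, 1, 0]), 9, g_obs,
                                       params.f, params.w1, params.w2)
                )
                tot += pa * pg * cov_term * nuc
        assert vec[GENOTYPE_INDEX[g]] == pytest.approx(tot, rel=1e-10)


# -- dataset container and TSV dialect --------------------------------


def test_dataset_validates_counts():
    with pytest.raises(ValueError):  # alt counts exceed coverage
        ReadCountDataset(np.array([[3]]), np.array([[[2, 1, 1]]]))
    with pytest.raises(ValueError):  # not sorted descending
        ReadCountDataset(np.array([[5]]), np.array([[[1, 2, 0]]]))


def test_dataset_tsv_round_trip(tmp_path, rng):
    I, J = 6, 3
    cov = rng.integers(0, 30, size=(I, J))
    alt = np.zeros((I, J, 3), dtype=int)
    for i in range(I):
        for j in range(J):
            raw = rng.multinomial(cov[i, j], [0.2, 0.1, 0.05, 0.65])[:3]
            alt[i, j] = np.sort(raw)[::-1]
    data = ReadCountDataset(cov, alt, cell_names=["a", "b", "c"],
                            background_site_count=42)
    path = tmp_path / "reads.tsv"
    data.to_tsv(path)
    back = ReadCountDataset.from_tsv(path)
    assert np.array_equal(back.coverage, data.coverage)
    assert np.array_equal(back.alt_counts, data.alt_counts)
    assert back.cell_names == data.cell_names
    assert back.background_site_count == 42
    assert np.array_equal(back.pos, data.pos)
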