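"""ML genotype decoding, event calling and dropout calling tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scphylodel.calling import (
    call_dropouts,
    call_events,
    ml_genotypes,
    read_variant_table,
    write_variant_table,
)
from scphylodel.genotypes import (
    ALLELE_COUNTS,
    GENOTYPE_INDEX,
    GENOTYPE_LABELS,
    N_STATES,
    build_rate_matrix,
    transition_probabilities,
)
from scphylodel.likelihood import ModelParameters, discrete_gamma_rates
from scphylodel.readcounts import ReadCountDataset, ReadCountParams, leaf_log_likelihood_tensor
from scphylodel.simulate import SimulationConfig, simulate_dataset


def _exhaustive_joint_argmax(data, tree, params):
    """Oracle: argmax over all 7^(2J-1) full node assignments and categories."""
    leaf_log = leaf_log_likelihood_tensor(data, params.read, params.mode)
    rates = discrete_gamma_rates(params.eta, params.n_rate_categories)
    Q = build_rate_matrix(params.d)
    J = tree.n_leaves
    free = list(range(tree.root))  # all nodes except the clamped root
    best = np.zeros((data.n_sites, tree.n_nodes), dtype=int)
    for i in range(data.n_sites):
        best_score = -np.inf
        for k, r in enumerate(rates):
            with np.errstate(divide="ignore"):
                logR = {
                    v: np.log(transition_probabilities(Q, tree.branch_lengths[v] * r))
                    for v in free
                }
            for combo in itertools.product(range(N_STATES), repeat=len(free)):
                state = dict(zip(free, combo))
                state[tree.root] = 0
                score = 0.0
                for v in free:
                    score += logR[v][state[tree.parent[v]], state[v]]
                for leaf in range(J):
                    score += leaf_log[i, leaf, state[leaf]]
                if score > best_score + 1e-12:
                    best_score = score
                    best[i] = [state[v] for v in range(tree.n_nodes)]
    return best


def test_joint_decoding_matches_exhaustive_argmax(tree3, rng):
    I, J = 4, 3
    cov = rng.integers(0, 20, size=(I, J))
    alt = np.zeros((I, J, 3), dtype=int)
    for i in range(I):
        for j in range(J):
            alt[i, j] = np.sort(rng.multinomial(cov[i, j], [0.4, 0.1, 0.0, 0.5])[:3])[::-1]
    data = ReadCountDataset(cov, alt)
    params = ModelParameters(d=0.3, eta=0.8, n_rate_categories=2,
                             read=ReadCountParams(t=6.0, nu=3.0, theta_ado=0.15))
    asg = ml_genotypes(data, tree3, params)
    oracle = _exhaustive_joint_argmax(data, tree3, params)
    assert np.array_equal(asg.node_genotypes, oracle)


def test_noise_floor_decoding_recovers_all_leaf_genotypes():
    cfg = SimulationConfig(n_cells=6, genome_sites=2000, mutation_rate=3e-5,
                           deletion_rate=1.0, theta_ado=0.0, f=1e-6,
                           coverage_mean=300.0, coverage_variance=1.0,
                           coverage_quality="high", size_factor_sd=0.0, seed=13)
    data, truth = simulate_dataset(cfg)
    params = ModelParameters(
        d=1.0, read=ReadCountParams(t=300.0, nu=1.0, f=1e-6, w1=cfg.w1, w2=cfg.w2,
                                    theta_ado=1e-9)
    )
    asg = ml_genotypes(data, truth.tree, params)
    assert np.array_equal(asg.leaf_genotypes, truth.leaf_genotypes)


def test_zero_reads_everywhere_decodes_without_crash(tree3):
    data = ReadCountDataset(np.zeros((3, 3), dtype=int), np.zeros((3, 3, 3), dtype=int))
    params = ModelParameters(read=ReadCountParams(theta_ado=1e-9))
    asg = ml_genotypes(data, tree3, params)
    assert asg.node_genotypes.shape == (3, 6)
    assert np.all(asg.leaf_alpha == 0)  # nothing was sequenced


def test_decoded_histories_only_use_supported_transitions():
    cfg = SimulationConfig(n_cells=8, genome_sites=2000, mutation_rate=3e-5,
                           deletion_rate=0.5, seed=17)
    data, truth = simulate_dataset(cfg)
    params = ModelParameters(d=0.5, read=cfg.read_params(np.ones(8)))
    asg = ml_genotypes(data, truth.tree, params)
    # call_events raises on any transition outside the support
    events = call_events(asg, truth.tree)
    for e in events:
        parent_g = asg.node_genotypes[e.site, e.parent_node]
        child_g = asg.node_genotypes[e.site, e.child_node]
        assert ALLELE_COUNTS[child_g] <= ALLELE_COUNTS[parent_g]


def _assignment_from_states(tree, states):
    from scphylodel.calling import GenotypeAssignment

    I = states.shape[0]
    J = tree.n_leaves
    return GenotypeAssignment(
        node_genotypes=states,
        leaf_alpha=ALLELE_COUNTS[states[:, :J]].astype(np.int8),
        cell_names=[f"cell{j+1}" for j in range(J)],
        pos=np.arange(1, I + 1),
        chrom=np.array(["1"] * I, dtype=object),
        ref=np.array(["N"] * I, dtype=object),
        rate_category=np.zeros(I, dtype=int),
    )


def test_single_trunk_mutation_yields_one_event(tree3):
    states = np.zeros((1, 6), dtype=np.int8)
    # trunk: root(5) -> mrca(4): 0/0 -> 0/1 inherited by everything below
    for v in (0, 1, 2, 3, 4):
        states[0, v] = GENOTYPE_INDEX["0/1"]
    events = call_events(_assignment_from_states(tree3, states), tree3)
    assert len(events) == 1
    assert events[0].event == "single point mutation"
    assert events[0].child_node == tree3.mrca
    assert not events[0].parallel


def test_parallel_point_mutations_are_flagged(tree3):
    states = np.zeros((1, 6), dtype=np.int8)
    states[0, 0] = GENOTYPE_INDEX["0/1"]  # private in leaf 0
    states[0, 2] = GENOTYPE_INDEX["0/1"]  # private in leaf 2 (disjoint branch)
    events = call_events(_assignment_from_states(tree3, states), tree3)
    assert len(events) == 2
    assert all(e.event == "single point mutation" and e.parallel for e in events)


def test_chained_deletion_then_mutation_addition(tree3):
    states = np.zeros((1, 6), dtype=np.int8)
    # trunk: 0/0 -> 0/-; then leaf 0: 0/- -> 1/-
    for v in (0, 1, 2, 3, 4):
        states[0, v] = GENOTYPE_INDEX["0/-"]
    states[0, 0] = GENOTYPE_INDEX["1/-"]
    events = call_events(_assignment_from_states(tree3, states), tree3)
    names = sorted(e.event for e in events)
    assert names == ["single deletion (not LOH)", "single deletion point mutation addition"]


def test_impossible_decoded_transition_raises(tree3):
    states = np.zeros((1, 6), dtype=np.int8)
    states[0, 4] = GENOTYPE_INDEX["-"]  # MRCA fully deleted ...
    states[0, 0] = GENOTYPE_INDEX["0/0"]  # ... but a leaf regains alleles
    states[0, 1] = GENOTYPE_INDEX["-"]
    states[0, 2] = GENOTYPE_INDEX["-"]
    states[0, 3] = GENOTYPE_INDEX["-"]
    with pytest.raises(RuntimeError, match="impossible transition"):
        call_events(_assignment_from_states(tree3, states), tree3)


def test_dropout_calls(tree3):
    states = np.zeros((2, 6), dtype=np.int8)
    states[0, 0] = GENOTYPE_INDEX["0/1"]
    states[1, 1] = GENOTYPE_INDEX["-"]
    asg = _assignment_from_states(tree3, states)
    asg.leaf_alpha[0, 0] = 1  # ADO on the 0/1 leaf
    asg.leaf_alpha[1, 2] = 0  # wildtype leaf with locus dropout
    drops = call_dropouts(asg, "ldo")
    assert drops["ado"][0, 0] and drops["ado"].sum() == 1
    assert drops["ldo"][1, 2] and drops["ldo"].sum() == 1
    # the fully deleted leaf has no alleles to lose
    assert not drops["ado"][1, 1] and not drops["ldo"][1, 1]
    with pytest.raises(ValueError):
        call_dropouts(asg, "ado", include_ldo=True)


def test_variant_table_round_trip(tmp_path, tree3):
    states = np.zeros((3, 6), dtype=np.int8)
    states[1, 0] = GENOTYPE_INDEX["0/1"]
    asg = _assignment_from_states(tree3, states)
    path = tmp_path / "variants.tsv"
    df = write_variant_table(asg, path)
    back = read_variant_table(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False)
    assert set(back["genotype"]) <= set(GENOTYPE_LABELS)
    assert asg.n_variant_sites == 1
    # all-wildtype assignment -> 0 variant sites
    asg0 = _assignment_from_states(tree3, np.zeros((3, 6), dtype=np.int8))
    assert asg0.n_variant_sites == 0
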