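import numpy as np
import pytest

from scphylodel.trees import CellPhylogeny


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tree3():
    """((0,1)3, 2)4 - 5: three cells, MRCA node 4, root 5."""
    parent = np.array([3, 3, 4, 4, 5, -1])
    lengths = np.array([0.10, 0.20, 0.15, 0.05, 0.30, 0.0])
    return CellPhylogeny(parent, lengths)


@pytest.fixture
def tree2():
    """Two cells joined at the MRCA (node 2), root 3, trunk above."""
    parent = np.array([2, 2, 3, -1])
    lengths = np.array([0.1, 0.2, 0.3, 0.0])
    return CellPhylogeny(parent, lengths)


def brute_force_site_likelihood(leaf_vectors, tree, Q, eta, h):
    """Exhaustive enumeration over internal-node genotypes (root clamped).

    Independent oracle for the pruning engine: sums the joint
    probability over all assignments of the free ancestral nodes,
    marginalizing leaf states against the leaf likelihood vectors.
    """
    import itertools

    from scphylodel.genotypes import N_STATES, transition_probabilities
    from scphylodel.likelihood import discrete_gamma_rates

    J = tree.n_leaves
    rates = discrete_gamma_rates(eta, h)
    free = [v for v in range(J, tree.n_nodes - 1)]  # internal nodes except root
    total = 0.0
    for r in rates:
        R = {v: transition_probabilities(Q, tree.branch_lengths[v] * r)
             for v in range(tree.root)}
        for combo in itertools.product(range(N_STATES), repeat=len(free)):
            state = dict(zip(free, combo))
            state[tree.root] = 0
            p = 1.0
            for v in free:
                p *= R[v][state[tree.parent[v]], state[v]]
            for leaf in range(J):
                p *= sum(
                    R[leaf][state[tree.parent[leaf]], g] * leaf_vectors[leaf, g]
                    for g in range(N_STATES)
                )
            total += p
    return np.log(total / h)
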