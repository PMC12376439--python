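"""Rooted cell phylogenies with a trunk.

A tree over ``J`` sequenced cells has ``2J`` nodes: leaves ``0..J-1``
(the cells), internal nodes ``J..2J-2`` (ancestral cells) and the root
``2J-1``, which represents a healthy diploid cell and has exactly one
child — the most recent common ancestor (MRCA) of the sampled cells.
The root-to-MRCA branch is the *trunk*.  Every node except the root has
a branch to its parent, so there are ``2J-1`` branch lengths, measured
in expected somatic mutations per site.  No molecular clock is assumed.
"""

from __future__ import annotations

import io
from typing import Optional, Sequence

import dendropy
import numpy as np

__all__ = ["CellPhylogeny", "random_coalescent_tree", "upgma_tree"]


class CellPhylogeny:
    """Rooted binary cell phylogeny with a trunk.

    Parameters
    ----------
    parent : array of int, shape (2J,)
        ``parent[v]`` is the parent node of ``v``; the root has -1.
    branch_lengths : array of float, shape (2J,)
        ``branch_lengths[v]`` is the length of the branch above ``v``
        (expected mutations per site); the root entry is ignored and
        stored as 0.
    leaf_names : sequence of str, optional
        Names of the J cells; defaults to ``cell1..cellJ``.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_lengths: Sequence[float],
        leaf_names: Optional[Sequence[str]] = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64).copy()
        n_nodes = self.parent.size
        if n_nodes < 4 or n_nodes % 2 != 0:
            raise ValueError("a cell phylogeny needs 2J nodes with J >= 2")
        self.n_nodes = n_nodes
        self.n_leaves = n_nodes // 2
        self.root = n_nodes - 1
        self.branch_lengths = np.asarray(branch_lengths, dtype=float).copy()
        if self.branch_lengths.size != n_nodes:
            raise ValueError("branch_lengths must have one entry per node")
        if np.any(self.branch_lengths[: self.root] < 0):
            raise ValueError("branch lengths must be non-negative")
        self.branch_lengths[self.root] = 0.0
        if leaf_names is None:
            leaf_names = [f"cell{i + 1}" for i in range(self.n_leaves)]
        if len(leaf_names) != self.n_leaves:
            raise ValueError("need one name per leaf")
        self.leaf_names = list(leaf_names)
        self._validate()

    def _validate(self) -> None:
        J = self.n_leaves
        if self.parent[self.root] != -1:
            raise ValueError("last node must be the root (parent -1)")
        counts = np.zeros(self.n_nodes, dtype=int)
        for v in range(self.n_nodes - 1):
            p = self.parent[v]
            if not (0 <= p < self.n_nodes) or p < J:
                raise ValueError(f"node {v} has invalid parent {p}")
            counts[p] += 1
        if counts[self.root] != 1:
            raise ValueError("root must have exactly one child (the trunk)")
        if np.any(counts[J : self.root] != 2):
            raise ValueError("internal nodes must be bifurcating")
        if np.any(counts[:J] != 0):
            raise ValueError("leaves cannot have children")

    # -- basic structure ------------------------------------------------
    @property
    def mrca(self) -> int:
        """The single child of the root."""
        return int(np.where(self.parent == self.root)[0][0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            ch[self.parent[v]].append(v)
        return ch

    def postorder(self) -> list[int]:
        """Nodes in post-order (children before parents, root last)."""
        ch = self.children()
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(ch[v])
        order.reverse()
        return order

    def total_length(self) -> float:
        return float(self.branch_lengths[: self.root].sum())

    def copy(self) -> "CellPhylogeny":
        return CellPhylogeny(self.parent, self.branch_lengths, self.leaf_names)

    def subtree_leaves(self, v: int) -> list[int]:
        ch = self.children()
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                out.append(u)
            stack.extend(ch[u])
        return sorted(out)

    # -- Newick / dendropy interop --------------------------------------
    def to_dendropy(
        self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None
    ) -> dendropy.Tree:
        ch = self.children()
        tns = taxon_namespace or dendropy.TaxonNamespace(self.leaf_names)
        tree = dendropy.Tree(taxon_namespace=tns)
        nodes: dict[int, dendropy.Node] = {self.root: tree.seed_node}
        for v in reversed(self.postorder()):
            if v == self.root:
                continue
            node = dendropy.Node()
            node.edge.length = float(self.branch_lengths[v])
            nodes[self.parent[v]].add_child(node)
            nodes[v] = node
            if v < self.n_leaves:
                node.taxon = tns.get_taxon(self.leaf_names[v])
        tree.is_rooted = True
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "CellPhylogeny":
        tree = tree.clone(depth=1)
        leaves = [lf for lf in tree.leaf_node_iter()]
        J = len(leaves)
        leaf_names = [lf.taxon.label if lf.taxon else f"cell{i+1}" for i, lf in enumerate(leaves)]
        seed = tree.seed_node
        seed_children = seed.child_nodes()
        if len(seed_children) == 2:
            # no explicit trunk in the source tree: graft a zero-length one
            root = dendropy.Node()
            inner = seed
            new_tree_root = root
            root.add_child(inner)
            inner.edge.length = inner.edge.length or 0.0
            seed = root
        elif len(seed_children) != 1:
            raise ValueError("tree root must have one (trunk) or two children")
        index: dict[dendropy.Node, int] = {lf: i for i, lf in enumerate(leaves)}
        internal = [nd for nd in seed.postorder_iter() if nd not in index and nd is not seed]
        for k, nd in enumerate(internal):
            index[nd] = J + k
        index[seed] = 2 * J - 1
        parent = np.full(2 * J, -1, dtype=np.int64)
        lengths = np.zeros(2 * J)
        for nd, v in index.items():
            if nd is seed:
                continue
            parent[v] = index[nd.parent_node]
            lengths[v] = float(nd.edge.length or 0.0)
        return cls(parent, lengths, leaf_names)

    @classmethod
    def from_newick(cls, newick: str) -> "CellPhylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def write_nexus(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_dendropy().as_string(schema="nexus"))

    @classmethod
    def read_newick(cls, path) -> "CellPhylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def __eq__(self, other) -> bool:  # structural equality
        return (
            isinstance(other, CellPhylogeny)
            and np.array_equal(self.parent, other.parent)
            and np.allclose(self.branch_lengths, other.branch_lengths)
            and self.leaf_names == other.leaf_names
        )


def random_coalescent_tree(
    n_leaves: int,
    rng: np.random.Generator,
    height: float = 1.0,
    trunk_mean_fraction: float = 1.0,
    rate_jitter_sd: float = 0.0,
    leaf_names: Optional[Sequence[str]] = None,
) -> CellPhylogeny:
    """Random Kingman-coalescent tree topology with a trunk.

    Pairs of lineages coalesce at exponential waiting times; the trunk
    length is drawn Exponential with mean ``trunk_mean_fraction`` times
    the MRCA height.  The whole tree is rescaled so the root-to-leaf
    height equals ``height`` (expected mutations per site).  If
    ``rate_jitter_sd > 0``, each branch is additionally multiplied by an
    i.i.d. LogNormal(0, sd) factor, breaking the molecular clock.
    """
    J = int(n_leaves)
    if J < 2:
        raise ValueError("need at least two cells")
    node_height = np.zeros(2 * J)
    parent = np.full(2 * J, -1, dtype=np.int64)
    active = list(range(J))
    t = 0.0
    nxt = J
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_height[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    mrca = active[0]
    trunk = rng.exponential(max(trunk_mean_fraction * t, 1e-12))
    root = 2 * J - 1
    parent[mrca] = root
    node_height[root] = t + trunk
    lengths = np.zeros(2 * J)
    for v in range(root):
        lengths[v] = node_height[parent[v]] - node_height[v]
    scale = height / node_height[root]
    lengths *= scale
    if rate_jitter_sd > 0:
        lengths[:root] *= rng.lognormal(0.0, rate_jitter_sd, size=root)
    return CellPhylogeny(parent, lengths, leaf_names)


def upgma_tree(
    distances: np.ndarray,
    leaf_names: Optional[Sequence[str]] = None,
    trunk_length: float = 0.0,
) -> CellPhylogeny:
    """Average-linkage (UPGMA) tree from a pairwise distance matrix.

    Used as a data-driven starting topology for MCMC; branch lengths
    derive from cluster merge heights (floored at a small positive
    value) and a trunk of ``trunk_length`` is attached above the MRCA.
    """
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    D = np.asarray(distances, dtype=float)
    J = D.shape[0]
    if D.shape != (J, J):
        raise ValueError("distance matrix must be square")
    Z = average(squareform(D, checks=False))
    parent = np.full(2 * J, -1, dtype=np.int64)
    heights = np.zeros(2 * J)
    for k, (a, b, h, _) in enumerate(Z):
        v = J + k
        parent[int(a)] = v
        parent[int(b)] = v
        heights[v] = h / 2.0
    mrca = 2 * J - 2
    root = 2 * J - 1
    parent[mrca] = root
    heights[root] = heights[mrca] + max(trunk_length, 1e-9)
    lengths = np.zeros(2 * J)
    for v in range(root):
        lengths[v] = max(heights[parent[v]] - heights[v], 1e-9)
    return CellPhylogeny(parent, lengths, leaf_names)
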