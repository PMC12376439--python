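"""Variant calling from a fixed tree and parameter estimates.

Given the summarized posterior (maximum clade credibility tree,
posterior-median parameters) and the read counts, every node of the
tree is assigned a genotype per site by *joint* maximum likelihood:
max-product dynamic programming up the tree with back-tracking, root
clamped to wildtype, maximizing over the shared site-rate category as
well.  Joint decoding guarantees a consistent evolutionary history —
every parent-to-child pair lies in the support of the transition model
— so branch events can be read off directly and classified.

For each leaf the number of sequenced alleles ``alpha`` is decoded
jointly with the observed genotype inside the leaf term, which yields
allelic-dropout (ADO: one allele lost) and locus-dropout (LDO: both
alleles of a diploid site lost) calls per cell and site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import (
    ALLELE_COUNTS,
    GENOTYPE_LABELS,
    GENOTYPE_INDEX,
    N_STATES,
    classify_transition,
)
from .likelihood import ModelParameters, branch_transition_tensor
from .readcounts import (
    ReadCountDataset,
    allele_count_distribution,
    coverage_log_pmf,
    leaf_log_likelihood_tensor,
    nucleotide_log_pmf,
    observed_genotype_distribution,
)
from .trees import CellPhylogeny

__all__ = [
    "GenotypeAssignment",
    "EventCall",
    "ml_genotypes",
    "call_events",
    "call_dropouts",
    "write_variant_table",
    "read_variant_table",
    "write_event_table",
]


@dataclass
class GenotypeAssignment:
    """Jointly most likely genotypes at every node, per site."""

    node_genotypes: np.ndarray  # (I, 2J) genotype indices; root column is 0
    leaf_alpha: np.ndarray  # (I, J) decoded sequenced-allele counts
    cell_names: list[str]
    pos: np.ndarray  # 1-based site positions
    chrom: np.ndarray
    ref: np.ndarray
    rate_category: np.ndarray  # (I,) decoded site-rate category
    log_score: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def leaf_genotypes(self) -> np.ndarray:
        return self.node_genotypes[:, : self.leaf_alpha.shape[1]]

    @property
    def n_variant_sites(self) -> int:
        return int((self.leaf_genotypes != 0).any(axis=1).sum())


@dataclass(frozen=True)
class EventCall:
    """One mutation event on one branch at one site."""

    site: int  # row index into the assignment
    parent_node: int
    child_node: int
    event: str
    parallel: bool = False


def ml_genotypes(
    data: ReadCountDataset, tree: CellPhylogeny, params: ModelParameters
) -> GenotypeAssignment:
    """Joint maximum-likelihood genotype assignment for all nodes and sites.

    Max-product DP up the tree per rate category; the best category per
    site is kept and back-tracked.  Ties break toward the genotype
    earlier in canonical order (argmax convention), deterministically.
    """
    I, J = data.n_sites, data.n_cells
    h = params.n_rate_categories
    leaf_log = leaf_log_likelihood_tensor(data, params.read, params.mode)
    R = branch_transition_tensor(tree, params.d, params.eta, h)
    with np.errstate(divide="ignore"):
        logR = np.log(R)  # (2J, h, 7, 7)
    children = tree.children()
    order = tree.postorder()
    best_states = np.zeros((h, I, tree.n_nodes), dtype=np.int8)
    scores = np.full((h, I), -np.inf)
    for k in range(h):
        delta: dict[int, np.ndarray] = {}
        back: dict[int, np.ndarray] = {}
        for v in order:
            if v < J:
                delta[v] = leaf_log[:, v, :]
            else:
                acc = np.zeros((I, N_STATES))
                for c in children[v]:
                    # (I, parent 7, child 7): transition + subtree score
                    B = logR[c, k][None, :, :] + delta.pop(c)[:, None, :]
                    back[c] = B.argmax(axis=2).astype(np.int8)
                    acc = acc + B.max(axis=2)
                delta[v] = acc
        scores[k] = delta[tree.root][:, 0]  # root clamped to 0/0
        # back-track
        states = best_states[k]
        states[:, tree.root] = 0
        for v in reversed(order):
            if v == tree.root:
                continue
            p = tree.parent[v]
            states[:, v] = np.take_along_axis(
                back[v], states[:, p][:, None].astype(np.int64), axis=1
            )[:, 0]
    best_k = scores.argmax(axis=0)
    node_geno = best_states[best_k, np.arange(I)]
    alpha = _decode_alpha(data, params, node_geno[:, :J])
    return GenotypeAssignment(
        node_genotypes=node_geno,
        leaf_alpha=alpha,
        cell_names=list(data.cell_names),
        pos=np.asarray(data.pos),
        chrom=np.asarray(data.chrom),
        ref=np.asarray(data.ref),
        rate_category=best_k,
        log_score=scores[best_k, np.arange(I)],
    )


def _decode_alpha(
    data: ReadCountDataset, params: ModelParameters, leaf_geno: np.ndarray
) -> np.ndarray:
    """Most likely (alpha, g') per leaf given the decoded true genotype."""
    I, J = leaf_geno.shape
    r = params.read
    s = r.size_factors if r.size_factors is not None else np.ones(J)
    theta_ldo = r.theta_ldo if params.mode == "ldo" else 0.0
    alpha_out = np.zeros((I, J), dtype=np.int8)
    # precompute coverage log-pmfs per cell and alpha
    cov_ll = np.empty((3, I, J))
    for a in range(3):
        for j in range(J):
            cov_ll[a, :, j] = coverage_log_pmf(data.coverage[:, j], a, r, s[j])
    nuc_cache: dict[str, np.ndarray] = {}

    def nuc(label: str) -> np.ndarray:
        if label not in nuc_cache:
            nuc_cache[label] = nucleotide_log_pmf(
                data.alt_counts, data.coverage, label, r.f, r.w1, r.w2
            )
        return nuc_cache[label]

    for g in range(N_STATES):
        mask = leaf_geno == g
        if not mask.any():
            continue
        best = np.full(mask.sum(), -np.inf)
        best_a = np.zeros(mask.sum(), dtype=np.int8)
        pa = allele_count_distribution(GENOTYPE_LABELS[g], params.mode, r.theta_ado, theta_ldo)
        for a, p_alpha in pa.items():
            for g_obs, p_obs in observed_genotype_distribution(
                GENOTYPE_LABELS[g], a, params.mode
            ).items():
                term = (
                    np.log(p_alpha * p_obs)
                    + cov_ll[a][mask]
                    + nuc(g_obs)[mask]
                )
                upd = term > best
                best = np.where(upd, term, best)
                best_a = np.where(upd, a, best_a)
        alpha_out[mask] = best_a
    return alpha_out


def call_events(assignment: GenotypeAssignment, tree: CellPhylogeny) -> list[EventCall]:
    """Classify every genotype change on every branch as a mutation event.

    An event name occurring at the same site on more than one branch is
    flagged as parallel evolution.  A genotype change outside the 28
    recognized transitions signals a decoding bug and raises.
    """
    geno = assignment.node_genotypes
    I = geno.shape[0]
    raw: list[EventCall] = []
    for v in range(tree.root):
        p = tree.parent[v]
        diff = np.where(geno[:, v] != geno[:, p])[0]
        for i in diff:
            ev = classify_transition(GENOTYPE_LABELS[geno[i, p]], GENOTYPE_LABELS[geno[i, v]])
            if ev is None:
                raise RuntimeError(
                    f"impossible transition {GENOTYPE_LABELS[geno[i, p]]} -> "
                    f"{GENOTYPE_LABELS[geno[i, v]]} decoded at site index {i}"
                )
            raw.append(EventCall(int(i), int(p), int(v), ev.name))
    counts: dict[tuple[int, str], int] = {}
    for e in raw:
        counts[(e.site, e.event)] = counts.get((e.site, e.event), 0) + 1
    return [
        EventCall(e.site, e.parent_node, e.child_node, e.event,
                  parallel=counts[(e.site, e.event)] > 1)
        for e in raw
    ]


def call_dropouts(
    assignment: GenotypeAssignment, mode: str = "ado", include_ldo: Optional[bool] = None
) -> dict[str, np.ndarray]:
    """Per-(site, cell) dropout calls from the decoded (g, alpha).

    ADO: one allele fewer sequenced than the genotype carries.
    LDO (LDO mode only): both alleles of a diploid genotype lost.
    """
    if include_ldo is None:
        include_ldo = mode == "ldo"
    if include_ldo and mode != "ldo":
        raise ValueError("LDO calls are only available in LDO mode")
    ell = ALLELE_COUNTS[assignment.leaf_genotypes]
    alpha = assignment.leaf_alpha
    out = {"ado": (ell >= 1) & (alpha == ell - 1)}
    if include_ldo:
        out["ldo"] = (ell == 2) & (alpha == 0)
    return out


def write_variant_table(assignment: GenotypeAssignment, path, mode: str = "ado") -> pd.DataFrame:
    """Write one record per (site, cell): genotype, alpha, dropout flags.

    Genotype labels are serialized exactly as the seven canonical
    strings.  Returns the table that was written.
    """
    drops = call_dropouts(assignment, mode)
    I, J = assignment.leaf_alpha.shape
    rows = {
        "chrom": np.repeat(assignment.chrom, J),
        "pos": np.repeat(assignment.pos, J),
        "ref": np.repeat(assignment.ref, J),
        "cell": np.tile(assignment.cell_names, I),
        "genotype": np.array(GENOTYPE_LABELS, dtype=object)[assignment.leaf_genotypes.ravel()],
        "alpha": assignment.leaf_alpha.ravel(),
        "ado": drops["ado"].ravel().astype(int),
        "ldo": drops.get("ldo", np.zeros((I, J), dtype=bool)).ravel().astype(int),
    }
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cell": str, "genotype": str})
    bad = set(df["genotype"]) - set(GENOTYPE_LABELS)
    if bad:
        raise ValueError(f"unknown genotype labels in {path}: {sorted(bad)}")
    return df


def write_event_table(events: list[EventCall], assignment: GenotypeAssignment, path) -> pd.DataFrame:
    """Per-branch mutation events as TSV."""
    df = pd.DataFrame(
        {
            "chrom": [assignment.chrom[e.site] for e in events],
            "pos": [assignment.pos[e.site] for e in events],
            "parent_node": [e.parent_node for e in events],
            "child_node": [e.child_node for e in events],
            "event": [e.event for e in events],
            "parallel": [int(e.parallel) for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
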