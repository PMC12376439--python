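"""Benchmark metrics: per-class confusion summaries and tree distances.

Genotype calls are scored one-vs-rest over all (cell, site) pairs for
each target class (each deletion genotype, single mutants, double
mutants, dropout events, and "any mutation", which collapses every
non-wildtype genotype).  Following standard practice for rare classes,
a replicate's summary is flagged invalid when the ground-truth class
proportion falls below 0.1%, and precision/F1 are reported as
unavailable (not zero) when no positive calls were made.

Tree accuracy uses the normalized Robinson-Foulds distance (topology
only; bipartition mismatches scaled by the maximum 2(J-3) for unrooted
binary trees) and the Kuhner-Felsenstein branch-score distance
(square root of summed squared branch-length differences over the
union of bipartitions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

from .trees import CellPhylogeny

__all__ = [
    "ConfusionSummary",
    "TARGET_CLASSES",
    "genotype_metrics",
    "dropout_metrics",
    "normalized_rf",
    "branch_score",
    "run_benchmark",
    "summarize_benchmark",
]

#: class name -> predicate over genotype-index matrices
TARGET_CLASSES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "0/1": lambda g: g == 1,
    "double_mutant": lambda g: (g == 2) | (g == 3),  # 1/1 or 1/1'
    "0/-": lambda g: g == 4,
    "1/-": lambda g: g == 5,
    "-": lambda g: g == 6,
    "any_mutation": lambda g: g != 0,
}

MIN_TRUTH_PROPORTION = 0.001  # class rarer than 0.1% -> replicate excluded


@dataclass(frozen=True)
class ConfusionSummary:
    """One-vs-rest confusion counts over (cell, site) pairs."""

    tp: int
    fp: int
    fn: int
    tn: int
    valid: bool = True

    @property
    def precision(self) -> Optional[float]:
        den = self.tp + self.fp
        return self.tp / den if den else None

    @property
    def recall(self) -> Optional[float]:
        den = self.tp + self.fn
        return self.tp / den if den else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def fpr(self) -> Optional[float]:
        den = self.fp + self.tn
        return self.fp / den if den else None


def _confusion(truth_mask: np.ndarray, call_mask: np.ndarray) -> ConfusionSummary:
    if truth_mask.shape != call_mask.shape:
        raise ValueError("truth and call matrices must have the same shape")
    tp = int(np.sum(truth_mask & call_mask))
    fp = int(np.sum(~truth_mask & call_mask))
    fn = int(np.sum(truth_mask & ~call_mask))
    tn = int(np.sum(~truth_mask & ~call_mask))
    valid = truth_mask.mean() >= MIN_TRUTH_PROPORTION if truth_mask.size else False
    return ConfusionSummary(tp, fp, fn, tn, valid)


def genotype_metrics(truth: np.ndarray, calls: np.ndarray, target: str) -> ConfusionSummary:
    """One-vs-rest confusion for a genotype class.

    ``truth`` and ``calls`` are (I, J) matrices of genotype indices in
    canonical order; ``target`` one of :data:`TARGET_CLASSES`.
    """
    try:
        pred = TARGET_CLASSES[target]
    except KeyError:
        raise ValueError(f"unknown target class {target!r}; choose from {sorted(TARGET_CLASSES)}")
    return _confusion(pred(np.asarray(truth)), pred(np.asarray(calls)))


def dropout_metrics(truth_mask: np.ndarray, call_mask: np.ndarray) -> ConfusionSummary:
    """Confusion summary for boolean dropout-event matrices (ADO or LDO)."""
    return _confusion(np.asarray(truth_mask, bool), np.asarray(call_mask, bool))


def _as_unrooted_pair(a: CellPhylogeny, b: CellPhylogeny) -> tuple[dendropy.Tree, dendropy.Tree]:
    if sorted(a.leaf_names) != sorted(b.leaf_names):
        raise ValueError("trees must share the same leaf label set")
    tns = dendropy.TaxonNamespace(a.leaf_names)
    out = []
    for t in (a, b):
        dt = t.to_dendropy(tns)
        dt.is_rooted = False
        dt.suppress_unifurcations()
        dt.encode_bipartitions()
        out.append(dt)
    return out[0], out[1]


def normalized_rf(a: CellPhylogeny, b: CellPhylogeny) -> float:
    """Robinson-Foulds bipartition distance scaled to [0, 1].

    Trees are compared unrooted (the trunk and root placement carry no
    topological information about the cells); the normalizer is the
    maximum attainable value 2(J-3) for binary trees.
    """
    da, db = _as_unrooted_pair(a, b)
    rf = treecompare.symmetric_difference(da, db)
    denom = 2 * (a.n_leaves - 3)
    return float(rf) / denom if denom > 0 else float(rf > 0)


def branch_score(a: CellPhylogeny, b: CellPhylogeny) -> float:
    """Kuhner-Felsenstein branch-score distance (unrooted comparison).

    Square root of the summed squared branch-length differences over
    the union of bipartitions; a split absent from one tree contributes
    its full length in the other.
    """
    da, db = _as_unrooted_pair(a, b)
    return float(treecompare.euclidean_distance(da, db))


# ---------------------------------------------------------------------------
# end-to-end benchmark


def _replicate_metrics(cfg, mcmc_template, seed: int) -> list[dict]:
    from .inference import maximum_clade_credibility_tree, run_mcmc
    from .calling import call_dropouts, ml_genotypes
    from .genotypes import ALLELE_COUNTS
    from .readcounts import estimate_size_factors
    from .simulate import simulate_dataset

    rng = np.random.default_rng(seed)
    data, truth = simulate_dataset(replace(cfg, seed=seed))
    mcmc = replace(mcmc_template, seed=int(rng.integers(2**31 - 1)),
                   dropout_mode=cfg.dropout_mode)
    res = run_mcmc(data, mcmc)
    mcc, _ = maximum_clade_credibility_tree(res.posterior_trees())
    params = res.posterior_median_params()
    params = replace(
        params, read=replace(params.read, size_factors=estimate_size_factors(data.coverage))
    )
    assignment = ml_genotypes(data, mcc, params)
    rows: list[dict] = []

    def add(metric: str, value, valid=True) -> None:
        rows.append({"metric": metric, "value": value if valid else np.nan, "valid": valid})

    truth_geno = truth.leaf_genotypes
    calls = assignment.leaf_genotypes
    for name in TARGET_CLASSES:
        cs = genotype_metrics(truth_geno, calls, name)
        for stat in ("f1", "precision", "recall", "fpr"):
            val = getattr(cs, stat)
            add(f"{stat}[{name}]", np.nan if val is None else val,
                valid=cs.valid and val is not None)
    ell = ALLELE_COUNTS[truth_geno]
    ado_truth = (ell >= 1) & (truth.alpha == ell - 1)
    drops = call_dropouts(assignment, cfg.dropout_mode)
    cs = dropout_metrics(ado_truth, drops["ado"])
    add("f1[ado]", np.nan if cs.f1 is None else cs.f1, cs.valid and cs.f1 is not None)
    if cfg.dropout_mode == "ldo":
        ldo_truth = (ell == 2) & (truth.alpha == 0)
        cs = dropout_metrics(ldo_truth, drops["ldo"])
        add("f1[ldo]", np.nan if cs.f1 is None else cs.f1, cs.valid and cs.f1 is not None)
    add("rf", normalized_rf(truth.tree, mcc))
    add("bs", branch_score(truth.tree, mcc))
    add("n_candidate_sites", data.n_sites)
    return rows


def run_benchmark(
    grid: Sequence, n_replicates: int, mcmc_template, base_seed: int = 0
) -> pd.DataFrame:
    """Simulate -> infer -> call -> score over a grid of conditions.

    Returns a long-format table (condition, replicate, metric, value,
    valid); per-replicate failures are recorded as ``error`` rows, not
    raised.
    """
    records = []
    for ci, cfg in enumerate(grid):
        cond = (
            f"mu={cfg.mutation_rate:g},d={cfg.deletion_rate:g},"
            f"cov={cfg.coverage_quality},mode={cfg.dropout_mode}"
        )
        for rep in range(n_replicates):
            seed = (base_seed + 7919 * ci + rep) % (2**31 - 1)
            try:
                rows = _replicate_metrics(cfg, mcmc_template, seed)
            except Exception as exc:  # noqa: BLE001 - per-replicate isolation
                rows = [{"metric": "error", "value": np.nan, "valid": False,
                         "note": repr(exc)}]
            for r in rows:
                r.update({"condition": cond, "replicate": rep})
                records.append(r)
    return pd.DataFrame(records)


def summarize_benchmark(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition medians over the valid replicates only."""
    ok = results[results["valid"] & results["value"].notna()]
    return (
        ok.groupby(["condition", "metric"])["value"]
        .median()
        .rename("median")
        .reset_index()
    )
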