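"""Genotype state space, rate matrix and mutation-event classification.

The model tracks, for every candidate variant site in every cell, one of
seven genotype states::

    0/0   wildtype (two reference alleles)
    0/1   heterozygous single mutant
    1/1   homozygous double mutant (both alleles carry the same alternative)
    1/1'  heterozygous double mutant (two different alternative nucleotides)
    0/-   single deletion retaining the reference allele
    1/-   single deletion retaining a mutated allele
    -     double (homozygous) deletion

Somatic evolution along the cell phylogeny is a continuous-time Markov
chain on these states.  Rates are expressed relative to the somatic
mutation rate (set to 1): a mutated allele reverts to the reference at
relative rate 1/3 (one of three possible target nucleotides), and each
allele is deleted at relative rate ``d``.  The chain is non-reversible
and reducible: the four diploid states and the two haploid states form
transient communicating classes and the fully deleted state ``-`` is
absorbing, so alleles are never regained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Genotype",
    "GENOTYPES",
    "GENOTYPE_LABELS",
    "GENOTYPE_INDEX",
    "ALLELE_COUNTS",
    "N_STATES",
    "MutationEvent",
    "TRANSITION_EVENTS",
    "EVENT_NAMES",
    "build_rate_matrix",
    "transition_probabilities",
    "classify_transition",
]


@dataclass(frozen=True)
class Genotype:
    """One of the seven genotype states.

    Attributes
    ----------
    label : str
        Canonical serialized form, e.g. ``"1/1'"`` or ``"0/-"``.
    allele_count : int
        Number of alleles present (2 diploid, 1 haploid, 0 deleted).
    index : int
        Position in the canonical state ordering (0..6).
    """

    label: str
    allele_count: int
    index: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: Canonical ordering used by every matrix and vector in the package.
GENOTYPES: tuple[Genotype, ...] = (
    Genotype("0/0", 2, 0),
    Genotype("0/1", 2, 1),
    Genotype("1/1", 2, 2),
    Genotype("1/1'", 2, 3),
    Genotype("0/-", 1, 4),
    Genotype("1/-", 1, 5),
    Genotype("-", 0, 6),
)

GENOTYPE_LABELS: tuple[str, ...] = tuple(g.label for g in GENOTYPES)
GENOTYPE_INDEX: dict[str, int] = {g.label: g.index for g in GENOTYPES}
ALLELE_COUNTS: np.ndarray = np.array([g.allele_count for g in GENOTYPES])
N_STATES: int = len(GENOTYPES)

WILDTYPE: Genotype = GENOTYPES[0]

# Instantaneous rates, transcribed as a literal table.  Each entry maps
# (parent label, child label) -> (constant part, coefficient of d); the
# rate is const + coeff * d.  Missing ordered pairs (and the absorbing
# state '-') have rate zero; diagonals are the negated row sums.
_RATE_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("0/0", "0/1"): (2.0, 0.0),
    ("0/0", "0/-"): (0.0, 2.0),
    ("0/1", "0/0"): (1.0 / 3.0, 0.0),
    ("0/1", "1/1"): (1.0 / 3.0, 0.0),
    ("0/1", "1/1'"): (2.0 / 3.0, 0.0),
    ("0/1", "0/-"): (0.0, 1.0),
    ("0/1", "1/-"): (0.0, 1.0),
    ("1/1", "0/1"): (2.0 / 3.0, 0.0),
    ("1/1", "1/1'"): (4.0 / 3.0, 0.0),
    ("1/1", "1/-"): (0.0, 2.0),
    ("1/1'", "0/1"): (2.0 / 3.0, 0.0),
    ("1/1'", "1/1"): (2.0 / 3.0, 0.0),
    ("1/1'", "1/-"): (0.0, 2.0),
    ("0/-", "1/-"): (1.0, 0.0),
    ("0/-", "-"): (0.0, 1.0),
    ("1/-", "0/-"): (1.0 / 3.0, 0.0),
    ("1/-", "-"): (0.0, 1.0),
}


def build_rate_matrix(d: float) -> np.ndarray:
    """Instantaneous 7x7 rate matrix Q for relative deletion rate ``d``.

    Rates are relative to the somatic mutation rate (1 per allele);
    back mutations occur at relative rate 1/3 per mutated allele and
    deletions at relative rate ``d`` per allele.  Every row sums to
    zero and the row of the absorbing state ``-`` is identically zero.

    Parameters
    ----------
    d : float
        Relative deletion rate, ``d >= 0`` (dimensionless).
    """
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"relative deletion rate must be non-negative, got {d}")
    Q = np.zeros((N_STATES, N_STATES))
    for (parent, child), (const, coeff) in _RATE_TABLE.items():
        Q[GENOTYPE_INDEX[parent], GENOTYPE_INDEX[child]] = const + coeff * d
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


#: entries (parent, child) where the child would have more alleles than the parent
_REGAIN_MASK: np.ndarray = ALLELE_COUNTS[None, :] > ALLELE_COUNTS[:, None]


def transition_probabilities(Q: np.ndarray, beta: float | np.ndarray) -> np.ndarray:
    """Finite-time transition probability matrix R(beta) = exp(Q beta).

    ``beta`` is a branch length in expected somatic mutations per site;
    it may be a scalar or an array, in which case a stack of matrices of
    shape ``beta.shape + (7, 7)`` is returned.  Uses scaling-and-squaring
    (Q is non-symmetric and need not be diagonalizable).
    """
    beta_arr = np.asarray(beta, dtype=float)
    if np.any(beta_arr < 0) or not np.all(np.isfinite(beta_arr)):
        raise ValueError("branch lengths must be finite and non-negative")
    R = expm(Q * beta_arr[..., None, None])
    # expm of a generator is row-stochastic up to roundoff; clip tiny negatives
    # and zero the structurally impossible entries (alleles are never regained)
    np.clip(R, 0.0, None, out=R)
    R[..., _REGAIN_MASK] = 0.0
    return R


@dataclass(frozen=True)
class MutationEvent:
    """A classified genotype change on a branch (parent -> child)."""

    name: str
    parent: Genotype
    child: Genotype


# The 28 identifiable genotype transitions and their event classes.
_EVENT_TABLE: dict[tuple[str, str], str] = {
    ("0/0", "0/1"): "single point mutation",
    ("0/0", "1/1"): "coincident homozygous double point mutation",
    ("0/0", "1/1'"): "coincident heterozygous double point mutation",
    ("0/1", "0/0"): "single back mutation",
    ("1/1", "0/1"): "single back mutation",
    ("1/1'", "0/1"): "single back mutation",
    ("1/1", "0/0"): "coincident double back mutation",
    ("1/1'", "0/0"): "coincident double back mutation",
    ("0/1", "1/1"): "homozygous single point mutation addition",
    ("0/1", "1/1'"): "heterozygous single point mutation addition",
    ("1/1'", "1/1"): "homozygous substitute single point mutation",
    ("1/1", "1/1'"): "heterozygous substitute single point mutation",
    ("0/0", "0/-"): "single deletion (not LOH)",
    ("1/1", "1/-"): "single deletion (not LOH)",
    ("0/1", "0/-"): "single deletion (LOH)",
    ("0/1", "1/-"): "single deletion (LOH)",
    ("1/1'", "1/-"): "single deletion (LOH)",
    ("0/0", "1/-"): "coincident deletion and point mutation",
    ("1/1", "0/-"): "coincident deletion and back mutation",
    ("1/1'", "0/-"): "coincident deletion and back mutation",
    ("0/-", "1/-"): "single deletion point mutation addition",
    ("1/-", "0/-"): "single deletion back mutation addition",
    ("0/-", "-"): "single deletion addition",
    ("1/-", "-"): "single deletion addition",
    ("0/0", "-"): "coincident double deletions",
    ("0/1", "-"): "coincident double deletions",
    ("1/1", "-"): "coincident double deletions",
    ("1/1'", "-"): "coincident double deletions",
}

TRANSITION_EVENTS = dict(_EVENT_TABLE)
EVENT_NAMES: tuple[str, ...] = tuple(sorted(set(_EVENT_TABLE.values())))


def classify_transition(parent: Genotype | str, child: Genotype | str) -> Optional[MutationEvent]:
    """Classify the genotype change ``parent -> child`` as a mutation event.

    Returns ``None`` for identity transitions and for pairs that cannot
    occur on a branch (any transition regaining alleles).
    """
    p = parent if isinstance(parent, Genotype) else GENOTYPES[GENOTYPE_INDEX[parent]]
    c = child if isinstance(child, Genotype) else GENOTYPES[GENOTYPE_INDEX[child]]
    name = _EVENT_TABLE.get((p.label, c.label))
    if name is None:
        return None
    return MutationEvent(name=name, parent=p, child=c)
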