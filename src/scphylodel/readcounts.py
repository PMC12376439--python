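"""Model of raw single-cell read counts.

For cell ``j`` at candidate site ``i`` the observed data are the total
sequencing coverage ``c_ij`` and the read counts of the three
alternative nucleotides ``m_ij1 >= m_ij2 >= m_ij3`` (sorted descending).
The likelihood factorizes into a coverage term and a nucleotide term:

* coverage ``c`` given the number of sequenced alleles ``alpha`` is
  negative binomial with mean ``alpha * t * s_j + eps`` and variance
  ``mean + alpha^2 * nu * s_j^2`` (``s_j`` a per-cell size factor,
  ``eps`` a small stabilizer for the zero-allele case);
* the split of ``c`` reads among the three alternative nucleotides and
  the reference is Dirichlet-Multinomial, with expected nucleotide
  frequencies determined by the *observed* genotype and the effective
  sequencing error rate ``f``, and overdispersion ``w1`` (one nucleotide
  expected) or ``w2`` (two nucleotides expected).

Whole-genome-amplification dropout can hide alleles, so the observed
genotype ``g'`` may differ from the true genotype ``g``.  In ADO mode a
single allele may drop out (probability ``theta_ado`` per retained
allele set); in LDO mode both alleles of a diploid site may additionally
drop together (probability ``theta_ldo``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom, poisson

from .genotypes import ALLELE_COUNTS, GENOTYPE_INDEX, GENOTYPE_LABELS, N_STATES, Genotype

__all__ = [
    "ReadCountDataset",
    "ReadCountParams",
    "estimate_size_factors",
    "coverage_log_pmf",
    "observed_genotype_distribution",
    "allele_count_distribution",
    "nucleotide_log_pmf",
    "leaf_likelihoods",
    "leaf_log_likelihood_tensor",
]

DROPOUT_MODES = ("ado", "ldo")


@dataclass
class ReadCountDataset:
    """Coverage and alternative-nucleotide counts for I sites x J cells."""

    coverage: np.ndarray  # (I, J) ints
    alt_counts: np.ndarray  # (I, J, 3) ints, sorted descending along k
    cell_names: list[str] = field(default_factory=list)
    chrom: Optional[np.ndarray] = None
    pos: Optional[np.ndarray] = None  # 1-based
    ref: Optional[np.ndarray] = None
    background_site_count: int = 0

    def __post_init__(self):
        self.coverage = np.asarray(self.coverage)
        self.alt_counts = np.asarray(self.alt_counts)
        I, J = self.coverage.shape
        if self.alt_counts.shape != (I, J, 3):
            raise ValueError("alt_counts must have shape (I, J, 3)")
        if np.any(self.coverage < 0) or np.any(self.alt_counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.alt_counts.sum(axis=2) > self.coverage):
            raise ValueError("alternative counts exceed coverage")
        if np.any(np.diff(self.alt_counts, axis=2) > 0):
            raise ValueError("alternative counts must be sorted descending")
        if self.background_site_count < 0:
            raise ValueError("background_site_count must be >= 0")
        if not self.cell_names:
            self.cell_names = [f"cell{j + 1}" for j in range(J)]
        if self.chrom is None:
            self.chrom = np.array(["1"] * I, dtype=object)
        if self.pos is None:
            self.pos = np.arange(1, I + 1, dtype=np.int64)
        if self.ref is None:
            self.ref = np.array(["N"] * I, dtype=object)

    @property
    def n_sites(self) -> int:
        return self.coverage.shape[0]

    @property
    def n_cells(self) -> int:
        return self.coverage.shape[1]

    # -- TSV dialect ----------------------------------------------------
    # One record per site: chrom, pos (1-based), ref, then per cell a
    # field "c,m1,m2,m3".  The background-site count is carried in a
    # "#background_sites=" header comment.
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#background_sites={self.background_site_count}\n")
            fh.write("\t".join(["CHROM", "POS", "REF", *self.cell_names]) + "\n")
            for i in range(self.n_sites):
                cells = [
                    f"{self.coverage[i, j]},"
                    + ",".join(str(x) for x in self.alt_counts[i, j])
                    for j in range(self.n_cells)
                ]
                fh.write(
                    "\t".join([str(self.chrom[i]), str(self.pos[i]), str(self.ref[i]), *cells])
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ReadCountDataset":
        background = 0
        with open(path) as fh:
            lines = fh.read().splitlines()
        body = []
        header = None
        for ln in lines:
            if ln.startswith("#background_sites="):
                background = int(ln.split("=", 1)[1])
            elif ln.startswith("#") or not ln.strip():
                continue
            elif header is None:
                header = ln.split("\t")
            else:
                body.append(ln.split("\t"))
        if header is None:
            raise ValueError(f"no header line in {path}")
        cell_names = header[3:]
        I, J = len(body), len(cell_names)
        coverage = np.zeros((I, J), dtype=np.int64)
        alt = np.zeros((I, J, 3), dtype=np.int64)
        chrom = np.empty(I, dtype=object)
        pos = np.zeros(I, dtype=np.int64)
        ref = np.empty(I, dtype=object)
        for i, row in enumerate(body):
            chrom[i], pos[i], ref[i] = row[0], int(row[1]), row[2]
            for j in range(J):
                c, m1, m2, m3 = (int(x) for x in row[3 + j].split(","))
                coverage[i, j] = c
                alt[i, j] = (m1, m2, m3)
        return cls(coverage, alt, cell_names, chrom, pos, ref, background)


@dataclass
class ReadCountParams:
    """Continuous parameters of the read-count model."""

    t: float = 10.0  # mean allelic coverage
    nu: float = 2.0  # variance of allelic coverage
    f: float = 1e-3  # effective sequencing error rate
    w1: float = 100.0  # overdispersion, single expected nucleotide
    w2: float = 100.0  # overdispersion, two expected nucleotides
    eps: float = 1e-6  # coverage stabilizer for alpha = 0
    theta_ado: float = 0.1  # single-allele dropout probability
    theta_ldo: float = 0.0  # locus dropout probability (LDO mode)
    size_factors: Optional[np.ndarray] = None  # (J,)

    def __post_init__(self):
        if not (0 < self.f < 1):
            raise ValueError("f must lie in (0, 1)")
        if self.t <= 0 or self.nu < 0 or self.w1 <= 0 or self.w2 <= 0 or self.eps <= 0:
            raise ValueError("t, w1, w2, eps must be positive and nu non-negative")
        if not (0 <= self.theta_ado < 1) or not (0 <= self.theta_ldo < 1):
            raise ValueError("dropout probabilities must lie in [0, 1)")
        if self.theta_ado + self.theta_ldo >= 1:
            raise ValueError("theta_ado + theta_ldo must be < 1")

    def with_(self, **kw) -> "ReadCountParams":
        return replace(self, **kw)


def estimate_size_factors(coverage: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factor per cell.

    For cell j, the median over sites with nonzero coverage of
    ``c_ij / geomean_{j': c_ij' != 0}(c_ij')``.
    """
    cov = np.asarray(coverage, dtype=float)
    I, J = cov.shape
    with np.errstate(divide="ignore"):
        logc = np.where(cov > 0, np.log(np.where(cov > 0, cov, 1.0)), 0.0)
    n_nonzero = (cov > 0).sum(axis=1)
    # per-site geometric mean over the cells with nonzero coverage
    geo = np.exp(logc.sum(axis=1) / np.maximum(n_nonzero, 1))
    s = np.empty(J)
    for j in range(J):
        mask = cov[:, j] > 0
        if not mask.any():
            raise ValueError(f"cell {j} has zero coverage at every site")
        s[j] = np.median(cov[mask, j] / geo[mask])
    return s


def coverage_log_pmf(
    c, alpha: int, params: ReadCountParams, size_factor: float = 1.0
) -> np.ndarray:
    """Log P(coverage = c | alpha sequenced alleles) for one cell.

    Negative binomial reparameterized by mean ``mu = alpha*t*s + eps``
    and variance ``mu + alpha^2*nu*s^2``; degenerates to the Poisson
    limit when the variance inflation vanishes (``alpha*nu == 0``).
    """
    if alpha not in (0, 1, 2):
        raise ValueError("alpha must be 0, 1 or 2")
    s = float(size_factor)
    mu = alpha * params.t * s + params.eps
    var = mu + alpha**2 * params.nu * s**2
    c = np.asarray(c)
    if var <= mu:  # Poisson limit of the negative binomial
        return poisson.logpmf(c, mu)
    p = mu / var
    r = mu**2 / (var - mu)
    return nbinom.logpmf(c, r, p)


# -- dropout tables ----------------------------------------------------
# P(observed genotype g' | true genotype g, alpha sequenced alleles),
# literal transcriptions; unlisted combinations have probability 0.
_OBS_TABLE_ADO: dict[tuple[str, int], dict[str, float]] = {
    ("0/0", 2): {"0/0": 1.0},
    ("0/0", 1): {"0/-": 1.0},
    ("0/1", 2): {"0/1": 1.0},
    ("0/1", 1): {"0/-": 0.5, "1/-": 0.5},
    ("1/1", 2): {"1/1": 1.0},
    ("1/1", 1): {"1/-": 1.0},
    ("1/1'", 2): {"1/1'": 1.0},
    ("1/1'", 1): {"1/-": 1.0},
    ("0/-", 1): {"0/-": 1.0},
    ("0/-", 0): {"-": 1.0},
    ("1/-", 1): {"1/-": 1.0},
    ("1/-", 0): {"-": 1.0},
    ("-", 0): {"-": 1.0},
}

_OBS_TABLE_LDO: dict[tuple[str, int], dict[str, float]] = {
    **_OBS_TABLE_ADO,
    ("0/0", 0): {"-": 1.0},
    ("0/1", 0): {"-": 1.0},
    ("1/1", 0): {"-": 1.0},
    ("1/1'", 0): {"-": 1.0},
}


def _check_mode(mode: str) -> str:
    mode = mode.lower()
    if mode not in DROPOUT_MODES:
        raise ValueError(f"dropout mode must be one of {DROPOUT_MODES}, got {mode!r}")
    return mode


def observed_genotype_distribution(g: Genotype | str, alpha: int, mode: str = "ado") -> dict[str, float]:
    """P(g' | g, alpha) as a dict over observed-genotype labels."""
    mode = _check_mode(mode)
    label = g.label if isinstance(g, Genotype) else g
    ell = ALLELE_COUNTS[GENOTYPE_INDEX[label]]
    if alpha > ell:
        raise ValueError(f"alpha={alpha} exceeds allele count {ell} of {label}")
    table = _OBS_TABLE_ADO if mode == "ado" else _OBS_TABLE_LDO
    try:
        return dict(table[(label, alpha)])
    except KeyError:
        raise ValueError(f"({label}, alpha={alpha}) unreachable in {mode.upper()} mode") from None


def allele_count_distribution(
    g: Genotype | str, mode: str = "ado", theta_ado: float = 0.0, theta_ldo: float = 0.0
) -> dict[int, float]:
    """P(alpha | g): distribution of the number of sequenced alleles.

    An ``l``-allele genotype retains all ``l`` alleles with probability
    ``1 - theta_ado`` (minus ``theta_ldo`` for diploids in LDO mode) and
    loses one with probability ``theta_ado``; in LDO mode a diploid
    additionally loses both with probability ``theta_ldo``.
    """
    mode = _check_mode(mode)
    if theta_ado + theta_ldo >= 1 or theta_ado < 0 or theta_ldo < 0:
        raise ValueError("require theta_ado, theta_ldo >= 0 and theta_ado + theta_ldo < 1")
    label = g.label if isinstance(g, Genotype) else g
    ell = int(ALLELE_COUNTS[GENOTYPE_INDEX[label]])
    if ell == 0:
        return {0: 1.0}
    if ell == 1:
        return {1: 1.0 - theta_ado, 0: theta_ado} if theta_ado > 0 else {1: 1.0}
    if mode == "ldo" and theta_ldo > 0:
        dist = {2: 1.0 - theta_ado - theta_ldo, 1: theta_ado, 0: theta_ldo}
    else:
        dist = {2: 1.0 - theta_ado, 1: theta_ado}
    return {a: p for a, p in dist.items() if p > 0}


# Expected-frequency vector index per observed genotype (f1..f4) and
# which overdispersion parameter applies.
_FREQ_CLASS = {"0/0": 1, "0/-": 1, "0/1": 2, "1/1": 3, "1/-": 3, "1/1'": 4}
_W_CLASS = {"0/0": 1, "0/-": 1, "1/1": 1, "1/-": 1, "0/1": 2, "1/1'": 2}


def _freq_vector(cls: int, f: float) -> np.ndarray:
    """Expected frequencies (alt1, alt2, alt3, ref) for frequency class 1..4."""
    e = f / 3.0
    if cls == 1:  # only the reference nucleotide expected
        return np.array([e, e, e, 1.0 - f])
    if cls == 2:  # reference + one alternative
        return np.array([0.5 - e, e, e, 0.5 - e])
    if cls == 3:  # one alternative only
        return np.array([1.0 - f, e, e, e])
    if cls == 4:  # two different alternatives
        return np.array([0.5 - e, 0.5 - e, e, e])
    raise ValueError(cls)


def _dirichlet_multinomial_logpmf(m: np.ndarray, c: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Log Dirichlet-Multinomial pmf over 4 categories.

    ``m``: (..., 3) alternative counts; the reference count is
    ``c - m.sum()``; ``a``: (4,) concentration parameters.
    """
    m = np.asarray(m)
    c = np.asarray(c)
    mref = c - m.sum(axis=-1)
    counts = np.concatenate([m, mref[..., None]], axis=-1)
    a0 = a.sum()
    return (
        gammaln(a0)
        + gammaln(c + 1)
        - gammaln(c + a0)
        + (gammaln(counts + a) - gammaln(a) - gammaln(counts + 1)).sum(axis=-1)
    )


def nucleotide_log_pmf(
    m, c, g_obs: Genotype | str, f: float, w1: float, w2: float
) -> np.ndarray:
    """Log P(m | c, g') for the alternative-nucleotide counts.

    ``g' = '-'`` carries no nucleotide information and returns log 1 = 0.
    """
    label = g_obs.label if isinstance(g_obs, Genotype) else g_obs
    m = np.asarray(m)
    c = np.asarray(c)
    if np.any(m.sum(axis=-1) > c):
        raise ValueError("alternative counts exceed coverage")
    if label == "-":
        return np.zeros(np.broadcast(m[..., 0], c).shape)
    w = w1 if _W_CLASS[label] == 1 else w2
    a = w * _freq_vector(_FREQ_CLASS[label], f)
    return _dirichlet_multinomial_logpmf(m, c, a)


def _compound_terms(mode: str, params: ReadCountParams) -> list[list[tuple[float, int, str]]]:
    """For each true genotype: list of (weight, alpha, g') mixture terms."""
    out = []
    for g in GENOTYPE_LABELS:
        terms = []
        for alpha, pa in allele_count_distribution(
            g, mode, params.theta_ado, params.theta_ldo if mode == "ldo" else 0.0
        ).items():
            for g_obs, pg in observed_genotype_distribution(g, alpha, mode).items():
                terms.append((pa * pg, alpha, g_obs))
        out.append(terms)
    return out


def leaf_log_likelihood_tensor(
    data: ReadCountDataset, params: ReadCountParams, mode: str = "ado"
) -> np.ndarray:
    """Log P(D_ij | g) for every site i, cell j and true genotype g.

    Returns an (I, J, 7) array; this is the quantity the pruning engine
    consumes at the leaves.  Marginalizes the number of sequenced
    alleles and the observed genotype:
    ``P(D|g) = sum_alpha P(alpha|g) P(c|alpha) sum_g' P(g'|g,alpha) P(m|c,g')``.
    """
    mode = _check_mode(mode)
    I, J = data.n_sites, data.n_cells
    s = params.size_factors
    if s is None:
        s = np.ones(J)
    cov = data.coverage
    alt = data.alt_counts
    cov_ll = np.empty((3, I, J))
    for alpha in range(3):
        for j in range(J):
            cov_ll[alpha, :, j] = coverage_log_pmf(cov[:, j], alpha, params, s[j])
    nuc_ll: dict[str, np.ndarray] = {"-": np.zeros((I, J))}
    for label in ("0/0", "0/1", "1/1", "1/1'"):
        w = params.w1 if _W_CLASS[label] == 1 else params.w2
        a = w * _freq_vector(_FREQ_CLASS[label], params.f)
        nuc_ll[label] = _dirichlet_multinomial_logpmf(alt, cov, a)
    nuc_ll["0/-"] = nuc_ll["0/0"]
    nuc_ll["1/-"] = nuc_ll["1/1"]
    out = np.empty((I, J, N_STATES))
    for gi, terms in enumerate(_compound_terms(mode, params)):
        stack = np.stack(
            [np.log(wt) + cov_ll[alpha] + nuc_ll[g_obs] for wt, alpha, g_obs in terms]
        )
        out[:, :, gi] = logsumexp(stack, axis=0)
    return out


def leaf_likelihoods(
    cell: int, site: int, data: ReadCountDataset, params: ReadCountParams, mode: str = "ado"
) -> np.ndarray:
    """7-vector P(D_ij | g) for one cell at one site (linear scale)."""
    sub = ReadCountDataset(
        data.coverage[[site]][:, [cell]],
        data.alt_counts[[site]][:, [cell]],
        cell_names=[data.cell_names[cell]],
    )
    p = params
    if params.size_factors is not None:
        p = params.with_(size_factors=params.size_factors[[cell]])
    return np.exp(leaf_log_likelihood_tensor(sub, p, mode)[0, 0])
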