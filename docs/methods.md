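# Methods

`scphylodel` jointly infers a cell phylogeny and per-cell genotypes from
raw single-cell DNA-seq read counts, explicitly modeling somatic
deletions alongside point mutations, and calls mutation events and
amplification dropouts from the fitted model. This note documents the
model, the package's own design choices where the design was open, the
synthetic-data generator, and the numerical conventions.

## Genotype state space and substitution model

Each candidate variant site in each cell carries one of seven genotype
states: `0/0` (wildtype), `0/1` (heterozygous single mutant), `1/1`
(homozygous double mutant), `1/1'` (heterozygous double mutant with two
distinct alternative nucleotides), `0/-` and `1/-` (single deletions
retaining the reference or a mutated allele), and `-` (double
deletion). Genotypes evolve along a rooted binary cell phylogeny whose
root is a healthy diploid cell with a single child — the branch to the
most recent common ancestor of the sampled tumor cells is the *trunk*.
Branch lengths are expected somatic mutations per site; no molecular
clock is imposed.

The continuous-time rate matrix uses per-allele rates relative to the
somatic mutation rate (set to 1): a reference allele mutates at rate 1,
a mutated allele mutates at rate 1 (reverting to the reference with
probability 1/3 or hitting another alternative nucleotide otherwise,
the three possible targets being equally likely), and every allele is
deleted at rate `d`. Rows sum to zero; the four diploid states and the
two haploid states form transient communicating classes and `-` is
absorbing, making the chain non-reversible and reducible: alleles are
never regained. Compound changes on a branch (e.g. `0/0 -> 1/-`) have
no direct rate and arise by path composition within the branch; the
finite-time transition matrix `R(beta) = expm(Q beta)` is computed by
scaling-and-squaring (`Q` is non-symmetric and need not be
diagonalizable), with the structurally impossible (allele-regaining)
entries pinned to exactly zero.

Among-site rate variation uses a mean-one discrete Gamma mixture with
`h = 4` equal-probability categories and shape `eta`; each category
rate is the conditional mean of its bin (the "mean" discretization,
which preserves the unit mean exactly).

The site likelihood is computed by Felsenstein pruning over the 7-state
space with the root clamped to `0/0`, averaging over rate categories.
Partial likelihoods are rescaled per node with accumulated log scalers.
The kernel cost is `O(I J K^2)` with `K = 7` states.

## Read-count model

Observed data per cell and site are the coverage `c` and the three
alternative-nucleotide counts `m1 >= m2 >= m3`. The likelihood
factorizes as coverage times nucleotide composition.

**Coverage.** `c | alpha` is negative binomial with mean
`mu = alpha t s_j + eps` and variance `mu + alpha^2 nu s_j^2`, where
`alpha` in {0, 1, 2} is the number of sequenced alleles, `t` and `nu`
the mean and variance of allelic coverage, `s_j` the cell's size factor
and `eps = 1e-6` a stabilizer so that `alpha = 0` yields essentially
zero coverage. When the variance inflation vanishes (`alpha nu = 0`)
the Poisson limit is used instead of dividing by zero in the
(mean, variance) -> (p, r) reparameterization. Size factors are the
median over a cell's nonzero-coverage sites of coverage divided by the
site's geometric mean over nonzero-coverage cells; they are computed
once from the input matrix and held fixed during inference.

**Dropout.** Whole-genome amplification may hide alleles, so the
*observed* genotype `g'` can differ from the true `g`. In ADO mode an
`l`-allele genotype retains all alleles with probability
`1 - theta_ado` and loses one with probability `theta_ado`; in LDO mode
a diploid genotype additionally loses both alleles with probability
`theta_ldo`. The induced distribution of `g'` given `(g, alpha)` is a
fixed table (e.g. `0/1` with one sequenced allele is `0/-` or `1/-`
with probability 1/2 each). The per-genotype dropout construction is
the package's parameterization of dropout (one sampled `theta_ado`,
plus `theta_ldo` in LDO mode); it is isolated in
`readcounts.allele_count_distribution` as the single interpretation
point.

**Nucleotide counts.** Given `g' != '-'`, the split of `c` reads among
the three alternatives and the reference is Dirichlet-Multinomial with
concentration `w * f_vec`: the expected frequencies `f_vec` depend on
`g'` and the effective sequencing error rate `f` (amplification and
sequencing errors compounded into one parameter), and the
overdispersion `w` is `w1` when one nucleotide is expected (`0/0`,
`0/-`, `1/1`, `1/-`) and `w2` when two are (`0/1`, `1/1'`). For
`g' = '-'` the nucleotide term is 1 — zero coverage carries no
composition information. All pmfs are evaluated in log space with
`lgamma`-based Beta functions.

The per-leaf 7-vector `P(D | g)` marginalizes `(alpha, g')` and feeds
the pruning engine.

## Acquisition bias correction

Only preselected variant sites enter the data, which inflates branch
lengths if ignored. The corrected likelihood augments the variant-site
product with `I'` background sites constrained to be wildtype in every
cell: `I' * log P(all leaves 0/0 | tree)`, computed from the same
substitution model. This genotype-level conditional form is the
package's implementation choice (kept behind one function,
`likelihood.background_site_log_likelihood`, for easy replacement);
with `I' = 0` it reduces exactly to the uncorrected likelihood.

## Inference

The posterior over {topology, branch lengths, `d`, `eta`, `t`, `nu`,
`f`, `w1`, `w2`, `theta`} is sampled by Metropolis-Hastings with a
fixed move mixture: single-branch and whole-tree multiplier scalings,
narrow (sibling/nephew) and wide subtree exchanges, multiplier random
walks for positive scalars and logit random walks for probabilities.
Proposal windows are preset per parameter for acceptance rates of
roughly 0.2-0.5 at the package's default problem sizes. Likelihood
caches (per-branch transition matrices, the leaf read-count tensor) are
invalidated selectively per move class. Seeded runs are
bit-reproducible.

Priors (package choices, configurable): `d ~ Exp(mean 0.1)`,
`eta ~ LogNormal(0, 1)`, `t ~ LogNormal(log(median coverage / 2), 1)`,
`nu ~ Exp(mean t)`, `f ~ Beta(1, 99)`, `w1, w2 ~ LogNormal(log 100, 1)`,
`theta ~ Beta(1, 9)`, i.i.d. `Exp(mean 0.1)` branch lengths and a
uniform topology prior. The trunk is an ordinary free branch.

The default starting tree is a UPGMA tree on mismatch distances between
per-cell provisional genotype calls (rescaled per genome site); a
random coalescent start with overdispersed scalars is available for
convergence diagnostics. Inference runs in two stages: stage 1 without
acquisition bias correction, stage 2 restarted from the stage-1
posterior medians and MCC tree with the correction enabled; final calls
use stage 2. Convergence is assessed with the classic Gelman-Rubin
PSRF on post-burn-in scalar traces (default burn-in 10%). The posterior
tree summary is the maximum clade credibility tree (sampled tree
maximizing the product of clade frequencies) with per-clade mean branch
lengths and clade supports; supports above 0.5 are considered reportable.

## Variant, event and dropout calling

Given the MCC tree and posterior-median parameters, every node gets a
genotype per site by *joint* maximum likelihood: max-product dynamic
programming up the tree with back-tracking, maximizing over the shared
site-rate category, root clamped to `0/0`, ties broken toward the
earlier canonical state. Joint decoding guarantees that every
parent-child pair lies in the transition support, so branch changes can
be classified directly into the 28 recognized genotype transitions (17
mutation-event types); the same event at the same site on more than one
branch is flagged as parallel evolution. Per-node marginal choices are
deliberately not used, because marginal MAP can produce impossible
parent-child pairs.

At each leaf, `alpha` is decoded jointly with `g'` by maximizing the
leaf term given the decoded genotype; ADO is called when one allele
fewer than the genotype carries was sequenced, LDO (LDO mode only) when
a diploid site lost both alleles.

## Synthetic-data generator

The simulator is the exact generative counterpart of the model: a
Kingman-coalescent topology with a trunk (`Exp` trunk length with mean
equal to the MRCA height), rescaled so the root-to-leaf height equals
`mutation_rate * height_scale` (default 1000) in expected mutations per
site, with optional per-branch LogNormal rate jitter (sd 0.3) breaking
the clock; genotypes evolved site-independently under `R(beta)` with
discrete-Gamma site rates; reads emitted through the dropout, coverage
and Dirichlet-Multinomial models with per-cell LogNormal size factors
(sd 0.25, geometric mean 1). Sites with at least one non-wildtype leaf
genotype become the candidate variant sites; the rest are counted as
wildtype background, mirroring acquisition. Defaults: 20 cells, 10000
genome sites, mutation rate 8e-6, relative deletion rate 0.1,
`theta_ado = 0.2` (`theta_ldo = 0.05` in LDO mode), `f = 1e-3`,
`w1 = 100`, `w2 = 10`. Coverage-quality presets share a high mean for
high and medium quality and differ in variance — high `(t, nu) =
(20, 2)`, medium `(20, 10)` — while low quality has low mean and high
variance `(5, 50)`; the numeric values are package choices.

Two corruptions deliberately violate the model: CNAs (a fraction of
sites has coverage driven by a copy number drawn uniformly from
{0..10} \ {2}, scaled `n/2`) and doublets (a fraction of cells receives
an independently re-simulated partner cell's reads added rank-wise to
its own; evaluation keeps the host's truth labels).

What the generator does *not* emulate about real data: correlated
CNA segments spanning neighboring sites (corrupted sites are chosen
independently), read-level artifacts (mapping, strand, base-quality
structure), germline contamination, and read-based candidate-site
preselection (ascertainment here is exact on true genotypes). Passing
benchmarks therefore demonstrate internal consistency and robustness to
the modeled noise sources, not performance on any particular real
dataset.

## Benchmark metrics

Genotype calls are scored one-vs-rest per class over all (cell, site)
pairs — each deletion genotype, single mutants, double mutants
(`1/1` + `1/1'`), "any mutation" (everything non-wildtype), ADO and
LDO events. A replicate is excluded for a class when the ground-truth
class proportion is below 0.1%; precision and F1 are reported
unavailable (not zero) when no positive calls exist. Tree accuracy uses
the normalized Robinson-Foulds distance (unrooted bipartitions, scaled
by the maximum `2(J-3)`; the trunk carries no topological information
about the cells) and the Kuhner-Felsenstein branch-score distance over
the union of bipartitions.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the pipeline at reduced
scale, chosen as the package's study design: 20 cells,
1500-10000-site genomes yielding roughly 250-900 candidate sites,
2000-4000 MCMC iterations with 10% burn-in, and 2-10 replicates per
condition. Tolerances: rate-matrix row sums to 1e-12, row-stochasticity
of `R` to 1e-10, pruning vs. exhaustive enumeration to 1e-10, pmf
normalization checks to 1e-6-1e-10. Degenerate inputs are contracts,
not crashes: all-zero leaf likelihood vectors yield `-inf` with a
warning; zero-coverage datasets decode to the zero-allele-preferring
states; a cell with all-zero coverage is rejected by name in size
factor estimation.

## Known limitations

- `0/-` is read-indistinguishable from ADO at a wildtype site in a
  single cell; the separation comes entirely from phylogenetic sharing,
  so deletion-rate estimates degrade when the tree is poorly resolved
  (few cells or few sites) and `d` tends to be conservative at small
  scale. At a few hundred candidate sites a dataset realizes only a few
  dozen deletion events, so per-dataset deletion-rate estimates scatter
  by roughly 25% around the generating value and sharp 90% credible
  intervals can miss it in an above-nominal fraction of small
  replicates.
- ADO calling at homozygous-reference sites rests on coverage alone;
  with mean allelic coverage 20 and allelic variance 10 (the medium
  preset) and a 20% dropout rate, even decoding with the true tree and
  true parameters tops out near F1 0.83-0.86 at medium coverage — an
  information ceiling of the study conditions, not of the estimator.
- `eta` (site-rate shape) is only weakly identified from ascertained
  variant sites at small `I`; its posterior is prior-dominated.
- The MCMC uses a modest move set; very large trees would benefit from
  smarter topology proposals than narrow/wide exchange.
- Copy numbers above 2 exist only as simulator corruption, never as
  modeled states; insertions are out of scope.
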