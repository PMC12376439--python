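# scphylodel

Deletion-aware joint inference of cell phylogenies and genotypes from
single-cell DNA sequencing read counts.

## The problem

Single-cell whole-genome/exome sequencing of tumors promises to resolve
the evolutionary history of individual cells, but the data are noisy in
characteristic ways: whole-genome amplification drops alleles (ADO) or
whole loci (LDO), coverage is wildly uneven, and amplification plus
sequencing errors corrupt nucleotide counts. On top of point mutations,
tumor genomes lose alleles through somatic *deletions* — and a deleted
allele looks exactly like a dropped-out one in a single cell. Variant
callers that ignore deletions misread them as dropout on top of single
or double mutants; callers that ignore the phylogeny cannot borrow the
evidence that distinguishes a heritable deletion (shared by a clade)
from a random technical dropout (independent per cell).

`scphylodel` addresses this by modeling both jointly, for researchers
analyzing targeted single-cell DNA-seq panels of tumor (or other
somatic) cell populations.

## The model

Each site in each cell carries one of seven genotypes

```
G = { 0/0, 0/1, 1/1, 1/1', 0/-, 1/-, - }
```

(wildtype; heterozygous and two kinds of homozygous/heterozygous double
mutants; reference- and alternative-remaining single deletions; double
deletion). Genotypes evolve along a rooted cell phylogeny with a trunk
under a non-reversible rate matrix Q(d): per-allele mutation rate 1,
back-mutation 1/3, deletion rate d (relative to the mutation rate);
`-` is absorbing, so alleles are never regained. Site likelihoods are
computed by Felsenstein pruning with `R(β) = exp(Qβ)` and a mean-one
discrete-Gamma site-rate mixture (shape η, h = 4), the root clamped to
0/0.

Reads enter through a two-part observation model: coverage
`c ~ NB(mean α·t·s_j + ε, var mean + α²·ν·s_j²)` given the number of
sequenced alleles α (which dropout can reduce), and alternative
nucleotide counts `m1 ≥ m2 ≥ m3 | c ~ DirichletMultinomial(w · f_vec)`
with expected frequencies set by the observed genotype and the
effective sequencing error rate f, and overdispersion w1/w2. Size
factors `s_j` are median-of-ratios constants per cell. Because only
variant sites are analyzed, the likelihood is corrected for acquisition
bias with background (invariant) sites and discovery conditioning, so
branch lengths are not inflated by ascertainment.

Tree, branch lengths and all scalar parameters
(d, η, t, ν, f, w1, w2, θ) are sampled by MCMC; variants, 17 types of
mutation events (28 genotype transitions), and ADO/LDO events are then
called per branch/cell/site by joint maximum-likelihood decoding on the
maximum clade credibility tree. A matched simulator generates read
counts from the same generative process (plus optional CNA and doublet
corruption) for benchmarking.

## Worked example

Simulate a small dataset, infer the phylogeny, and call variants:

```bash
scphylodel simulate --cells 8 --sites 2000 --mutation-rate 3e-5 \
    --deletion-rate 0.3 --coverage high --seed 7 -o run/sim
scphylodel infer -i run/sim/reads.tsv --iterations 3000 --stage both \
    --seed 7 -o run/inf
scphylodel call -i run/sim/reads.tsv --tree run/inf/mcc_tree.nwk \
    --posterior run/inf/posterior_summary.json -o run/calls
scphylodel evaluate --calls run/calls/variants.tsv --truth run/sim/truth.tsv \
    --tree run/inf/mcc_tree.nwk --true-tree run/sim/true_tree.nwk \
    -o run/metrics.tsv
```

The `simulate` step reports the ascertainment split:

```
INFO scphylodel: simulated 221 candidate sites (1779 background) for 8 cells
```

`infer` prints the posterior median of the relative deletion rate —
`d=0.2252` here, against a simulated truth of 0.3 — and writes
`posterior_summary.json` with medians and a 90% credible interval for
every parameter. `call` reports `197 variant sites, 300 mutation
events`, writing per-cell genotypes (`variants.tsv`, with the canonical
labels above, decoded allele counts and dropout flags) and per-branch
classified events (`events.tsv`; this run's first events are a
`single point mutation` flagged as parallel and a
`single deletion (not LOH)` on a leaf branch). The final `metrics.tsv`
scores the calls against the simulation truth; here it reports, for
instance, `f1[0/1] = 0.941`, `f1[double_mutant] = 0.931`,
`f1[0/-] = 0.828`, and a normalized Robinson-Foulds distance of `0.0` —
the inferred topology is exactly the true one — with a branch-score
distance of `0.0027`.

The numbers above are from the exact commands shown; rerunning with the
same seeds reproduces them bit-for-bit.

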