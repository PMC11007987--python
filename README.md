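# phylogwas

Phylogeny-aware association of microbial pan-genomes with many phenotypes.

Bacteria reproduce clonally, so the whole genome is effectively in linkage
disequilibrium and population structure confounds naive genotype–phenotype
association: a gene carried by one clade will "correlate" with every trait
that clade happens to share. `phylogwas` scores orthogroup presence/absence
against binary — or automatically binarized continuous — phenotypes with
Fisher's exact test, then corrects for shared ancestry with a
contrasting-pairs statistic on the isolate phylogeny plus a label-switching
permutation test. It is built for high-throughput phenotype panels
(metabolomes, growth matrices), where thousands of traits are screened
against one pan-genome and results must be ranked, multiple-testing
corrected, and summarized for exploration.

## The statistics

For each (orthogroup *g*, trait *t*) pair over *n* isolates with a defined
trait value:

* **Fisher's exact test** on the 2×2 table of *g*-presence vs *t*-state, with
  the two-sided probability-mass definition, computed in exact integer
  arithmetic. q-values by Bonferroni or Benjamini–Hochberg, either per trait
  (trait-wise) or pooled across all traits.
* **Contrasting pairs.** A contrasting pair is two isolates differing in both
  gene and trait state whose connecting paths in the rooted tree are
  edge-disjoint from every other chosen pair — each pair is one
  phylogenetically independent observation. A single postorder dynamic
  program yields the maximum number of non-intersecting pairs and, among all
  maximum pairings, the most (*best*) and fewest (*worst*) pairs supporting
  the association (g⁺t⁺ matched with g⁻t⁻). `p_best`/`p_worst` are upper
  tails of Binomial(max_pairs, ½) at those counts.
* **Label-switching permutation test.** Trait labels are shuffled across
  isolates (tree and gene fixed); the empirical p-value of the observed best
  supporting count is `(1 + #{null ≥ obs}) / (1 + n_permut)`. The null
  distribution depends only on the gene's labeled topology and the number of
  trait-positive isolates, so it is cached in a SQLite file and reused across
  traits and duplicated gene patterns.
* **Binarization.** Continuous traits are split by an exact two-cluster 1-D
  k-means, or by a two-component Gaussian mixture whose ambiguous isolates
  (maximum posterior < 0.85 by default) abstain and are excluded for that
  trait.

Only the branching pattern of the tree matters; branch lengths are ignored.
All traversals are iterative, so fully unbalanced trees with tens of
thousands of leaves are handled without recursion limits.

## Worked example

Simulate a 40-genome pan-genome with one causal gene driving a 2σ phenotype
shift, then run the pipeline:

```sh
phylogwas simulate powerbench --effect 2 --genomes 40 --replicates 5 \
    --seed 7 --out demo
phylogwas run --genotype demo/genotype.tsv --traits demo/traits.tsv \
    --tree demo/tree.nwk --outdir demo_out \
    --multiple-testing fdr_bh:0.1 --n-permut 1000 --seed 7
```

The first command prints the benchmark over 5 replicates:

```
ranks: [1, 1, 1, 1, 1]
mean rank 1.00; top-4 fraction 100.0%
```

i.e. the causal gene was the top-ranked candidate in every replicate. The
second prints `1 significant trait(s); results in demo_out` and writes
`summary.tsv`:

```
trait	n_candidates	best_orthogroup	best_p_fisher	best_q_fisher	best_p_empirical
phenotype	1	OG0050	0.000111932	0.0113052	0.000999001
```

and per-trait tables (`demo_out/traits/phenotype/result.tsv`):

```
orthogroup	tp	fp	fn	tn	odds_ratio	p_fisher	q_fisher	p_best	p_worst	p_empirical
OG0050	9	2	4	25	28.125	0.000111932	0.0113052	0.0107422	0.0546875	0.000999001
```

Reading: of the isolates called trait-positive, 9 carry OG0050 and 4 do not
(odds ratio 28); the Fisher q survives the 0.1 FDR threshold; the tree
admits enough independent contrasting pairs that the association also holds
up under the permutation test (p ≈ 0.001, the add-one floor at
n_permut = 1000). Traits with no orthogroup passing the q-threshold are
dropped from the output entirely. When at least two traits survive, an
`overview.png` dendrogram (correlation/Jaccard distances, symmetrized so
anti-correlated traits cluster together) with −log₁₀ p-value panels is
written alongside machine-readable `overview_*.tsv` and per-trait data
bundles (coverage matrix, histogram values, newick tree).

Genotype input is accepted as gene-count or gene-list tables (Roary- and
OrthoFinder-style, CSV or TSV, either orientation). Without `--tree`, a
UPGMA tree is inferred from genotype Hamming distances.

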