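# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `phylogwas`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

Isolates of related bacterial strains share most of their genome by descent.
When a phenotype panel (e.g. a metabolome measured across strains) is
screened against pan-genome orthogroup presence/absence, the strongest raw
correlations are usually clade markers, not causal genes: clonal descendants
are pseudoreplicates, not independent observations. The package therefore
layers three statistics per (orthogroup, trait) pair — a fast unadjusted
score (Fisher), a phylogeny-aware count of independent evidence (contrasting
pairs), and an empirical null for that count (label-switching permutations).

## Contrasting-pairs dynamic program

A *contrasting pair* is two leaves with opposite gene state and opposite
trait state whose connecting paths are mutually edge-disjoint with all other
chosen pairs' paths. Each admissible pair witnesses at least one independent
gene flip and one independent trait flip somewhere on the tree, so the
maximum number of non-intersecting pairs bounds the number of independent
co-occurrence events.

The DP runs once per labeling, in postorder, over cells indexed by the
"leftover" state a subtree may expose upward: one of AB / Ab / aB / ab
(capital = gene present, trait positive) or none. Key structural fact: a
pair matched across a node's two children consumes both child edges, so a
node can either match across its children or expose a single leftover leaf —
never both. Each cell stores the maximum pair count plus, conditional on
that maximum, the largest and smallest attainable number of *supporting*
pairs ({AB, ab}-type); tie options merge their support ranges. The root's
no-leftover cell gives `max_pairs`, `best_supporting`, `worst_supporting`.
Exactness is verified in the test suite against a brute-force edge-disjoint
pairing enumerator, exhaustively for every rooted binary tree shape with up
to 7 leaves and every 4-ary labeling.

Infeasible cells carry a large negative sentinel, saturated at each level so
it cannot underflow the int32 working arrays; the per-node work is
unconditional (uniform), which keeps the scan time close to
`constant × n_genes × n_genomes` — verified by a log-log regression over a
6×6 genes × genomes grid (exponents required within 1.0 ± 0.25). Working
arrays are int32 to keep the whole DP state of typical trees inside L1
cache. The kernels are JIT-compiled with numba.

`p_best` and `p_worst` are the upper tails P[X ≥ best] and P[X ≥ worst] for
X ~ Binomial(max_pairs, ½): if each independent pair were a fair coin flip
for direction, this is the chance of seeing that much directional agreement.
Both are reported; `p_best ≤ p_worst` always holds.

## Permutation test

The post hoc guard permutes trait labels uniformly across (non-abstained)
leaves while the tree and the gene labeling stay fixed; the statistic is
`best_supporting`. The empirical p-value uses the add-one estimator
`(1 + #{null ≥ observed}) / (1 + n_permut)`, so ties count against
significance and p is bounded below by `1/(n_permut+1)`. If the observed
labeling admits no contrasting pair the test short-circuits to p = 1.

Because a uniformly permuted binary vector is just a uniformly random
arrangement of its ones, the null distribution depends only on (i) the
gene-labeled topology up to child-order swaps and (ii) the number of
trait-positive leaves. Null distributions are therefore cached in a
single-file SQLite store keyed by a canonical digest of the gene-labeled
tree (per-node blake2b over sorted child digests), the positive count, the
permutation count, and the seed. The permutation seed itself is derived by
stable hashing of (master seed, gene key, positive count, permutation
count): this makes a cache hit bit-identical to a fresh computation, makes
results independent of processing order and worker count, and lets two
traits with the same positive count share one null. Values are
deterministic given their key, so last-writer-wins under concurrent writers
is safe.

## Binarization of continuous traits

The pairs machinery needs binary phenotypes. Two methods:

* **k-means** (`--binarize kmeans`): exact two-cluster 1-D k-means — the
  optimal split is a contiguous prefix of the sorted values, found by
  enumerating all n−1 splits with prefix sums. Every isolate is labeled;
  label 1 is the larger-mean cluster; SSE ties send an equidistant point to
  the lower cluster. Exactness makes labels invariant under increasing
  affine transforms.
* **Gaussian mixture** (`--binarize gmm`, default): two-component univariate
  mixture fit by EM (scikit-learn), deterministically initialized with
  component means at the 25th/75th percentiles, equal weights, pooled
  variance, up to 500 iterations. Isolates are labeled by the larger-mean
  component only when their maximum posterior reaches the cutoff (default
  0.85); the rest abstain and are excluded from that trait's association,
  contingency table, and permutation test alike.

A GMM fit counts as **failed** when EM does not converge, a component weight
falls below 2/n, a component variance collapses below 1e−10 × the data
variance, or — a condition this package adds — the confident labels all fall
in one class. The last case matters in practice: at moderate separation EM
can converge to a legitimate-looking fit whose posterior-confident calls
carry no contrast at all, which is indistinguishable downstream from a
failed fit. All failures route through the same user policy: skip the trait
or fall back to k-means (default).

Binary input traits bypass binarization untouched. A numeric trait needs at
least 3 distinct values (and ≥ 6 non-missing for the GMM); constant and
two-valued non-binary columns are excluded at parse time with a warning.

## Multiple testing and gating

`method:alpha` strings configure correction: `native` (none), `bonferroni`,
or `fdr_bh` (Benjamini–Hochberg step-up, via statsmodels). Trait-wise
correction pools within one trait's orthogroup p-values; global correction
pools across all traits × orthogroups. Only orthogroups passing the
q-threshold proceed to the (expensive) pairs + permutation stage — the
Fisher q alone decides which traits survive into the output, matching the
gating role the q-filter plays in the overall design; `--permute-all`
removes the gate. Records are sorted by ascending Fisher p (ties by
orthogroup id) and truncated to `max_genes` (default 50). Fisher p-values
are computed with exact integer arithmetic (probability-mass two-sided
definition), so tied tables compare exactly and results match an independent
exact oracle to machine precision.

## Synthetic data

Two generators, both bit-reproducible per seed:

* `random_dataset`: i.i.d. Bernoulli(½) gene presence plus a random binary
  trait — scaling studies only; labels carry no signal by construction.
* `evolve_pangenome` / `simulate_phenotype`: a random bifurcating tree built
  by uniform joining of lineages; each gene evolves down the tree from a
  Bernoulli(½) root state with a symmetric per-branch flip probability
  (default 0.1); monomorphic genes are resampled, and the causal gene is
  resampled until its presence frequency lies in 20–80%. The phenotype is
  N(0, 1) per genome without the causal gene and N(effect, 1) with it.
  Defaults: 100 non-causal genes + 1 causal. The flip probability of 0.1
  per branch gives realistic intermediate gene frequencies and moderate
  homoplasy — enough phylogenetic correlation that sister leaves agree more
  than random pairs (a tested property) while keeping most genes
  polymorphic.

What this emulates: phylogenetically correlated gene content with a single
additive causal signal. What it does not: recombination/HGT networks, rate
heterogeneity across branches or genes, gene-length or annotation effects,
measurement batch structure. Benchmarks passing on these simulations show
the statistical machinery behaves as designed, not that any particular real
dataset will yield causal genes.

`rank_recovery` runs the full loop — evolve, draw phenotype, GMM-binarize
(k-means fallback), Fisher-scan — and reports the causal gene's 1-based rank
under the key (Fisher p, permutation p, orthogroup id). The permutation p
is evaluated lazily, only for orthogroups exactly tied with the causal gene
on Fisher p, where it can change the rank. A replicate whose trait cannot
be binarized at all scores worse than last place.

Benchmark presets follow the study grid: genome counts
{25, 50, 75, 100, 150, 200}, effect sizes {0.5, 1, 1.5, 2, 3}, 20
replicates; the acceptance script runs the 75-genome / 1.5σ cell and the
test suite additionally checks the 50-genome / 3σ cell (mean rank ≤ 1.5).

## Reports

Significant traits are clustered by a symmetrized distance: numeric pairs
use 1 − |Pearson r| over co-observed isolates; binary (or mixed, via the
numeric trait's binarized view) pairs use 1 − max(J(a,b), J(a,¬b)) with
Jaccard index J. The symmetrization formulas are this package's choice; the
goal they implement is that strongly anti-correlated traits cluster with
their correlated counterparts. Pairs with fewer than 3 co-observed isolates,
and zero-variance traits, get distance 1. Average-linkage hierarchical
clustering orders the dendrogram; per trait the panels show −log₁₀ of the
best Fisher q, the best permutation p, and their product, with p-values
floored at 1e−300 before the log. Leaf order and bar values are also written
as TSV so the figure is testable and the data reusable.

Per-trait bundles contain the isolate tree (newick), a coverage matrix
(per-genome gene counts per candidate orthogroup, with gene identifiers
attached when a gene-list table was supplied), the raw numeric values with
4-way g±/t± class labels (abstained isolates keep an explicit `excluded`
class), metadata joined by identifier, and URL templates echoed verbatim.
The interactive browser front-end of the original tool is out of scope; the
bundles carry the same information as static files.

## Determinism and parallelism

One master seed governs everything. Per-unit seeds are derived by stable
blake2b hashing, so adding or removing traits never changes other traits'
results, and outputs are byte-identical for any `--n-cpus` and for
cold-vs-warm cache runs (asserted in the test suite). Traits are processed
as independent work units in two stages (binarize + Fisher scan; gate +
pairs + permutation) so that globally pooled correction sees all p-values
between the stages. Output tables print floats with 6 significant digits;
undefined values serialize as `NA`, infinite odds ratios as `inf`.

## Numerical and degenerate-input choices

* Fisher: zero-margin tables return p = 1; the odds ratio is ∞ when only the
  off-diagonal is empty and NA when the table is degenerate.
* Exact integer comparison (`w ≤ w_obs`) decides two-sided inclusion — no
  floating tie tolerance.
* Polytomies in input trees are resolved to binary by a left-fold in input
  order (zero-length edges), with a warning that pair counts can depend on
  the resolution.
* The UPGMA fallback tree (no `--tree` given) uses Hamming distances on the
  binarized genotype, average linkage, and breaks ties by the
  lexicographically smallest member id, making it invariant to input order.
  Identical genotype rows (distance 0) join first.
* Alignment of inputs keeps the sorted intersection of isolate ids and
  requires at least 4 shared isolates.
* Tree parsing accepts quoted labels and comments, ignores branch lengths
  and internal node labels, and reports positions for unbalanced
  parentheses and duplicate labels.

## Problem sizes used in the checked benchmarks

The test suite exercises: all tree shapes to 7 leaves × all 4^n labelings
(DP oracle); all 2×2 tables with n ≤ 40 (Fisher oracle); 4- and 5-leaf
trees with 10,000 permutations against exhaustive enumeration; a
{25..100}² 6×6 subgrid for runtime scaling; 500 null traits over a
50-genome evolved pan-genome for FDR calibration; and the 75-genome /
50-genome power-benchmark cells with 20 replicates each. These sizes keep
the full suite in the low tens of seconds on one core while leaving each
check statistically meaningful.

## Known limitations

* Fisher p-values on clonal data are scores, not causal probabilities; the
  pairs statistics are the structure-aware part of the output.
* The pairs algorithm needs binary phenotypes and sacrifices power when a
  gene–trait association traces back to a single branch (one clade, one
  event): such associations are, by design, not counted as repeated
  independent evidence.
* GMM abstention shrinks the per-trait sample; heavily overlapping mixtures
  can leave few labeled isolates, and the k-means fallback trades abstention
  for misclassification.
* Errors in the input tree topology propagate directly into the pair counts;
  the user tree's root is taken as given.
* Gene copy numbers beyond presence/absence are surfaced only in the
  coverage matrix, never in the statistics.
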