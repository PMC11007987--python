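"""Synthetic data generators: scaling-benchmark matrices and tree-evolved
pan-genomes with a causal gene driving a Gaussian phenotype.

Two kinds of inputs are produced:

* ``random_dataset`` — i.i.d. Bernoulli(1/2) gene presence and a random
  binary trait, used for runtime-scaling studies of the pairwise-comparisons
  step (no phylogenetic signal on purpose: the cost of the algorithm does not
  depend on the labels).
* ``evolve_pangenome`` + ``simulate_phenotype`` — a random bifurcating tree
  (uniform joining), genes gained/lost along branches with a symmetric
  per-branch flip probability, and a numeric phenotype drawn N(0,1) for
  genomes lacking the designated causal gene and N(effect_size,1) for
  carriers.  This is the power benchmark for the automatic binarization:
  how highly does the causal gene rank after binarize + associate?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import association as _assoc
from . import binarize as _binarize
from . import pairs as _pairs
from .data_io import GenotypeMatrix
from .phylo import Phylogeny

__all__ = [
    "SimulationSpec",
    "random_dataset",
    "random_tree",
    "evolve_pangenome",
    "simulate_phenotype",
    "rank_recovery",
    "BENCHMARK_GENOMES",
    "BENCHMARK_EFFECTS",
    "GRID_SIZES",
]

# benchmark presets
BENCHMARK_GENOMES = (25, 50, 75, 100, 150, 200)
BENCHMARK_EFFECTS = (0.5, 1.0, 1.5, 2.0, 3.0)
GRID_SIZES = tuple(range(5, 101, 5))  # [5, 10, ..., 100] on both axes

DEFAULT_FLIP_PROB = 0.1  # per-branch symmetric gain/loss probability
DEFAULT_N_GENES = 100  # non-causal genes per simulated pan-genome


@dataclass
class SimulationSpec:
    n_genomes: int
    n_genes: int = DEFAULT_N_GENES
    effect_size: float = 1.5
    flip_prob: float = DEFAULT_FLIP_PROB
    seed: int = 0
    causal_gene_index: int | None = None  # default: middle of the gene list


def random_dataset(n_genes: int, n_genomes: int, seed: int):
    """I.i.d. Bernoulli(1/2) genotype matrix plus a random binary trait."""
    if n_genes < 2 or n_genomes < 2:
        raise ValueError("need at least 2 genes and 2 genomes")
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 2, size=(n_genomes, n_genes))
    trait = rng.integers(0, 2, size=n_genomes).astype(np.int8)
    isolates = [f"I{i:04d}" for i in range(n_genomes)]
    genes = [f"OG{j:04d}" for j in range(n_genes)]
    return GenotypeMatrix(isolates, genes, counts), trait


def random_tree(n_leaves: int, rng) -> Phylogeny:
    """Random bifurcating tree by uniform joining of lineages."""
    names = [f"I{i:04d}" for i in range(n_leaves)]
    lineages = list(names)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append((a, b))
    return Phylogeny.from_nested(lineages[0])


def _evolve_gene(tree: Phylogeny, flip_prob: float, rng) -> np.ndarray:
    """One gene's presence per leaf: root Bernoulli(1/2), per-branch flips.

    Iterative preorder (root last in postorder arrays, so walk backwards).
    """
    state = np.empty(tree.n_nodes, dtype=np.int8)
    state[tree.root] = rng.integers(0, 2)
    flips = rng.random(tree.n_nodes) < flip_prob
    for i in range(tree.n_nodes - 1, -1, -1):  # parents precede children
        if tree.left[i] >= 0:
            for c in (tree.left[i], tree.right[i]):
                state[c] = state[i] ^ (1 if flips[c] else 0)
    out = np.empty(tree.n_leaves, dtype=np.int8)
    for i in range(tree.n_nodes):
        if tree.left[i] < 0:
            out[tree.leaf_pos[i]] = state[i]
    return out


def evolve_pangenome(
    n_genomes: int,
    n_genes: int = DEFAULT_N_GENES,
    seed: int = 0,
    flip_prob: float = DEFAULT_FLIP_PROB,
    causal_gene_index: int | None = None,
    causal_freq=(0.2, 0.8),
):
    """Tree-evolved pan-genome with one frequency-constrained causal gene.

    Returns ``(tree, genotype, causal_index)``.  Monomorphic genes are
    resampled; the causal gene is additionally resampled until its presence
    frequency lies in ``causal_freq`` so the phenotype contrast is informative.
    """
    if n_genomes < 4:
        raise ValueError("need at least 4 genomes")
    rng = np.random.default_rng(seed)
    tree = random_tree(n_genomes, rng)
    if causal_gene_index is None:
        causal_gene_index = (n_genes + 1) // 2
    total = n_genes + 1
    counts = np.empty((n_genomes, total), dtype=np.int64)
    lo, hi = causal_freq
    for j in range(total):
        causal = j == causal_gene_index
        for _ in range(10_000):
            gene = _evolve_gene(tree, flip_prob, rng)
            f = gene.mean()
            if causal:
                if lo <= f <= hi:
                    break
            elif 0.0 < f < 1.0:
                break
        counts[:, j] = gene
    genes = [f"OG{j:04d}" for j in range(total)]
    # rows follow the tree's leaf order, so genotype and tree stay aligned
    g = GenotypeMatrix(list(tree.leaf_names), genes, counts)
    return tree, g, causal_gene_index


def simulate_phenotype(genotype: GenotypeMatrix, causal_gene_index: int, effect_size: float, seed: int):
    """Numeric phenotype: N(0,1) without the causal gene, N(effect,1) with it."""
    gene = genotype.present[:, causal_gene_index]
    if gene.all() or not gene.any():
        raise ValueError("causal gene must be polymorphic")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, size=len(gene)) + effect_size * gene


def _causal_rank(p, p_emp_fn, ids, causal_idx) -> int:
    """1-based rank with key (p_fisher, p_empirical, orthogroup id).

    The permutation p is only evaluated for orthogroups tied with the causal
    gene on the Fisher p (exact arithmetic makes those ties exact), which is
    the only place the tie-break can change the causal gene's rank.
    """
    pc = p[causal_idx]
    ahead = int(np.sum(p < pc))
    tied = [j for j in range(len(p)) if p[j] == pc]
    if len(tied) == 1:
        return ahead + 1
    emp = {j: p_emp_fn(j) for j in tied}
    key_c = (emp[causal_idx], ids[causal_idx])
    ahead += sum(1 for j in tied if j != causal_idx and (emp[j], ids[j]) < key_c)
    return ahead + 1


def rank_recovery(spec: SimulationSpec, n_replicates: int = 20, n_permut: int = 1000):
    """Per-replicate 1-based rank of the causal gene in the association output.

    Each replicate: evolve a pan-genome, draw the phenotype, binarize with the
    Gaussian mixture (k-means fallback), Fisher-scan all orthogroups on the
    labeled isolates, and rank by ascending Fisher p with permutation-p and
    orthogroup-id tie-breaks.  A replicate whose trait cannot be binarized at
    all scores ``n_genes + 2`` (worse than last).
    """
    ranks = []
    for rep in range(n_replicates):
        rep_seed = _pairs.derive_seed(spec.seed, "rank_recovery", rep)
        tree, g, causal_idx = evolve_pangenome(
            spec.n_genomes,
            spec.n_genes,
            seed=rep_seed,
            flip_prob=spec.flip_prob,
            causal_gene_index=spec.causal_gene_index,
        )
        pheno = simulate_phenotype(g, causal_idx, spec.effect_size, _pairs.derive_seed(rep_seed, "pheno"))
        try:
            b = _binarize.binarize_gmm(
                pheno, on_failure="kmeans", seed=_pairs.derive_seed(rep_seed, "gmm"), trait_id="sim"
            )
        except _binarize.BinarizationError:
            ranks.append(g.counts.shape[1] + 1)
            continue
        trait = b.trait_vector()
        if np.nansum(trait) in (0, np.sum(~np.isnan(trait))):  # constant after binarization
            ranks.append(g.counts.shape[1] + 1)
            continue
        _, p = _assoc.trait_fisher_scan(trait, g)

        def p_emp(j, _tree=tree, _g=g, _trait=trait, _seed=rep_seed):
            return _pairs.permutation_test(
                _tree,
                _g.present[:, j].astype(np.int8),
                _trait,
                n_permut=n_permut,
                seed=_pairs.derive_seed(_seed, "perm", j),
            )

        ranks.append(_causal_rank(p, p_emp, g.orthogroup_ids, causal_idx))
    return ranks
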