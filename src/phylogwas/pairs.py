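"""Contrasting-pairs statistic and label-switching permutation test.

The population-structure correction at the heart of the package.  A
*contrasting pair* is a pair of leaves with opposite gene state AND opposite
trait state whose connecting paths are edge-disjoint from every other chosen
pair's path; each such pair is one phylogenetically independent observation.
A single postorder dynamic program per labeling computes

* ``max_pairs`` — the maximum number of non-intersecting contrasting pairs,
* ``best_supporting`` / ``worst_supporting`` — among all maximum pairings,
  the most and fewest pairs that co-vary in the hypothesized direction
  (gene+trait+ matched with gene-trait-).

States are encoded 0=AB, 1=Ab, 2=aB, 3=ab (capital = gene present / trait
positive).  The DP cell per node is indexed by the "leftover" leaf state a
subtree may expose to be paired higher up (4 = none); because a matched pair
between the two children consumes both child edges, a node can either match
across its children or expose one leftover, never both.

The permutation test shuffles trait labels across leaves while gene and tree
stay fixed; its null distribution depends only on the gene's labeled topology
and the number of trait-positive leaves, which is what makes the on-disk
cache effective for many-trait datasets.
"""

from __future__ import annotations

import hashlib
import sqlite3
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import binom

__all__ = [
    "PairSummary",
    "LeafLabeling",
    "max_contrasting_pairs",
    "contrasting_pairs_scan",
    "permutation_test",
    "canonical_gene_key",
    "PermCache",
    "derive_seed",
]

# state encoding: 0=AB 1=Ab 2=aB 3=ab ; 4 = no leftover
_NEG = -(1 << 28)  # sentinel small enough that int32 sums cannot overflow


@dataclass(frozen=True)
class PairSummary:
    max_pairs: int
    best_supporting: int
    worst_supporting: int
    p_best: float
    p_worst: float


@dataclass
class LeafLabeling:
    """Per-leaf joint gene/trait state aligned with ``tree.leaf_names``.

    ``states`` holds 0..3 (AB, Ab, aB, ab) or -1 for excluded leaves
    (missing trait, e.g. mixture-model abstentions); excluded leaves are
    pruned before the pair analysis.
    """

    states: np.ndarray

    @classmethod
    def from_vectors(cls, gene, trait) -> "LeafLabeling":
        gene = np.asarray(gene)
        trait = np.asarray(trait, dtype=float)
        states = np.where(
            np.isnan(trait), -1, 3 - 2 * gene.astype(np.int8) - np.nan_to_num(trait).astype(np.int8)
        ).astype(np.int8)
        return cls(states)


@njit(cache=True)
def _dp_core(left, right, state, pairs, smax, smin):  # pragma: no cover - jitted
    """Postorder DP; returns (max_pairs, best_supporting, worst_supporting)."""
    n = left.shape[0]
    for i in range(n):
        for s in range(5):
            pairs[i, s] = _NEG
            smax[i, s] = 0
            smin[i, s] = 0
        if left[i] < 0:
            s = state[i]
            pairs[i, s] = 0
            pairs[i, 4] = 0
        else:
            l, r = left[i], right[i]
            # leftover states 0..3: reserved leaf in one child, other child free.
            # Infeasible cells stay at the (clamped) sentinel; their support
            # values are meaningless but only ever feed other infeasible cells.
            for st in range(4):
                v1 = pairs[l, st] + pairs[r, 4]
                v2 = pairs[l, 4] + pairs[r, st]
                if v1 > v2:
                    best = v1
                    hi = smax[l, st] + smax[r, 4]
                    lo = smin[l, st] + smin[r, 4]
                elif v2 > v1:
                    best = v2
                    hi = smax[l, 4] + smax[r, st]
                    lo = smin[l, 4] + smin[r, st]
                else:
                    best = v1
                    h1 = smax[l, st] + smax[r, 4]
                    w1 = smin[l, st] + smin[r, 4]
                    h2 = smax[l, 4] + smax[r, st]
                    w2 = smin[l, 4] + smin[r, st]
                    hi = h1 if h1 > h2 else h2
                    lo = w1 if w1 < w2 else w2
                if best < _NEG:  # saturate so sentinels never compound
                    best = _NEG
                pairs[i, st] = best
                smax[i, st] = hi
                smin[i, st] = lo
            # no leftover: both children unreserved, or match across children.
            # pairs[*, 4] >= 0 always, so a match touching an infeasible cell
            # (deeply negative v) can never win or tie.
            best = pairs[l, 4] + pairs[r, 4]
            hi = smax[l, 4] + smax[r, 4]
            lo = smin[l, 4] + smin[r, 4]
            # contrasting combinations: (AB,ab) supporting, (Ab,aB) opposing
            for k in range(4):
                if k == 0:
                    x, y, supp = 0, 3, 1
                elif k == 1:
                    x, y, supp = 3, 0, 1
                elif k == 2:
                    x, y, supp = 1, 2, 0
                else:
                    x, y, supp = 2, 1, 0
                v = pairs[l, x] + pairs[r, y] + 1
                h = smax[l, x] + smax[r, y] + supp
                w = smin[l, x] + smin[r, y] + supp
                if v > best:
                    best = v
                    hi = h
                    lo = w
                elif v == best:
                    if h > hi:
                        hi = h
                    if w < lo:
                        lo = w
            pairs[i, 4] = best
            smax[i, 4] = hi
            smin[i, 4] = lo
    rt = n - 1
    return pairs[rt, 4], smax[rt, 4], smin[rt, 4]


@njit(cache=True)
def _dp_single(left, right, state):  # pragma: no cover - jitted
    n = left.shape[0]
    pairs = np.empty((n, 5), np.int32)
    smax = np.empty((n, 5), np.int32)
    smin = np.empty((n, 5), np.int32)
    return _dp_core(left, right, state, pairs, smax, smin)


@njit(cache=True)
def _dp_genes(left, right, leaf_node, genes, trait):  # pragma: no cover - jitted
    """DP for many genes against one binary trait; returns (G,3) int64."""
    n = left.shape[0]
    g_count = genes.shape[0]
    out = np.empty((g_count, 3), np.int64)
    pairs = np.empty((n, 5), np.int32)
    smax = np.empty((n, 5), np.int32)
    smin = np.empty((n, 5), np.int32)
    state = np.full(n, -1, np.int8)
    for g in range(g_count):
        for k in range(leaf_node.shape[0]):
            state[leaf_node[k]] = 3 - 2 * genes[g, k] - trait[k]
        mp, bs, ws = _dp_core(left, right, state, pairs, smax, smin)
        out[g, 0] = mp
        out[g, 1] = bs
        out[g, 2] = ws
    return out


@njit(cache=True)
def _perm_null(left, right, leaf_node, gene, perms):  # pragma: no cover - jitted
    """best_supporting for each permuted trait vector (rows of ``perms``)."""
    n = left.shape[0]
    n_perm = perms.shape[0]
    stats = np.empty(n_perm, np.int64)
    pairs = np.empty((n, 5), np.int32)
    smax = np.empty((n, 5), np.int32)
    smin = np.empty((n, 5), np.int32)
    state = np.full(n, -1, np.int8)
    for p in range(n_perm):
        for k in range(leaf_node.shape[0]):
            state[leaf_node[k]] = 3 - 2 * gene[k] - perms[p, k]
        _, bs, _ = _dp_core(left, right, state, pairs, smax, smin)
        stats[p] = bs
    return stats


def _leaf_node_map(tree) -> np.ndarray:
    """node index of each leaf, ordered by leaf position."""
    leaf_node = np.empty(tree.n_leaves, dtype=np.int64)
    for node in range(tree.n_nodes):
        if tree.left[node] < 0:
            leaf_node[tree.leaf_pos[node]] = node
    return leaf_node


def _binom_upper_tail(k: int, n: int) -> float:
    """P[X >= k] for X ~ Binomial(n, 1/2)."""
    if n == 0:
        return 1.0
    return float(binom.sf(k - 1, n, 0.5))


def max_contrasting_pairs(tree, labels: LeafLabeling) -> PairSummary:
    """Maximum non-intersecting contrasting pairs plus binomial tail bounds.

    ``p_best`` (resp. ``p_worst``) is the upper tail P[X >= best_supporting]
    (P[X >= worst_supporting]) for X ~ Binomial(max_pairs, 1/2): the chance of
    seeing that many direction-consistent pairs if gene and trait flips were
    independent coin tosses on each independent pair.
    """
    states = np.asarray(labels.states, dtype=np.int8)
    if len(states) != tree.n_leaves:
        raise ValueError("labeling length does not match number of leaves")
    if np.any(states < 0):
        keep = [tree.leaf_names[i] for i in range(tree.n_leaves) if states[i] >= 0]
        if len(keep) < 2:
            return PairSummary(0, 0, 0, 1.0, 1.0)
        sub = tree.prune(keep)
        idx = {n: i for i, n in enumerate(tree.leaf_names)}
        states = np.array([states[idx[n]] for n in sub.leaf_names], dtype=np.int8)
        tree = sub
    node_state = np.full(tree.n_nodes, -1, dtype=np.int8)
    node_state[_leaf_node_map(tree)] = states
    mp, bs, ws = _dp_single(tree.left.astype(np.int64), tree.right.astype(np.int64), node_state)
    mp, bs, ws = int(mp), int(bs), int(ws)
    if mp == 0:
        return PairSummary(0, 0, 0, 1.0, 1.0)
    return PairSummary(mp, bs, ws, _binom_upper_tail(bs, mp), _binom_upper_tail(ws, mp))


def contrasting_pairs_scan(tree, genes: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Batched DP: (max_pairs, best, worst) for each row of ``genes``.

    ``genes`` is a (n_genes, n_leaves) 0/1 matrix and ``trait`` a binary
    vector, both aligned with ``tree.leaf_names``.  One jitted call per
    dataset, so per-gene overhead is a handful of array writes — this is the
    workhorse behind the linear runtime scaling in both factors.
    """
    genes = np.ascontiguousarray(np.asarray(genes, dtype=np.int8))
    trait = np.asarray(trait, dtype=np.int8)
    if genes.shape[1] != tree.n_leaves or len(trait) != tree.n_leaves:
        raise ValueError("gene matrix / trait length must match number of leaves")
    return _dp_genes(
        tree.left.astype(np.int64),
        tree.right.astype(np.int64),
        _leaf_node_map(tree),
        genes,
        trait,
    )


# ---------------------------------------------------------------- canonical key
def canonical_gene_key(tree, gene) -> str:
    """Canonical digest of the gene-labeled topology.

    Invariant under child-order swaps: two presence/absence vectors that induce
    isomorphic labeled topologies share a key and hence one cache entry.
    Computed bottom-up with per-node digests of the sorted child digests.
    """
    gene = np.asarray(gene).astype(np.uint8)
    if len(gene) != tree.n_leaves:
        raise ValueError("gene vector length does not match number of leaves")
    digests = [b""] * tree.n_nodes
    for i in range(tree.n_nodes):
        if tree.left[i] < 0:
            digests[i] = bytes([gene[tree.leaf_pos[i]]])
        else:
            a, b = digests[tree.left[i]], digests[tree.right[i]]
            if b < a:
                a, b = b, a
            digests[i] = hashlib.blake2b(a + b"|" + b, digest_size=16).digest()
    return digests[tree.root].hex() + f":n{tree.n_leaves}"


def derive_seed(*parts) -> int:
    """Stable sub-2^31 seed from arbitrary hashable parts (order matters)."""
    h = hashlib.blake2b("\x1f".join(map(repr, parts)).encode(), digest_size=8)
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)


# ----------------------------------------------------------------- perm cache
class PermCache:
    """Single-file key-value store for permutation null distributions.

    Values are deterministic given their key (canonical gene topology,
    number of trait-positive leaves, permutation count, seed policy), so
    last-writer-wins is safe under concurrent writers.
    """

    VERSION = "phylogwas-permcache-1"

    def __init__(self, path):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("CREATE TABLE IF NOT EXISTS kv (key TEXT PRIMARY KEY, value BLOB)")
        cur = self._conn.execute("SELECT value FROM kv WHERE key='__version__'").fetchone()
        if cur is None:
            self._conn.execute(
                "INSERT OR REPLACE INTO kv VALUES ('__version__', ?)", (self.VERSION.encode(),)
            )
            self._conn.commit()
        elif cur[0].decode() != self.VERSION:
            raise ValueError(f"incompatible cache version in {self.path}")

    def get(self, key: str):
        row = self._conn.execute("SELECT value FROM kv WHERE key=?", (key,)).fetchone()
        if row is None:
            return None
        return np.frombuffer(row[0], dtype=np.int32)

    def put(self, key: str, stats: np.ndarray) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO kv VALUES (?, ?)",
            (key, np.asarray(stats, dtype=np.int32).tobytes()),
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _null_cache_key(gene_key: str, n_pos: int, n_permut: int, seed: int) -> str:
    return f"{gene_key}|npos={n_pos}|nperm={n_permut}|seed={seed}"


def permutation_null(tree, gene, n_pos: int, n_permut: int, seed: int, cache=None) -> np.ndarray:
    """Sorted null distribution of best_supporting under trait-label shuffles.

    The trait vector is an arbitrary arrangement of ``n_pos`` ones over the
    leaves; uniformly random permutations of it are exactly uniformly random
    arrangements, so the null depends only on (gene topology, n_pos).
    """
    gene = np.asarray(gene).astype(np.int8)
    key = _null_cache_key(canonical_gene_key(tree, gene), n_pos, n_permut, seed)
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit.astype(np.int64)
    n = tree.n_leaves
    base = np.zeros(n, dtype=np.int8)
    base[:n_pos] = 1
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permut, n), dtype=np.int8)
    for i in range(n_permut):
        perms[i] = base[rng.permutation(n)]
    stats = _perm_null(
        tree.left.astype(np.int64),
        tree.right.astype(np.int64),
        _leaf_node_map(tree),
        gene,
        perms,
    )
    stats = np.sort(stats)
    if cache is not None:
        cache.put(key, stats)
    return stats


def permutation_test(tree, gene, trait, n_permut: int, seed: int, cache=None) -> float:
    """Empirical p-value of the observed best_supporting under label switching.

    Add-one estimator ``(1 + #{null >= observed}) / (1 + n_permut)``; ties
    count against significance.  Returns 1.0 without permuting when the
    observed labeling admits no contrasting pair.
    """
    if n_permut < 100:
        raise ValueError("n_permut must be >= 100")
    gene = np.asarray(gene).astype(np.int8)
    trait = np.asarray(trait, dtype=float)
    labeled = ~np.isnan(trait)
    if not labeled.all():  # permute only among leaves with a defined trait
        keep = [tree.leaf_names[i] for i in range(tree.n_leaves) if labeled[i]]
        if len(keep) < 2:
            return 1.0
        idx = {n: i for i, n in enumerate(tree.leaf_names)}
        tree = tree.prune(keep)
        order = [idx[n] for n in tree.leaf_names]
        gene = gene[order]
        trait = trait[order]
    trait = trait.astype(np.int8)
    obs = max_contrasting_pairs(tree, LeafLabeling.from_vectors(gene, trait))
    if obs.max_pairs == 0:
        return 1.0
    null = permutation_null(tree, gene, int(trait.sum()), n_permut, seed, cache=cache)
    exceed = int(np.sum(null >= obs.best_supporting))
    return (1 + exceed) / (1 + n_permut)
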