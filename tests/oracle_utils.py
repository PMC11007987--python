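"""Independent oracles used by the test suite.

Everything here is deliberately naive — enumeration, exact rational
arithmetic, exhaustive search — and shares no code with the package paths it
checks.
"""

import itertools
from fractions import Fraction
from functools import lru_cache

import numpy as np


# ----------------------------------------------------- rooted binary tree shapes
@lru_cache(maxsize=None)
def tree_shapes(n):
    """All unlabeled rooted binary tree shapes with n leaves (nested tuples)."""
    if n == 1:
        return ("L",)
    out = []
    seen = set()
    for a in range(1, n // 2 + 1):
        for sa in tree_shapes(a):
            for sb in tree_shapes(n - a):
                key = frozenset([(str(sa), str(sb)), (str(sb), str(sa))])
                if key in seen:
                    continue
                seen.add(key)
                out.append((sa, sb))
    return tuple(out)


def shape_to_nested(shape, prefix="T"):
    counter = itertools.count()

    def rec(s):
        if s == "L":
            return f"{prefix}{next(counter)}"
        return (rec(s[0]), rec(s[1]))

    return rec(shape)


# ------------------------------------------------ brute-force contrasting pairs
def _leaf_nodes_and_parents(tree):
    leafnodes = [None] * tree.n_leaves
    parent = {}
    for i in range(tree.n_nodes):
        if tree.left[i] < 0:
            leafnodes[tree.leaf_pos[i]] = i
        else:
            parent[tree.left[i]] = i
            parent[tree.right[i]] = i
    return leafnodes, parent


def path_edge_masks(tree):
    """Bitmask (over child-node ids) of the edges on each leaf-pair path."""
    leafnodes, parent = _leaf_nodes_and_parents(tree)
    depth = {}
    for i in range(tree.n_nodes):
        d, j = 0, i
        while j in parent:
            j = parent[j]
            d += 1
        depth[i] = d
    masks = {}
    L = tree.n_leaves
    for a in range(L):
        for b in range(a + 1, L):
            x, y = leafnodes[a], leafnodes[b]
            mask = 0
            while x != y:
                if depth[x] >= depth[y]:
                    mask |= 1 << x
                    x = parent[x]
                else:
                    mask |= 1 << y
                    y = parent[y]
            masks[(a, b)] = mask
    return masks


def brute_force_pairs(tree, states, masks=None):
    """Exhaustive maximum set of edge-disjoint contrasting pairs.

    states: per-leaf 0=AB 1=Ab 2=aB 3=ab.  Returns
    (max_pairs, best_supporting, worst_supporting).
    """
    if masks is None:
        masks = path_edge_masks(tree)
    L = tree.n_leaves
    cand = []
    for a in range(L):
        for b in range(a + 1, L):
            pair = {states[a], states[b]}
            if pair == {0, 3}:
                cand.append((masks[(a, b)], 1))
            elif pair == {1, 2}:
                cand.append((masks[(a, b)], 0))
    best = [0, 0, 0]

    def rec(i, used, count, supp):
        if count > best[0]:
            best[0], best[1], best[2] = count, supp, supp
        elif count == best[0]:
            if supp > best[1]:
                best[1] = supp
            if supp < best[2]:
                best[2] = supp
        for j in range(i, len(cand)):
            m, s = cand[j]
            if not (m & used):
                rec(j + 1, used | m, count + 1, supp + s)

    rec(0, 0, 0, 0)
    return tuple(best)


def exhaustive_permutation_p(tree, gene, trait, masks=None):
    """Exact permutation p: fraction of all trait-label orderings whose
    best_supporting is >= the observed one (identity included)."""
    gene = list(gene)
    trait = list(trait)
    obs = brute_force_pairs(
        tree, [3 - 2 * g - t for g, t in zip(gene, trait)], masks=masks
    )[1]
    hits = total = 0
    for perm in itertools.permutations(trait):
        stat = brute_force_pairs(
            tree, [3 - 2 * g - t for g, t in zip(gene, perm)], masks=masks
        )[1]
        total += 1
        if stat >= obs:
            hits += 1
    return hits / total, obs


# --------------------------------------------------------- exact Fisher oracle
@lru_cache(maxsize=1)
def _factorials(n_max=200):
    f = [1] * (n_max + 1)
    for i in range(1, n_max + 1):
        f[i] = f[i - 1] * i
    return f


def fisher_two_sided_oracle(tp, fp, fn, tn):
    """Two-sided Fisher p by summing exact hypergeometric pmfs (Fractions)."""
    fact = _factorials()
    r1, r2 = tp + fp, fn + tn
    c1 = tp + fn
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def pmf(k):
        return Fraction(
            fact[r1] * fact[r2] * fact[c1] * fact[n - c1],
            fact[k] * fact[r1 - k] * fact[c1 - k] * fact[r2 - c1 + k] * fact[n],
        )

    p_obs = pmf(tp)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs:
            total += pk
    return float(total)


# ----------------------------------------------------------- brute-force BH
def bh_qvalues_brute(p):
    """q_i = min over j with p_(j) >= p_i of m * p_(j) / j (step-up), capped at 1."""
    p = list(p)
    m = len(p)
    q = []
    for pi in p:
        vals = []
        for pj in p:
            if pj >= pi:
                j = sum(1 for pk in p if pk <= pj)
                vals.append(m * pj / j)
        q.append(min(1.0, min(vals)))
    return q
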