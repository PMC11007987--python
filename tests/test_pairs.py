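"""Contrasting-pairs DP, permutation test, canonical keys, and the cache."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracle_utils import (
    brute_force_pairs,
    exhaustive_permutation_p,
    path_edge_masks,
    shape_to_nested,
    tree_shapes,
)
from phylogwas.pairs import (
    LeafLabeling,
    PermCache,
    canonical_gene_key,
    derive_seed,
    max_contrasting_pairs,
    permutation_null,
    permutation_test,
)
from phylogwas.phylo import Phylogeny, parse_newick


def _summary(tree, states):
    s = max_contrasting_pairs(tree, LeafLabeling(np.asarray(states, dtype=np.int8)))
    return s.max_pairs, s.best_supporting, s.worst_supporting


class TestMaxContrastingPairs:
    def test_two_perfect_pairs(self):
        tree = parse_newick("((A,B),(C,D));")
        # A=AB B=ab C=AB D=ab: both cherries are supporting contrasting pairs
        assert _summary(tree, [0, 3, 0, 3]) == (2, 2, 2)

    def test_no_contrast(self):
        tree = parse_newick("((A,B),(C,D));")
        s = max_contrasting_pairs(tree, LeafLabeling(np.zeros(4, dtype=np.int8)))
        assert s.max_pairs == 0 and s.p_best == 1.0 and s.p_worst == 1.0

    def test_caterpillar_matches_brute_force(self):
        tree = parse_newick("(((A,B),C),D);")
        states = [0, 2, 1, 3]  # AB, aB, Ab, ab
        assert _summary(tree, states) == brute_force_pairs(tree, states)

    def test_excluded_leaves_pruned(self):
        tree = parse_newick("((A,B),(C,D));")
        full = _summary(parse_newick("(A,(C,D));"), [0, 0, 3])
        with_excl = max_contrasting_pairs(tree, LeafLabeling(np.array([0, -1, 0, 3], dtype=np.int8)))
        assert (with_excl.max_pairs, with_excl.best_supporting) == full[:2]

    def test_invariant_ordering(self):
        tree = parse_newick("((A,B),(C,D));")
        s = _summary(tree, [0, 3, 1, 2])
        assert 0 <= s[2] <= s[1] <= s[0]

    @given(
        st.integers(min_value=0, max_value=len(tree_shapes(6)) - 1),
        st.lists(st.integers(min_value=0, max_value=3), min_size=6, max_size=6),
    )
    def test_matches_brute_force_on_random_labelings(self, shape_idx, labels):
        tree = Phylogeny.from_nested(shape_to_nested(tree_shapes(6)[shape_idx]))
        assert _summary(tree, labels) == brute_force_pairs(tree, labels)

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=5, max_size=5))
    def test_gene_trait_swap_symmetry(self, labels):
        tree = parse_newick("(((A,B),C),(D,E));")
        swap = {0: 0, 1: 2, 2: 1, 3: 3}  # Ab <-> aB
        assert _summary(tree, labels) == _summary(tree, [swap[s] for s in labels])

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=5, max_size=5))
    def test_complement_symmetries(self, labels):
        tree = parse_newick("((A,(B,C)),(D,E));")
        both = {0: 3, 3: 0, 1: 2, 2: 1}  # complement gene AND trait
        assert _summary(tree, labels) == _summary(tree, [both[s] for s in labels])
        gene_only = {0: 2, 2: 0, 1: 3, 3: 1}
        mp, best, worst = _summary(tree, labels)
        mp2, best2, worst2 = _summary(tree, [gene_only[s] for s in labels])
        assert mp2 == mp
        assert best2 == mp - worst and worst2 == mp - best


class TestPermutationTest:
    def test_p_bounds(self):
        tree = parse_newick("(((A,B),C),(D,E));")
        gene = np.array([1, 0, 1, 0, 1], dtype=np.int8)
        trait = np.array([1, 0, 0, 1, 0], dtype=float)
        p = permutation_test(tree, gene, trait, n_permut=200, seed=1)
        assert 1 / 201 <= p <= 1.0

    def test_zero_pairs_short_circuit(self):
        tree = parse_newick("((A,B),(C,D));")
        p = permutation_test(tree, np.ones(4, dtype=np.int8), np.array([1, 0, 1, 0.0]), 200, seed=1)
        assert p == 1.0

    def test_statistic_never_below_observed_gives_p_one(self):
        # observed labeling has only opposing pairs (best_supporting = 0), so
        # every permutation scores at least as high -> p = 1 exactly
        tree = parse_newick("((A,B),(C,D));")
        gene = np.array([1, 0, 1, 0], dtype=np.int8)
        trait = np.array([0.0, 1, 0, 1])
        assert permutation_test(tree, gene, trait, 200, seed=3) == 1.0

    def test_determinism_given_seed(self):
        tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        rng = np.random.default_rng(0)
        gene = rng.integers(0, 2, 8).astype(np.int8)
        trait = rng.integers(0, 2, 8).astype(float)
        p1 = permutation_test(tree, gene, trait, 500, seed=11)
        p2 = permutation_test(tree, gene, trait, 500, seed=11)
        assert p1 == p2

    def test_small_n_permut_rejected(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            permutation_test(tree, np.zeros(4, np.int8), np.zeros(4), 50, seed=0)

    def test_null_distribution_matches_exhaustive(self):
        # the sampled null must reproduce the exact arrangement distribution
        tree = parse_newick("(((A,B),C),(D,E));")
        masks = path_edge_masks(tree)
        gene = [1, 0, 1, 0, 1]
        exact = np.zeros(3)
        for pos in itertools.combinations(range(5), 2):
            t = [1 if i in pos else 0 for i in range(5)]
            stat = brute_force_pairs(tree, [3 - 2 * g - ti for g, ti in zip(gene, t)], masks=masks)[1]
            exact[stat] += 0.1
        n = 10_000
        null = permutation_null(tree, np.array(gene, np.int8), 2, n, seed=5)
        freq = np.bincount(null, minlength=3) / n
        for k in range(3):
            se = np.sqrt(exact[k] * (1 - exact[k]) / n)
            assert abs(freq[k] - exact[k]) <= 4 * se

    def test_empirical_p_matches_exhaustive(self):
        tree = parse_newick("(((A,B),C),(D,E));")
        masks = path_edge_masks(tree)
        gene = [1, 0, 1, 0, 1]
        trait = [1, 0, 0, 1, 0]
        p_star, _ = exhaustive_permutation_p(tree, gene, trait, masks=masks)
        n = 10_000
        p_hat = permutation_test(tree, np.array(gene, np.int8), np.array(trait, float), n, seed=5)
        se = np.sqrt(p_star * (1 - p_star) / n)
        assert abs(p_hat - p_star) <= 3 * se + 1 / n


class TestCanonicalKey:
    def test_child_swap_invariance(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((C,D),(A,B));")
        g1 = np.array([1, 0, 1, 1])  # aligned with each tree's own leaf order
        idx = {n: i for i, n in enumerate(t1.leaf_names)}
        g2 = np.array([g1[idx[n]] for n in t2.leaf_names])
        assert canonical_gene_key(t1, g1) == canonical_gene_key(t2, g2)

    def test_complement_distinct(self):
        # no complement symmetry is assumed (3 carriers vs 1 carrier)
        t = parse_newick("((A,B),(C,D));")
        g = np.array([1, 1, 1, 0])
        assert canonical_gene_key(t, g) != canonical_gene_key(t, 1 - g)

    def test_isomorphic_gene_patterns_share_key(self):
        t = parse_newick("((A,B),(C,D));")
        # presence on one leaf of each cherry: isomorphic labelings
        assert canonical_gene_key(t, np.array([1, 0, 0, 0])) == canonical_gene_key(
            t, np.array([0, 0, 1, 0])
        )


class TestPermCache:
    def test_cache_hit_bit_identical(self, tmp_path):
        tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        gene = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=np.int8)
        with PermCache(tmp_path / "c.sqlite") as cache:
            n1 = permutation_null(tree, gene, 4, 300, seed=9, cache=cache)
            n2 = permutation_null(tree, gene, 4, 300, seed=9, cache=cache)
        assert np.array_equal(n1, n2)
        fresh = permutation_null(tree, gene, 4, 300, seed=9, cache=None)
        assert np.array_equal(n1, fresh)

    def test_version_guard(self, tmp_path):
        path = tmp_path / "c.sqlite"
        with PermCache(path) as cache:
            cache.put("k", np.array([1, 2, 3]))
        import sqlite3

        conn = sqlite3.connect(path)
        conn.execute("UPDATE kv SET value=? WHERE key='__version__'", (b"other",))
        conn.commit()
        conn.close()
        with pytest.raises(ValueError):
            PermCache(path)

    def test_derive_seed_stable_and_bounded(self):
        s1 = derive_seed(42, "k", 3)
        assert s1 == derive_seed(42, "k", 3)
        assert 0 <= s1 < 2**31
        assert s1 != derive_seed(42, "k", 4)


class TestScaleRobustness:
    def test_dp_on_13k_caterpillar(self):
        n = 13_000
        s = "L0"
        for i in range(1, n):
            s = f"({s},L{i})"
        tree = parse_newick(s + ";")
        rng = np.random.default_rng(4)
        states = rng.integers(0, 4, n).astype(np.int8)
        summary = max_contrasting_pairs(tree, LeafLabeling(states))
        assert summary.max_pairs > 0
        assert 0 <= summary.worst_supporting <= summary.best_supporting <= summary.max_pairs
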