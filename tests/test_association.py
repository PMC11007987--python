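"""Fisher exact test, descriptive stats, correction, and trait analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracle_utils import bh_qvalues_brute, fisher_two_sided_oracle
from phylogwas.association import (
    AssocConfig,
    ContingencyTable,
    analyze_trait,
    contingency,
    correct_pvalues,
    descriptive_stats,
    fisher_exact,
    parse_multiple_testing,
    trait_fisher_scan,
)
from phylogwas.data_io import GenotypeMatrix
from phylogwas.phylo import parse_newick


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_perfect_association_closed_form(self):
        p = fisher_exact(ContingencyTable(10, 0, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_transpose_symmetry(self):
        assert fisher_exact(ContingencyTable(8, 2, 1, 9)) == fisher_exact(
            ContingencyTable(8, 1, 2, 9)
        )

    def test_zero_margin(self):
        assert fisher_exact(ContingencyTable(0, 0, 7, 3)) == 1.0

    @given(st.tuples(*[st.integers(min_value=0, max_value=12)] * 4))
    def test_matches_exact_oracle(self, tbl):
        p = fisher_exact(ContingencyTable(*tbl))
        assert p == pytest.approx(fisher_two_sided_oracle(*tbl), rel=1e-12)

    def test_matches_scipy_on_sample(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, 4)
            ours = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-6)


class TestDescriptiveStats:
    @pytest.mark.parametrize(
        "tbl,expect",
        [
            ((10, 0, 0, 10), (np.inf, 1.0, 1.0)),
            ((5, 5, 5, 5), (1.0, 0.5, 0.5)),
            ((8, 2, 1, 9), (36.0, 8 / 9, 9 / 11)),
        ],
    )
    def test_examples(self, tbl, expect):
        odds, sens, spec = descriptive_stats(ContingencyTable(*tbl))
        assert odds == pytest.approx(expect[0])
        assert sens == pytest.approx(expect[1])
        assert spec == pytest.approx(expect[2])

    def test_undefined_fields(self):
        odds, sens, spec = descriptive_stats(ContingencyTable(0, 0, 0, 5))
        assert np.isnan(odds) and np.isnan(sens)


class TestCorrection:
    def test_bonferroni(self):
        assert list(correct_pvalues([0.01, 0.5], "bonferroni")) == [0.02, 1.0]

    def test_native_identity(self):
        p = [0.3, 0.001, 0.7]
        assert list(correct_pvalues(p, "native")) == p

    def test_bh_example(self):
        q = correct_pvalues([0.01, 0.02, 0.03, 0.04], "fdr_bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=12))
    def test_bh_matches_brute_force(self, p):
        q = correct_pvalues(p, "fdr_bh")
        assert np.allclose(q, bh_qvalues_brute(p), rtol=1e-9)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30))
    def test_bh_monotone_in_sorted_order(self, p):
        q = correct_pvalues(p, "fdr_bh")
        order = np.argsort(p)
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)

    def test_parse_multiple_testing(self):
        assert parse_multiple_testing("fdr_bh:0.1") == ("fdr_bh", 0.1)
        for bad in ("fdr_bh", "magic:0.1", "bonferroni:1.5", "bonferroni:0"):
            with pytest.raises(ValueError):
                parse_multiple_testing(bad)


def _toy_inputs():
    tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    iso = list(tree.leaf_names)
    # gene0 tracks the trait perfectly, gene1 is constant, gene2 random-ish
    counts = np.array(
        [
            [1, 1, 0],
            [1, 1, 1],
            [1, 1, 0],
            [1, 1, 1],
            [0, 1, 0],
            [0, 1, 1],
            [0, 1, 0],
            [0, 1, 1],
        ]
    )
    g = GenotypeMatrix(iso, ["OG0", "OG1", "OG2"], counts)
    trait = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
    return tree, g, trait


class TestAnalyzeTrait:
    def test_constant_gene_never_significant(self):
        tree, g, trait = _toy_inputs()
        tables, p = trait_fisher_scan(trait, g)
        j = g.orthogroup_ids.index("OG1")
        assert p[j] == 1.0
        assert tables[j].fn == 0 and tables[j].tn == 0

    def test_gating_and_sorting(self):
        tree, g, trait = _toy_inputs()
        cfg = AssocConfig(method="native", alpha=0.05, n_permut=200, master_seed=1)
        res = analyze_trait("t", trait, g, tree, cfg)
        assert res.significant
        ids = [r.orthogroup_id for r in res.records]
        assert ids == ["OG0"]  # only the perfect gene passes native:0.05
        assert res.records[0].p_fisher == pytest.approx(2 / math.comb(8, 4), rel=1e-12)
        assert res.records[0].q_fisher >= res.records[0].p_fisher - 1e-15

    def test_permute_all_includes_everything(self):
        tree, g, trait = _toy_inputs()
        cfg = AssocConfig(method="native", alpha=0.05, n_permut=200, permute_all=True, master_seed=1)
        res = analyze_trait("t", trait, g, tree, cfg)
        # OG1 and OG2 tie at p = 1; the id tie-break orders them
        assert [r.orthogroup_id for r in res.records] == ["OG0", "OG1", "OG2"]
        assert all(r.p_empirical is not None for r in res.records)

    def test_max_genes_truncation(self):
        tree, g, trait = _toy_inputs()
        cfg = AssocConfig(
            method="native", alpha=1.0, n_permut=200, max_genes=2, permute_all=True, master_seed=1
        )
        res = analyze_trait("t", trait, g, tree, cfg)
        assert len(res.records) == 2

    def test_duplicated_orthogroups_identical_records(self, tmp_path):
        from phylogwas.pairs import PermCache

        tree, g, trait = _toy_inputs()
        counts = np.hstack([g.counts, g.counts[:, :1]])
        g2 = GenotypeMatrix(g.isolate_ids, ["OG0", "OG1", "OG2", "OG9"], counts)
        cfg = AssocConfig(method="native", alpha=0.05, n_permut=200, master_seed=1)
        with PermCache(tmp_path / "c.sqlite") as cache:
            res = analyze_trait("t", trait, g2, tree, cfg, cache=cache)
        by_id = {r.orthogroup_id: r for r in res.records}
        assert by_id["OG0"].p_fisher == by_id["OG9"].p_fisher
        assert by_id["OG0"].p_empirical == by_id["OG9"].p_empirical
        assert by_id["OG0"].pairs == by_id["OG9"].pairs

    def test_missing_traits_reduce_contingency(self):
        tree, g, trait = _toy_inputs()
        trait = trait.copy()
        trait[0] = np.nan
        tbl = contingency(g.present[:, 0], trait)
        assert tbl.n == 7
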