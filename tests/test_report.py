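"""Trait distances, overview outputs, and per-trait bundles."""

import numpy as np
import pytest

from phylogwas.association import AssociationRecord, ContingencyTable, TraitResult
from phylogwas.pairs import PairSummary
from phylogwas.report import overview_figure, trait_bundle, trait_distances, write_overview


def _record(tid, og, p=0.01, q=0.01, pemp=0.1):
    return AssociationRecord(
        trait_id=tid,
        orthogroup_id=og,
        table=ContingencyTable(4, 1, 1, 4),
        odds_ratio=16.0,
        sensitivity=0.8,
        specificity=0.8,
        p_fisher=p,
        q_fisher=q,
        pairs=PairSummary(3, 3, 2, 0.125, 0.5),
        p_empirical=pemp,
    )


class TestTraitDistances:
    def test_anticorrelated_numeric_distance_zero(self, rng):
        x = rng.normal(0, 1, 30)
        traits = {"a": x, "b": -x}
        ids, D = trait_distances(traits, {"a": "numeric", "b": "numeric"})
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_complement_binary_distance_zero(self):
        a = np.array([1, 0, 1, 1, 0, 0], dtype=float)
        traits = {"a": a, "b": 1 - a}
        ids, D = trait_distances(traits, {"a": "binary", "b": "binary"})
        assert D[0, 1] == 0.0

    def test_independent_numeric_far_apart(self, rng):
        x = rng.choice([-1.0, 1.0], 1000)
        y = rng.choice([-1.0, 1.0], 1000)
        ids, D = trait_distances({"a": x, "b": y}, {"a": "numeric", "b": "numeric"})
        assert D[0, 1] == pytest.approx(1.0, abs=0.1)

    def test_symmetry_and_zero_diagonal(self, rng):
        traits = {f"t{i}": rng.normal(0, 1, 20) for i in range(4)}
        kinds = {k: "numeric" for k in traits}
        ids, D = trait_distances(traits, kinds)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)

    def test_mixed_pair_uses_binarized_view(self, rng):
        num = rng.normal(0, 1, 24)
        bview = (num > 0).astype(float)
        traits = {"num": num, "bin": bview}
        ids, D = trait_distances(
            traits, {"num": "numeric", "bin": "binary"}, binarized={"num": bview}
        )
        assert D[0, 1] == 0.0  # identical binarized views

    def test_few_coobserved_isolates(self):
        a = np.array([1.0, 2.0, np.nan, np.nan, np.nan, 3.0])
        b = np.array([np.nan, np.nan, 1.0, 2.0, 3.0, np.nan])
        ids, D = trait_distances({"a": a, "b": b}, {"a": "numeric", "b": "numeric"})
        assert D[0, 1] == 1.0


class TestOverview:
    def test_duplicate_traits_adjacent(self, rng, tmp_path):
        x = rng.normal(0, 1, 30)
        traits = {"t1": x, "t2": x.copy(), "t3": rng.normal(0, 1, 30)}
        ids, D = trait_distances(traits, {k: "numeric" for k in traits})
        results = {k: TraitResult(k, records=[_record(k, "OG0")], significant=True) for k in traits}
        ordered, rows = overview_figure(ids, D, results)
        i1, i2 = ordered.index("t1"), ordered.index("t2")
        assert abs(i1 - i2) == 1

    def test_bar_values_log_arithmetic(self):
        results = {"t": TraitResult("t", records=[_record("t", "OG0", q=0.01, pemp=0.1)], significant=True)}
        ordered, rows = overview_figure(["t"], np.zeros((1, 1)), results)
        tid, f, e, prod = rows[0]
        assert (f, e, prod) == (pytest.approx(2.0), pytest.approx(1.0), pytest.approx(3.0))

    def test_write_overview_deterministic(self, rng, tmp_path):
        traits = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}
        kinds = {k: "numeric" for k in traits}
        ids, D = trait_distances(traits, kinds)
        results = {k: TraitResult(k, records=[_record(k, "OG0")], significant=True) for k in traits}
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_overview(ids, D, results, d1)
        write_overview(ids, D, results, d2)
        for name in ("overview_order.tsv", "overview_pvalues.tsv", "overview.png"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_many_traits_render(self, rng, tmp_path):
        n = 300
        ids = [f"t{i:04d}" for i in range(n)]
        X = rng.normal(0, 1, (n, n))
        D = 1 - np.abs(np.corrcoef(X))
        np.fill_diagonal(D, 0)
        D = (D + D.T) / 2
        results = {t: TraitResult(t, records=[_record(t, "OG0")], significant=True) for t in ids}
        write_overview(ids, D, results, tmp_path / "big")
        assert (tmp_path / "big" / "overview.png").exists()


class TestTraitBundle:
    def test_bundle_contents(self, tmp_path):
        from phylogwas.binarize import binarize_gmm
        from phylogwas.data_io import GenotypeMatrix
        from phylogwas.phylo import parse_newick

        rng = np.random.default_rng(3)
        tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        iso = list(tree.leaf_names)
        counts = rng.integers(0, 3, size=(8, 2))
        g = GenotypeMatrix(iso, ["OG0", "OG1"], counts)
        vals = np.where(counts[:, 0] > 0, 5.0, 0.0) + rng.normal(0, 0.1, 8)
        b = binarize_gmm(vals, seed=0, trait_id="t")
        rec = _record("t", "OG0")
        res = TraitResult("t", binarization=b, records=[rec], significant=True)
        trait_bundle(res, g, tree, tmp_path / "t")
        cov = (tmp_path / "t" / "coverage.tsv").read_text().splitlines()
        assert cov[0].split("\t")[:2] == ["isolate", "OG0"]
        # coverage cells carry the raw gene counts
        row_a = cov[1].split("\t")
        assert int(row_a[1].split(":")[0]) == counts[iso.index(row_a[0]), 0]
        vals_lines = (tmp_path / "t" / "values.tsv").read_text().splitlines()
        classes = {line.split("\t")[2] for line in vals_lines[1:]}
        assert classes <= {"g+t+", "g+t-", "g-t+", "g-t-", "excluded", "missing"}
        assert (tmp_path / "t" / "tree.nwk").read_text().strip().endswith(";")

    def test_pie_counts_partition(self):
        rec = _record("t", "OG0")
        tbl = rec.table
        assert tbl.tp + tbl.fp + tbl.fn + tbl.tn == tbl.n

    def test_bundle_idempotent(self, tmp_path):
        from phylogwas.data_io import GenotypeMatrix
        from phylogwas.phylo import parse_newick

        tree = parse_newick("((A,B),(C,D));")
        g = GenotypeMatrix(list(tree.leaf_names), ["OG0"], np.eye(4, 1, dtype=int) + 0)
        res = TraitResult("t", records=[_record("t", "OG0")], significant=True)
        trait_bundle(res, g, tree, tmp_path / "x")
        first = {p.name: p.read_bytes() for p in (tmp_path / "x").iterdir()}
        trait_bundle(res, g, tree, tmp_path / "x")
        second = {p.name: p.read_bytes() for p in (tmp_path / "x").iterdir()}
        assert first == second
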