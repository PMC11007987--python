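"""Post-GWAS outputs: trait dendrogram with p-value panels, per-trait bundles.

The overview clusters all significant traits by a symmetrized similarity —
1 - |Pearson r| for numeric pairs, 1 - max(Jaccard, complement-Jaccard) for
binary pairs — so strongly anti-correlated traits land next to their
correlated counterparts.  Next to the dendrogram, horizontal bars show
-log10 of each trait's best Fisher q, best permutation p, and their product.
Everything is also emitted as plain TSV so the figures are testable and the
data reusable by external viewers.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .data_io import fmt6, _safe_name
from .association import P_FLOOR

__all__ = ["trait_distances", "overview_figure", "trait_bundle", "write_overview"]


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.sum(a | b)
    if union == 0:
        return 1.0  # two all-absent vectors are identical
    return float(np.sum(a & b) / union)


def _pair_distance(x, y, kind_x, kind_y, binar_x, binar_y) -> float:
    """Distance between two traits over co-observed isolates.

    Numeric-numeric: 1 - |pearson|.  Binary (or mixed, via the binarized view
    of the numeric trait): 1 - max(J(a,b), J(a,~b)).  Fewer than 3 co-observed
    isolates, or a zero-variance side, gives distance 1.
    """
    if kind_x == "numeric" and kind_y == "numeric":
        mask = ~np.isnan(x) & ~np.isnan(y)
        if mask.sum() < 3:
            return 1.0
        xv, yv = x[mask], y[mask]
        if xv.std() == 0 or yv.std() == 0:
            return 1.0
        r = float(np.corrcoef(xv, yv)[0, 1])
        return 1.0 - abs(r)
    # binary or mixed: use the binarized views
    a = binar_x if kind_x == "numeric" else x
    b = binar_y if kind_y == "numeric" else y
    mask = ~np.isnan(a) & ~np.isnan(b)
    if mask.sum() < 3:
        return 1.0
    ab = a[mask].astype(bool)
    bb = b[mask].astype(bool)
    return 1.0 - max(_jaccard(ab, bb), _jaccard(ab, ~bb))


def trait_distances(traits, kinds, binarized=None):
    """Symmetric distance matrix over significant traits.

    ``traits``: dict trait_id -> value vector (aligned isolates, NaN missing);
    ``kinds``: dict trait_id -> "binary" | "numeric";
    ``binarized``: dict trait_id -> binarized 0/1/NaN vector for numeric traits.
    Returns (ids, matrix).
    """
    ids = sorted(traits)
    if len(ids) < 2:
        raise ValueError("need at least 2 traits for a distance matrix")
    binarized = binarized or {}
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        xi = np.asarray(traits[ids[i]], dtype=float)
        if kinds[ids[i]] == "numeric" and np.nanstd(xi) == 0:
            warnings.warn(f"trait {ids[i]!r} has zero variance; distance 1 to all others")
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_distance(
                np.asarray(traits[ids[i]], dtype=float),
                np.asarray(traits[ids[j]], dtype=float),
                kinds[ids[i]],
                kinds[ids[j]],
                np.asarray(binarized.get(ids[i]), dtype=float) if ids[i] in binarized else None,
                np.asarray(binarized.get(ids[j]), dtype=float) if ids[j] in binarized else None,
            )
            D[i, j] = D[j, i] = d
    return ids, D


def _neglog10(p: float) -> float:
    return -float(np.log10(max(float(p), P_FLOOR)))


def overview_figure(ids, D, results, out_path=None):
    """Average-linkage dendrogram + aligned -log10 p-value bars.

    ``results``: dict trait_id -> TraitResult.  Per trait the *best* (minimum
    over its records) Fisher q and permutation p feed three bars: f = -log10 q,
    e = -log10 p_emp, * = -log10(q x p_emp).  Returns the leaf-ordered trait
    list; writes the figure when ``out_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    n = len(ids)
    if n > 1:
        Z = hierarchy.linkage(squareform(np.asarray(D), checks=False), method="average")
        order = list(hierarchy.leaves_list(Z))
    else:
        Z, order = None, [0]
    ordered = [ids[i] for i in order]

    rows = []
    for tid in ordered:
        recs = results[tid].records
        q_best = min((r.q_fisher for r in recs), default=1.0)
        e_best = min((r.p_empirical for r in recs if r.p_empirical is not None), default=1.0)
        rows.append((tid, _neglog10(q_best), _neglog10(e_best), _neglog10(q_best * e_best)))

    if out_path is not None:
        fig_h = max(2.0, 0.18 * n + 1.0)
        fig, axes = plt.subplots(
            1, 4, figsize=(11, fig_h), sharey=True, gridspec_kw={"width_ratios": [2, 1, 1, 1]}
        )
        y = np.arange(n)
        if Z is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hierarchy.dendrogram(Z, ax=axes[0], orientation="left", no_labels=True)
        axes[0].set_title("traits")
        for ax, col, title in zip(axes[1:], (1, 2, 3), ("f: -log10 q_fisher", "e: -log10 p_emp", "*: product")):
            ax.barh(10.0 * y + 5.0, [row[col] for row in rows], height=8.0)
            ax.set_title(title, fontsize=8)
        axes[1].set_ylim(0, 10 * n)
        fig.tight_layout()
        fig.savefig(out_path, dpi=100)
        plt.close(fig)
    return ordered, rows


def write_overview(ids, D, results, out_dir) -> None:
    """Write overview_order.tsv, overview_pvalues.tsv and overview.png."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered, rows = overview_figure(ids, D, results, out_path=out / "overview.png")
    with open(out / "overview_order.tsv", "w") as fh:
        fh.write("trait\n")
        for tid in ordered:
            fh.write(tid + "\n")
    with open(out / "overview_pvalues.tsv", "w") as fh:
        fh.write("trait\tneglog10_q_fisher\tneglog10_p_empirical\tneglog10_product\n")
        for tid, f, e, prod in rows:
            fh.write(f"{tid}\t{fmt6(f)}\t{fmt6(e)}\t{fmt6(prod)}\n")


def trait_bundle(result, genotype, tree, out_dir, metadata=None, gene_url=None, orthogroup_url=None):
    """Per-trait machine-readable bundle for downstream viewers.

    Writes the isolate tree (newick), a coverage matrix (isolates x candidate
    orthogroups, cells = gene counts, gene ids attached when available), and
    for numeric traits the raw values with the 4-way gene/trait class label
    (mixture abstentions keep their own ``excluded`` class).  Metadata columns
    are joined by id; URL templates are echoed verbatim into config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    candidates = [r.orthogroup_id for r in result.records]
    og_idx = {og: j for j, og in enumerate(genotype.orthogroup_ids)}
    iso_meta = (metadata or {}).get("isolate")
    missing_meta_warned = False

    if tree is not None:
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")

    meta_cols = []
    if iso_meta is not None:
        meta_cols = sorted({k for rec in iso_meta.records.values() for k in rec})
    with open(out / "coverage.tsv", "w") as fh:
        fh.write("isolate\t" + "\t".join(candidates + meta_cols) + "\n")
        for i, iso in enumerate(genotype.isolate_ids):
            cells = []
            for og in candidates:
                j = og_idx[og]
                if genotype.gene_lists is not None and genotype.counts[i, j]:
                    cells.append(f"{genotype.counts[i, j]}:{'|'.join(genotype.gene_lists[i][j])}")
                else:
                    cells.append(str(genotype.counts[i, j]))
            if iso_meta is not None:
                rec = iso_meta.get(iso)
                if not rec and not missing_meta_warned:
                    warnings.warn("some isolates have no metadata record")
                    missing_meta_warned = True
                cells += [rec.get(k, "") for k in meta_cols]
            fh.write(iso + "\t" + "\t".join(cells) + "\n")

    b = result.binarization
    if b is not None and getattr(b, "raw_values", None) is not None and candidates:
        top = og_idx[candidates[0]]
        gene = genotype.present[:, top]
        with open(out / "values.tsv", "w") as fh:
            fh.write("isolate\tvalue\tclass\n")
            for i, iso in enumerate(genotype.isolate_ids):
                lab = b.labels[i]
                if lab == -2:
                    cls = "missing"
                elif lab == -1:
                    cls = "excluded"
                else:
                    cls = ("g+" if gene[i] else "g-") + ("t+" if lab == 1 else "t-")
                fh.write(f"{iso}\t{fmt6(float(b.raw_values[i]))}\t{cls}\n")

    config = {
        "trait": result.trait_id,
        "gene_url": gene_url,
        "orthogroup_url": orthogroup_url,
        "candidates": candidates,
    }
    (out / "config.json").write_text(json.dumps(config, indent=1, sort_keys=True) + "\n")
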