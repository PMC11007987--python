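"""Reading and validating genotype/trait/metadata tables; writing results.

Genotype tables come in two dialects: *gene-count* (cells are per-genome
copy numbers, the Roary default) and *gene-list* (cells are delimiter-joined
gene identifiers, produced by Roary and OrthoFinder orthogroup tables).
Both are accepted as CSV or TSV, with orthogroups as rows (the upstream
convention) or as columns; presence is count >= 1 everywhere downstream,
copy numbers survive only into the coverage matrix.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitTable",
    "MetadataTable",
    "read_genotype",
    "read_traits",
    "read_metadata",
    "align_inputs",
    "write_results",
    "fmt6",
    "DataError",
]

MISSING_TOKENS = {"", "na", "nan"}
_LIST_SEP = re.compile(r"[,;]")


class DataError(ValueError):
    """Fatal input-validation problem."""


def fmt6(x) -> str:
    """Canonical 6-significant-digit float formatting; NA for undefined."""
    if x is None:
        return "NA"
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    if isinstance(x, float) and np.isinf(x):
        return "inf" if x > 0 else "-inf"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{x:.6g}"


# ----------------------------------------------------------------------- types
@dataclass
class GenotypeMatrix:
    """Isolates x orthogroups counts, with optional per-cell gene-ID lists."""

    isolate_ids: list
    orthogroup_ids: list
    counts: np.ndarray  # (n_isolates, n_orthogroups) non-negative ints
    gene_lists: Optional[list] = None  # [i][j] -> list of gene ids

    def __post_init__(self):
        if len(set(self.isolate_ids)) != len(self.isolate_ids):
            raise DataError("duplicate isolate ids in genotype table")
        if len(set(self.orthogroup_ids)) != len(self.orthogroup_ids):
            raise DataError("duplicate orthogroup ids in genotype table")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.isolate_ids), len(self.orthogroup_ids)):
            raise DataError("genotype count matrix shape mismatch")
        if (self.counts < 0).any():
            raise DataError("negative counts in genotype table")
        if self.gene_lists is not None:
            for i in range(len(self.isolate_ids)):
                for j in range(len(self.orthogroup_ids)):
                    if len(self.gene_lists[i][j]) != self.counts[i, j]:
                        raise DataError(
                            f"gene list length != count at isolate "
                            f"{self.isolate_ids[i]!r}, orthogroup {self.orthogroup_ids[j]!r}"
                        )

    @property
    def present(self) -> np.ndarray:
        """Binarized view: present iff count >= 1."""
        return self.counts >= 1

    def subset_isolates(self, ids) -> "GenotypeMatrix":
        idx = [self.isolate_ids.index(i) for i in ids]
        gl = None
        if self.gene_lists is not None:
            gl = [self.gene_lists[i] for i in idx]
        return GenotypeMatrix(list(ids), list(self.orthogroup_ids), self.counts[idx], gl)


@dataclass
class TraitTable:
    """Isolates x traits; each trait binary ({0,1} plus missing) or numeric."""

    isolate_ids: list
    trait_ids: list
    values: np.ndarray  # float matrix, NaN = missing
    kinds: dict = field(default_factory=dict)  # trait_id -> "binary" | "numeric"

    def __post_init__(self):
        if len(set(self.isolate_ids)) != len(self.isolate_ids):
            raise DataError("duplicate isolate ids in trait table")
        if len(set(self.trait_ids)) != len(self.trait_ids):
            raise DataError("duplicate trait ids in trait table")
        self.values = np.asarray(self.values, dtype=float)

    def column(self, trait_id: str) -> np.ndarray:
        return self.values[:, self.trait_ids.index(trait_id)]

    def subset_isolates(self, ids) -> "TraitTable":
        idx = [self.isolate_ids.index(i) for i in ids]
        return TraitTable(list(ids), list(self.trait_ids), self.values[idx], dict(self.kinds))


@dataclass
class MetadataTable:
    entity_kind: str  # isolate | trait | orthogroup
    records: dict  # key -> {field: value}

    def get(self, key: str) -> dict:
        return self.records.get(key, {})


# --------------------------------------------------------------------- reading
def _sniff_delimiter(header_line: str, override: Optional[str]) -> str:
    if override:
        return override
    return "\t" if "\t" in header_line else ","


def _read_rect(path, delimiter=None):
    """Delimited file -> (header, rows); fatal on ragged rows with row number."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise DataError(f"empty file: {path}")
        delim = _sniff_delimiter(first, delimiter)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        rows = list(reader)
    header = rows[0]
    width = len(header)
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise DataError(f"ragged row {k} in {path}: {len(row)} fields, expected {width}")
    return header, rows[1:]


def _is_count_token(tok: str) -> bool:
    tok = tok.strip()
    if tok == "":
        return True
    try:
        v = float(tok)
    except ValueError:
        return False
    return v >= 0 and float(v).is_integer()


def read_genotype(
    path,
    format_hint: str = "auto",
    delimiter: Optional[str] = None,
    known_isolates: Optional[set] = None,
) -> GenotypeMatrix:
    """Read a gene-count or gene-list genotype table.

    Orientation is auto-detected: tables are accepted with orthogroups as rows
    (Roary/OrthoFinder convention) or as columns.  When ``known_isolates`` is
    given (e.g. the trait table's ids), the axis matching more of those ids is
    taken as the isolate axis; otherwise rows are assumed to be orthogroups.
    """
    if format_hint not in ("auto", "gene_count", "gene_list"):
        raise DataError(f"unknown genotype format hint: {format_hint}")
    header, rows = _read_rect(path, delimiter)
    row_ids = [r[0] for r in rows]
    col_ids = header[1:]
    cells = [r[1:] for r in rows]

    rows_are_isolates = False
    if known_isolates:
        hits_rows = len(set(row_ids) & set(known_isolates))
        hits_cols = len(set(col_ids) & set(known_isolates))
        rows_are_isolates = hits_rows > hits_cols
    if not rows_are_isolates:  # transpose: rows were orthogroups
        cells = [list(col) for col in zip(*cells)] if cells else []
        row_ids, col_ids = col_ids, row_ids
    isolate_ids, orthogroup_ids = row_ids, col_ids

    if format_hint == "auto":
        is_list = False
        for row in cells:
            for tok in row:
                if tok.strip().lower() in MISSING_TOKENS:
                    continue
                if not _is_count_token(tok):
                    is_list = True
                break  # first non-empty token per row decides quickly
            if is_list:
                break
        fmt = "gene_list" if is_list else "gene_count"
    else:
        fmt = format_hint

    n_i, n_o = len(isolate_ids), len(orthogroup_ids)
    counts = np.zeros((n_i, n_o), dtype=np.int64)
    gene_lists = None
    if fmt == "gene_list":
        gene_lists = [[[] for _ in range(n_o)] for _ in range(n_i)]
        for i in range(n_i):
            for j in range(n_o):
                tok = cells[i][j].strip()
                if tok.lower() in MISSING_TOKENS:
                    continue
                genes = [g.strip() for g in _LIST_SEP.split(tok) if g.strip()]
                gene_lists[i][j] = genes
                counts[i, j] = len(genes)
    else:
        for i in range(n_i):
            for j in range(n_o):
                tok = cells[i][j].strip()
                if tok.lower() in MISSING_TOKENS:
                    counts[i, j] = 0
                elif _is_count_token(tok):
                    counts[i, j] = int(float(tok))
                else:
                    raise DataError(
                        f"non-count token {tok!r} at isolate {isolate_ids[i]!r}, "
                        f"orthogroup {orthogroup_ids[j]!r}"
                    )
    g = GenotypeMatrix(isolate_ids, orthogroup_ids, counts, gene_lists)
    empty = [orthogroup_ids[j] for j in np.where(counts.sum(axis=0) == 0)[0]]
    if empty:
        warnings.warn(f"{len(empty)} all-zero orthogroup column(s) retained, e.g. {empty[:3]}")
    return g


def read_traits(path, delimiter: Optional[str] = None) -> TraitTable:
    """Read the trait table (isolates as rows, traits as columns).

    Per-trait kind is auto-detected: non-missing values within {0,1} -> binary,
    otherwise numeric.  Traits with fewer than 2 distinct non-missing values,
    or non-binary traits with fewer than 3 distinct values, carry no usable
    contrast and are excluded with a warning.
    """
    header, rows = _read_rect(path, delimiter)
    isolate_ids = [r[0] for r in rows]
    trait_ids = header[1:]
    if len(set(isolate_ids)) != len(isolate_ids):
        raise DataError("duplicate isolate ids in trait table")
    n_i = len(isolate_ids)
    values = np.full((n_i, len(trait_ids)), np.nan)
    for j, tid in enumerate(trait_ids):
        for i in range(n_i):
            tok = rows[i][j + 1].strip()
            if tok.lower() in MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise DataError(
                    f"non-numeric value {tok!r} at isolate {isolate_ids[i]!r}, trait {tid!r}"
                ) from None

    kinds = {}
    keep = []
    for j, tid in enumerate(trait_ids):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        distinct = np.unique(obs)
        if len(obs) == 0 or len(distinct) < 2:
            warnings.warn(f"trait {tid!r} excluded: fewer than 2 distinct values")
            continue
        if set(distinct).issubset({0.0, 1.0}):
            kinds[tid] = "binary"
        elif len(distinct) < 3:
            warnings.warn(f"trait {tid!r} excluded: 2 distinct non-binary values")
            continue
        else:
            kinds[tid] = "numeric"
        keep.append(j)
    return TraitTable(isolate_ids, [trait_ids[j] for j in keep], values[:, keep], kinds)


def read_metadata(path, entity_kind: str, delimiter: Optional[str] = None) -> MetadataTable:
    """TSV metadata, first column = identifier; unknown keys tolerated."""
    header, rows = _read_rect(path, delimiter or "\t")
    records = {}
    for row in rows:
        key = row[0]
        if key in records:
            raise DataError(f"duplicate metadata key {key!r} in {path}")
        records[key] = dict(zip(header[1:], row[1:]))
    return MetadataTable(entity_kind, records)


# ------------------------------------------------------------------- alignment
def align_inputs(g: GenotypeMatrix, t: TraitTable, tree=None):
    """Restrict genotype, traits and tree to shared isolates, canonical order.

    The shared-id order is sorted lexicographically so downstream output does
    not depend on input row order.  Fatal when fewer than 4 isolates remain.
    """
    shared = sorted(set(g.isolate_ids) & set(t.isolate_ids))
    if tree is not None:
        shared = sorted(set(shared) & set(tree.leaf_names))
    if len(shared) == 0:
        raise DataError(
            "no shared isolates between inputs; genotype has e.g. "
            f"{g.isolate_ids[:3]}, traits have e.g. {t.isolate_ids[:3]}"
        )
    if len(shared) < 4:
        raise DataError(f"only {len(shared)} shared isolate(s); at least 4 required")
    g2 = g.subset_isolates(shared)
    t2 = t.subset_isolates(shared)
    tree2 = tree.prune(shared) if tree is not None else None
    return g2, t2, tree2


# --------------------------------------------------------------------- writing
RESULT_COLUMNS = [
    "orthogroup",
    "tp",
    "fp",
    "fn",
    "tn",
    "odds_ratio",
    "sensitivity",
    "specificity",
    "p_fisher",
    "q_fisher",
    "p_best",
    "p_worst",
    "p_empirical",
]


def _safe_name(trait_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", trait_id)


def write_results(results, out_dir, genotype=None, tree=None, metadata=None) -> None:
    """Write per-trait result tables, the run summary, and the binarization log.

    ``results`` is an iterable of TraitResult.  Traits without at least one
    orthogroup passing the configured q-threshold are omitted from the summary
    and get no trait directory.  Per-trait data bundles (coverage matrix,
    values, tree) are delegated to :mod:`phylogwas.report` when a genotype is
    supplied.
    """
    from . import report as _report  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = sorted(results, key=lambda r: r.trait_id)

    summary_rows = []
    binlog_rows = []
    for res in results:
        b = res.binarization
        if b is not None:
            binlog_rows.append(
                [
                    res.trait_id,
                    b.method,
                    fmt6(b.means[0]),
                    fmt6(b.means[1]),
                    str(b.n_excluded),
                    b.outcome,
                ]
            )
        if not res.significant or not res.records:
            continue
        best = res.records[0]
        summary_rows.append(
            [
                res.trait_id,
                str(len(res.records)),
                best.orthogroup_id,
                fmt6(best.p_fisher),
                fmt6(best.q_fisher),
                fmt6(best.p_empirical),
            ]
        )
        tdir = out / "traits" / _safe_name(res.trait_id)
        tdir.mkdir(parents=True, exist_ok=True)
        with open(tdir / "result.tsv", "w") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for r in res.records:
                fh.write(
                    "\t".join(
                        [
                            r.orthogroup_id,
                            str(r.table.tp),
                            str(r.table.fp),
                            str(r.table.fn),
                            str(r.table.tn),
                            fmt6(r.odds_ratio),
                            fmt6(r.sensitivity),
                            fmt6(r.specificity),
                            fmt6(r.p_fisher),
                            fmt6(r.q_fisher),
                            fmt6(r.pairs.p_best if r.pairs else None),
                            fmt6(r.pairs.p_worst if r.pairs else None),
                            fmt6(r.p_empirical),
                        ]
                    )
                    + "\n"
                )
        if genotype is not None:
            _report.trait_bundle(res, genotype, tree, tdir, metadata=metadata)

    with open(out / "summary.tsv", "w") as fh:
        fh.write("trait\tn_candidates\tbest_orthogroup\tbest_p_fisher\tbest_q_fisher\tbest_p_empirical\n")
        for row in summary_rows:
            fh.write("\t".join(row) + "\n")
    with open(out / "binarization.tsv", "w") as fh:
        fh.write("trait\tmethod\tmean_low\tmean_high\tn_excluded\toutcome\n")
        for row in binlog_rows:
            fh.write("\t".join(row) + "\n")


def write_genotype(g: GenotypeMatrix, path, orientation: str = "orthogroups_rows") -> None:
    """Write a genotype table (round-trips counts and gene lists exactly)."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        if orientation == "orthogroups_rows":
            w.writerow(["Orthogroup"] + list(g.isolate_ids))
            for j, og in enumerate(g.orthogroup_ids):
                row = [og]
                for i in range(len(g.isolate_ids)):
                    if g.gene_lists is not None:
                        row.append(", ".join(g.gene_lists[i][j]))
                    else:
                        row.append(str(g.counts[i, j]))
                w.writerow(row)
        else:
            w.writerow(["Isolate"] + list(g.orthogroup_ids))
            for i, iso in enumerate(g.isolate_ids):
                row = [iso]
                for j in range(len(g.orthogroup_ids)):
                    if g.gene_lists is not None:
                        row.append(", ".join(g.gene_lists[i][j]))
                    else:
                        row.append(str(g.counts[i, j]))
                w.writerow(row)
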