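"""Per (trait, orthogroup) scoring and multiple-testing correction.

Fisher's exact test scores the 2x2 table of gene presence vs trait state over
the isolates with a defined (non-missing, non-abstained) trait.  The two-sided
p-value follows the probability-mass definition — the sum over all tables with
the observed margins whose probability does not exceed the observed table's —
and is computed with exact integer arithmetic, so it can be checked against an
independent exact oracle to machine precision.

Fisher q-values gate the expensive phylogeny-aware step: only orthogroups
passing the configured ``method:alpha`` threshold proceed to the
contrasting-pairs analysis and the label-switching permutation test (a
``permute_all`` switch removes the gate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import pairs as _pairs

__all__ = [
    "ContingencyTable",
    "AssociationRecord",
    "TraitResult",
    "AssocConfig",
    "fisher_exact",
    "descriptive_stats",
    "correct_pvalues",
    "contingency",
    "trait_fisher_scan",
    "analyze_trait",
    "parse_multiple_testing",
]

P_FLOOR = 1e-300  # clamp before -log10 transforms in reports


@dataclass(frozen=True)
class ContingencyTable:
    tp: int  # gene+ trait+
    fp: int  # gene+ trait-
    fn: int  # gene- trait+
    tn: int  # gene- trait-

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class AssociationRecord:
    trait_id: str
    orthogroup_id: str
    table: ContingencyTable
    odds_ratio: float
    sensitivity: float
    specificity: float
    p_fisher: float
    q_fisher: float
    pairs: Optional[_pairs.PairSummary] = None
    p_empirical: Optional[float] = None


@dataclass
class TraitResult:
    trait_id: str
    binarization: object = None  # BinarizationResult | None
    records: list = field(default_factory=list)  # sorted by p_fisher asc
    significant: bool = False


@dataclass
class AssocConfig:
    method: str = "fdr_bh"  # native | bonferroni | fdr_bh
    alpha: float = 0.1
    trait_wise: bool = True
    n_permut: int = 1000
    max_genes: Optional[int] = 50
    permute_all: bool = False
    master_seed: int = 42


def parse_multiple_testing(spec: str):
    """Parse a ``method:alpha`` string such as ``fdr_bh:0.1``."""
    try:
        method, alpha_s = spec.split(":")
        alpha = float(alpha_s)
    except ValueError:
        raise ValueError(f"multiple-testing spec must be method:alpha, got {spec!r}") from None
    if method not in ("native", "bonferroni", "fdr_bh"):
        raise ValueError(f"unknown multiple-testing method {method!r}")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return method, alpha


# --------------------------------------------------------------------- fisher
@lru_cache(maxsize=1_000_000)
def _fisher_exact_cached(tp: int, fp: int, fn: int, tn: int) -> float:
    r1 = tp + fp
    c1 = tp + fn
    n = tp + fp + fn + tn
    r2 = n - r1
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # unnormalized table weights share the denominator C(n, c1)
    w_obs = math.comb(r1, tp) * math.comb(r2, c1 - tp)
    num = 0
    den = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        den += w
        if w <= w_obs:  # exact integer comparison: no tie tolerance needed
            num += w
    # exact rational -> correctly rounded float
    return num / den


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (probability-mass definition), exact arithmetic.

    A zero margin means no contrast and returns p = 1.
    """
    return _fisher_exact_cached(table.tp, table.fp, table.fn, table.tn)


def descriptive_stats(table: ContingencyTable):
    """(odds_ratio, sensitivity, specificity); NaN where a margin is empty."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if tp * tn == 0 and fp * fn == 0:
        odds = float("nan")
    elif fp * fn == 0:
        odds = float("inf")
    else:
        odds = (tp * tn) / (fp * fn)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return odds, sens, spec


def correct_pvalues(p, method: str) -> np.ndarray:
    """native (identity), bonferroni, or Benjamini-Hochberg step-up q-values.

    The pool is whatever vector the caller passes: per-trait for trait-wise
    correction, all traits x orthogroups pooled for global correction.
    """
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p.copy()
    if method == "native":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "fdr_bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction method {method!r}")


# ------------------------------------------------------------------- analysis
def contingency(gene_present: np.ndarray, trait: np.ndarray) -> ContingencyTable:
    """2x2 counts over isolates with non-missing trait."""
    mask = ~np.isnan(trait)
    g = np.asarray(gene_present, dtype=bool)[mask]
    t = np.asarray(trait)[mask].astype(bool)
    tp = int(np.sum(g & t))
    fp = int(np.sum(g & ~t))
    fn = int(np.sum(~g & t))
    tn = int(np.sum(~g & ~t))
    return ContingencyTable(tp, fp, fn, tn)


def trait_fisher_scan(trait: np.ndarray, genotype):
    """Contingency tables and Fisher p for every orthogroup of one trait.

    ``trait`` is a float vector over the aligned isolates with NaN for
    missing/abstained; ``genotype`` is a GenotypeMatrix.  Vectorized counts,
    cached exact Fisher per distinct table.
    """
    trait = np.asarray(trait, dtype=float)
    mask = ~np.isnan(trait)
    G = genotype.present[mask]
    t = trait[mask].astype(bool)
    tp = (G & t[:, None]).sum(axis=0)
    fp = (G & ~t[:, None]).sum(axis=0)
    fn = ((~G) & t[:, None]).sum(axis=0)
    tn = ((~G) & ~t[:, None]).sum(axis=0)
    tables = [ContingencyTable(int(a), int(b), int(c), int(d)) for a, b, c, d in zip(tp, fp, fn, tn)]
    p = np.array([fisher_exact(tb) for tb in tables])
    return tables, p


def analyze_trait(
    trait_id: str,
    trait: np.ndarray,
    genotype,
    tree,
    config: AssocConfig,
    cache=None,
    binarization=None,
    q_override: Optional[np.ndarray] = None,
) -> TraitResult:
    """Full association analysis for one (already binarized) trait.

    Fisher scan over all orthogroups, multiple-testing correction (trait-wise
    by default; pass ``q_override`` for globally pooled q-values), q-threshold
    gating, then contrasting pairs + permutation test for surviving
    orthogroups.  Records are sorted by ascending p_fisher (ties by
    orthogroup id) and truncated to ``max_genes``.
    """
    tables, p = trait_fisher_scan(trait, genotype)
    if q_override is not None:
        q = np.asarray(q_override, dtype=float)
    else:
        q = correct_pvalues(p, config.method)

    order = sorted(range(len(p)), key=lambda j: (p[j], genotype.orthogroup_ids[j]))
    passing = [j for j in order if q[j] <= config.alpha]
    selected = order if config.permute_all else passing
    significant = len(passing) > 0

    if config.max_genes is not None:
        selected = selected[: config.max_genes]

    records = []
    trait_f = np.asarray(trait, dtype=float)
    present = genotype.present
    mask = ~np.isnan(trait_f)
    sub_names = [genotype.isolate_ids[i] for i in range(len(mask)) if mask[i]]
    if len(sub_names) < 2:  # no contrast left after abstentions
        selected = []
        sub_tree = tree
    else:
        sub_tree = tree.prune(sub_names) if not mask.all() else tree
    name_to_i = {n: i for i, n in enumerate(genotype.isolate_ids)}
    order_idx = [name_to_i[n] for n in sub_tree.leaf_names]
    sub_trait = trait_f[order_idx].astype(np.int8)
    for j in selected:
        gene = present[:, j].astype(np.int8)
        summary = _pairs.max_contrasting_pairs(
            tree, _pairs.LeafLabeling.from_vectors(gene, trait_f)
        )
        sub_gene = gene[order_idx]
        if summary.max_pairs == 0:
            p_emp = 1.0
        else:
            gene_key = _pairs.canonical_gene_key(sub_tree, sub_gene)
            seed = _pairs.derive_seed(
                config.master_seed, gene_key, int(sub_trait.sum()), config.n_permut
            )
            null = _pairs.permutation_null(
                sub_tree, sub_gene, int(sub_trait.sum()), config.n_permut, seed, cache=cache
            )
            exceed = int(np.sum(null >= summary.best_supporting))
            p_emp = (1 + exceed) / (1 + config.n_permut)
        odds, sens, spec = descriptive_stats(tables[j])
        records.append(
            AssociationRecord(
                trait_id=trait_id,
                orthogroup_id=genotype.orthogroup_ids[j],
                table=tables[j],
                odds_ratio=odds,
                sensitivity=sens,
                specificity=spec,
                p_fisher=float(p[j]),
                q_fisher=float(q[j]),
                pairs=summary,
                p_empirical=p_emp,
            )
        )
    return TraitResult(trait_id, binarization=binarization, records=records, significant=significant)
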