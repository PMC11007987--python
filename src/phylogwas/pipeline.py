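"""End-to-end run orchestration: read -> align -> binarize -> associate -> report.

Traits are independent work units.  A single master seed governs every
stochastic stage; per-unit seeds are derived by stable hashing so results are
byte-identical regardless of worker count, processing order, or which other
traits are present in the run.
"""

from __future__ import annotations

import logging
import multiprocessing as mp
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import association as assoc
from . import binarize as binz
from . import data_io
from . import pairs as prs
from . import phylo
from . import report as rpt

__all__ = ["RunConfig", "run", "ConfigError"]

log = logging.getLogger("phylogwas")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    genotype: str
    traits: str
    out_dir: str
    tree: Optional[str] = None
    isolate_metadata: Optional[str] = None
    trait_metadata: Optional[str] = None
    orthogroup_metadata: Optional[str] = None
    genotype_format: str = "auto"
    binarize_method: str = "gmm"
    gmm_cutoff: float = binz.DEFAULT_POSTERIOR_CUTOFF
    gmm_on_failure: str = "kmeans"
    multiple_testing: str = "fdr_bh:0.1"
    trait_wise: bool = True
    n_permut: int = 1000
    max_genes: Optional[int] = 50
    permute_all: bool = False
    n_cpus: int = 1
    seed: int = 42
    cache_path: Optional[str] = None  # None -> <out_dir>/permcache.sqlite
    no_cache: bool = False
    gene_url: Optional[str] = None
    orthogroup_url: Optional[str] = None

    def validate(self):
        method, alpha = assoc.parse_multiple_testing(self.multiple_testing)
        if self.binarize_method not in ("kmeans", "gmm"):
            raise ConfigError(f"unknown binarization method {self.binarize_method!r}")
        if self.gmm_on_failure not in ("skip", "kmeans"):
            raise ConfigError(f"unknown gmm failure policy {self.gmm_on_failure!r}")
        if not (0 < self.gmm_cutoff < 1):
            raise ConfigError(f"gmm cutoff must be in (0,1), got {self.gmm_cutoff}")
        if self.n_permut < 100:
            raise ConfigError("n_permut must be >= 100")
        if self.n_cpus < 1:
            raise ConfigError("n_cpus must be >= 1")
        for path_attr in ("genotype", "traits"):
            p = getattr(self, path_attr)
            if not Path(p).exists():
                raise ConfigError(f"{path_attr} file not found: {p}")
        if self.tree is not None and not Path(self.tree).exists():
            raise ConfigError(f"tree file not found: {self.tree}")
        return method, alpha

    def echo_rows(self):
        for key in sorted(self.__dataclass_fields__):
            yield key, str(getattr(self, key))


# ------------------------------------------------------------------ worker fns
_G = {}  # worker globals (fork-inherited)


def _init_worker(genotype, tree, config, assoc_cfg, cache_path):
    _G["genotype"] = genotype
    _G["tree"] = tree
    _G["config"] = config
    _G["assoc_cfg"] = assoc_cfg
    _G["cache"] = prs.PermCache(cache_path) if cache_path else None


def _binarize_stage(item):
    """(trait_id, column, kind) -> (trait_id, binarization|None, vector|None, p, elapsed)."""
    trait_id, col, kind = item
    cfg: RunConfig = _G["config"]
    t0 = time.perf_counter()
    binarization = None
    if kind == "numeric":
        seed = prs.derive_seed(cfg.seed, "binarize", trait_id)
        try:
            if cfg.binarize_method == "kmeans":
                binarization = binz.binarize_kmeans(col, trait_id=trait_id)
            else:
                binarization = binz.binarize_gmm(
                    col,
                    posterior_cutoff=cfg.gmm_cutoff,
                    on_failure=cfg.gmm_on_failure,
                    seed=seed,
                    trait_id=trait_id,
                )
        except binz.BinarizationError as exc:
            stub = binz.BinarizationResult(
                trait_id,
                cfg.binarize_method,
                np.full(len(col), binz.MISSING, dtype=np.int8),
                (float("nan"), float("nan")),
                None,
                0,
                outcome=f"skipped: {exc}",
                raw_values=np.asarray(col, dtype=float),
            )
            return trait_id, stub, None, None, time.perf_counter() - t0
        vector = binarization.trait_vector()
    else:
        vector = np.asarray(col, dtype=float)
    _, p = assoc.trait_fisher_scan(vector, _G["genotype"])
    return trait_id, binarization, vector, p, time.perf_counter() - t0


def _analyze_stage(item):
    trait_id, vector, binarization, q_override = item
    t0 = time.perf_counter()
    res = assoc.analyze_trait(
        trait_id,
        vector,
        _G["genotype"],
        _G["tree"],
        _G["assoc_cfg"],
        cache=_G["cache"],
        binarization=binarization,
        q_override=q_override,
    )
    return res, time.perf_counter() - t0


def _map(func, items, n_cpus):
    if n_cpus <= 1 or len(items) <= 1:
        return [func(it) for it in items]
    ctx = mp.get_context("fork")
    with ctx.Pool(
        n_cpus,
        initializer=_init_worker,
        initargs=(_G["genotype"], _G["tree"], _G["config"], _G["assoc_cfg"], _G["cache_path"]),
    ) as pool:
        return pool.map(func, items)


# ------------------------------------------------------------------------ run
def run(config: RunConfig) -> int:
    """Execute the full pipeline; returns the number of significant traits."""
    method, alpha = config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        with open(out / "config.tsv", "w") as fh:
            fh.write("parameter\tvalue\n")
            for key, value in config.echo_rows():
                fh.write(f"{key}\t{value}\n")

        traits = data_io.read_traits(config.traits)
        genotype = data_io.read_genotype(
            config.genotype,
            format_hint=config.genotype_format,
            known_isolates=set(traits.isolate_ids),
        )
        if config.tree:
            tree = phylo.parse_newick(Path(config.tree).read_text())
        else:
            log.info("no tree supplied; inferring UPGMA tree from genotype")
            tree = phylo.infer_tree(genotype)
        genotype, traits, tree = data_io.align_inputs(genotype, traits, tree)
        log.info(
            "aligned inputs: %d isolates, %d orthogroups, %d traits",
            len(genotype.isolate_ids),
            len(genotype.orthogroup_ids),
            len(traits.trait_ids),
        )

        metadata = {}
        for kind, path in (
            ("isolate", config.isolate_metadata),
            ("trait", config.trait_metadata),
            ("orthogroup", config.orthogroup_metadata),
        ):
            if path:
                metadata[kind] = data_io.read_metadata(path, kind)

        cache_path = None
        if not config.no_cache:
            cache_path = config.cache_path or str(out / "permcache.sqlite")
        assoc_cfg = assoc.AssocConfig(
            method=method,
            alpha=alpha,
            trait_wise=config.trait_wise,
            n_permut=config.n_permut,
            max_genes=config.max_genes,
            permute_all=config.permute_all,
            master_seed=config.seed,
        )
        _init_worker(genotype, tree, config, assoc_cfg, cache_path)
        _G["cache_path"] = cache_path

        trait_order = sorted(traits.trait_ids)
        stage1_items = [(tid, traits.column(tid), traits.kinds[tid]) for tid in trait_order]
        stage1 = _map(_binarize_stage, stage1_items, config.n_cpus)

        skipped_results = []
        analyzable = []  # (trait_id, vector, binarization, p)
        for trait_id, binarization, vector, p, elapsed in stage1:
            log.info("binarize+scan %s: %.3fs", trait_id, elapsed)
            if vector is None:
                log.warning("trait %s skipped: %s", trait_id, binarization.outcome)
                skipped_results.append(
                    assoc.TraitResult(trait_id, binarization=binarization, significant=False)
                )
            else:
                analyzable.append((trait_id, vector, binarization, p))

        if config.trait_wise:
            stage2_items = [(tid, vec, b, None) for tid, vec, b, _ in analyzable]
        else:  # global correction: pool Fisher p across all traits and orthogroups
            pooled = np.concatenate([p for *_, p in analyzable]) if analyzable else np.array([])
            q_all = assoc.correct_pvalues(pooled, method)
            stage2_items = []
            ofs = 0
            for tid, vec, b, p in analyzable:
                stage2_items.append((tid, vec, b, q_all[ofs : ofs + len(p)]))
                ofs += len(p)

        stage2 = _map(_analyze_stage, stage2_items, config.n_cpus)
        results = skipped_results + [res for res, _ in stage2]
        for res, elapsed in stage2:
            log.info(
                "analyze %s: %.3fs, %d candidate(s), significant=%s",
                res.trait_id,
                elapsed,
                len(res.records),
                res.significant,
            )

        data_io.write_results(results, out, genotype=genotype, tree=tree, metadata=metadata)

        significant = {r.trait_id: r for r in results if r.significant and r.records}
        if len(significant) >= 2:
            tvals, kinds, bviews = {}, {}, {}
            for tid, res in significant.items():
                tvals[tid] = traits.column(tid)
                kinds[tid] = traits.kinds[tid]
                if res.binarization is not None:
                    bviews[tid] = res.binarization.trait_vector()
            ids, D = rpt.trait_distances(tvals, kinds, binarized=bviews)
            rpt.write_overview(ids, D, significant, out)
        log.info("run complete: %d significant trait(s)", len(significant))
        return len(significant)
    finally:
        cache = _G.get("cache")
        if cache is not None:
            cache.close()
            _G["cache"] = None
        log.removeHandler(handler)
        handler.close()
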