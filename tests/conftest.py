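import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_dataset(tmp_path):
    """A tiny on-disk dataset: genotype, traits (binary + numeric), tree."""
    from phylogwas import simulate as sim
    from phylogwas.data_io import write_genotype

    tree, g, causal = sim.evolve_pangenome(16, n_genes=25, seed=99)
    pheno = sim.simulate_phenotype(g, causal, 3.0, seed=7)
    gpath = tmp_path / "genotype.tsv"
    write_genotype(g, gpath)
    tpath = tmp_path / "traits.tsv"
    with open(tpath, "w") as fh:
        fh.write("isolate\tbin_causal\tnum_pheno\n")
        for iso, present, value in zip(g.isolate_ids, g.present[:, causal], pheno):
            fh.write(f"{iso}\t{int(present)}\t{value:.6f}\n")
    nwk = tmp_path / "tree.nwk"
    nwk.write_text(tree.to_newick() + "\n")
    return {
        "genotype": gpath,
        "traits": tpath,
        "tree": nwk,
        "causal": causal,
        "tmp": tmp_path,
    }
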