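import pytest

from ficcseq.pipeline import run_pipeline
from ficcseq.simdata import Reference, SimConfig, build_reference, simulate_reads


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_trna_genes=6, n_other_genes=2, reads_per_gene=400,
                     reads_per_other_gene=100, seed=11)


@pytest.fixture(scope="session")
def small_ref(small_cfg) -> Reference:
    return build_reference(small_cfg)


@pytest.fixture(scope="session")
def small_reads(small_ref, small_cfg):
    return simulate_reads(small_ref, small_cfg)


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory):
    """One shared end-to-end run on a mid-sized simulation."""
    outdir = tmp_path_factory.mktemp("pipe")
    config = {
        "seed": 5,
        "simulate": {"n_trna_genes": 10, "n_other_genes": 2,
                     "reads_per_gene": 600, "reads_per_other_gene": 150},
    }
    return run_pipeline(config, str(outdir)), str(outdir)
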