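import numpy as np
import pytest

from triagene import PipelineConfig, SyntheticConfig, run_pipeline, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study with three planted colocalized genes."""
    cfg = SyntheticConfig(n_samples=1500, n_snps=1000, n_genes=100,
                          n_true_genes=3, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_run(small_study, tmp_path_factory):
    """The small study written to disk and run through the full pipeline."""
    root = tmp_path_factory.mktemp("small_run")
    paths = small_study.write(root / "inputs")
    config = PipelineConfig(
        gwas=str(paths["gwas"]),
        eqtl_discovery=str(paths["eqtl_discovery"]),
        eqtl_replication=str(paths["eqtl_replication"]),
        annotation=str(paths["annotation"]),
        dosage=str(paths["dosage"]),
        gene_sets=str(paths["gene_sets"]),
        expression=str(paths["expression"]),
        outdir=str(root / "out"),
        gba_n_perm=2000, n_trials=5000, seed=23,
    )
    report = run_pipeline(config)
    return {"study": small_study, "config": config, "report": report,
            "root": root, "paths": paths}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
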