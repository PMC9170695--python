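import numpy as np
import pytest

from chromdyn.pipeline import RunConfig, run_all
from chromdyn.simulate import SyntheticConfig, TruthTables


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One full-scale pipeline run on the default synthetic conditions.

    Shared by the recovery tests; default config = the study conditions
    (4 stages, 2000 genes, 10x rate ratio, 20% activated share, six
    archetypes, 80% motif planting, 0.5 footprint dip).
    """
    outdir = tmp_path_factory.mktemp("full_run")
    config = RunConfig(outdir=str(outdir), seed=1, synthetic=SyntheticConfig(seed=1))
    report = run_all(config)
    truth = TruthTables.from_json(outdir / "sim" / "truth.json")
    return {"outdir": outdir, "report": report, "truth": truth, "config": config}


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale synthetic conditions for fast structural tests."""
    return SyntheticConfig(
        seed=7,
        n_chroms=2,
        chrom_length=600_000,
        n_genes=40,
        n_intergenic_peaks=120,
        gene_spacing=12_000,
    )
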