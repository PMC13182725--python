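import glob
import os

import pytest

from editome.pipeline import PipelineConfig, run_pipeline
from editome.simulate import SimulationConfig, simulate_dataset


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    base = dict(n_true_sites=40, n_het_snps=20, n_hom_snps=10,
                n_contaminant_sites=9, chrom_length=30_000,
                coverage_mean=30.0, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact simulated dataset shared across tests."""
    out = tmp_path_factory.mktemp("smallsim")
    return simulate_dataset(small_config(), str(out))


def pipeline_config_for(ds, out_dir: str, **overrides) -> PipelineConfig:
    base = dict(
        fasta=ds.paths["fasta"], gtf=ds.paths["gtf"], sam_paths=ds.paths["sams"],
        design=ds.paths["design"], counts=ds.paths["counts"],
        dbsnp_vcf=ds.paths["germline_vcf"], repeat_bed=ds.paths["repeats_bed"],
        out_dir=out_dir, seed=ds.config.seed)
    base.update(overrides)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    """The full pipeline executed once on the shared small dataset."""
    out = tmp_path_factory.mktemp("smallrun")
    cfg = pipeline_config_for(small_dataset, str(out))
    report, paths = run_pipeline(cfg)
    return small_dataset, cfg, report, paths
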