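"""Shared locations and the fixture definition used by the analysis scripts."""

import os

from editome.pipeline import PipelineConfig
from editome.simulate import SimulationConfig

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch")
RESULTS = os.path.join(ROOT, "results")
SEED = 1

STANDARD_SIM_DIR = os.path.join(SCRATCH, "standard", "sim")
STANDARD_OUT_DIR = os.path.join(SCRATCH, "standard", "out")


def standard_config(seed: int = SEED) -> SimulationConfig:
    """Standard fixture: 2 x 100 kb chromosomes, 6 samples in 2 groups,
    200 true sites, 100 het + 50 hom SNPs, 30 contaminants, 50x, 0.1% error."""
    return SimulationConfig(seed=seed)


def pipeline_config(ds, out_dir: str) -> PipelineConfig:
    return PipelineConfig(
        fasta=ds.paths["fasta"], gtf=ds.paths["gtf"], sam_paths=ds.paths["sams"],
        design=ds.paths["design"], counts=ds.paths["counts"],
        dbsnp_vcf=ds.paths["germline_vcf"], repeat_bed=ds.paths["repeats_bed"],
        out_dir=out_dir, seed=ds.config.seed)


def ensure_dirs():
    os.makedirs(SCRATCH, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
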