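"""End-to-end driver: simulated or user-supplied inputs to report tables.

A single :class:`PipelineConfig` (JSON round-trippable) drives discovery,
quantification, annotation, differential testing, correlation and summary
stages; every output table is tab-separated with a header line and a
'#'-prefixed provenance comment carrying the config hash and seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from . import discovery as disc
from . import quantify as qt
from . import stats as st
from .annotation import AnnotationIndex, read_gtf
from .discovery import DiscoveryThresholds

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class StatSettings:
    alpha: float = 0.05
    fdr_method: str = "bh"
    glm_family: str = "binomial"
    min_corr_pairs: int = 5
    pca_components: int = 0  # 0 = all


@dataclass
class PipelineConfig:
    fasta: str
    gtf: str
    sam_paths: list[str]
    design: str                       # TSV: sample, group[, adar_activity]
    counts: str | None = None         # TSV: gene_id, exonic_length, samples...
    dbsnp_vcf: str | None = None
    whitelist_bed: str | None = None
    repeat_bed: str | None = None
    mito_chrom: str = "chrM"
    out_dir: str = "editome_out"
    thresholds: DiscoveryThresholds = field(default_factory=DiscoveryThresholds)
    stats: StatSettings = field(default_factory=StatSettings)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["thresholds"] = DiscoveryThresholds(**{
            k: tuple(v) if k == "het_band" else v
            for k, v in d.get("thresholds", {}).items()})
        d["stats"] = StatSettings(**d.get("stats", {}))
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # identifies the analysis, not its destination
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    stage_counts: dict[str, int]
    attrition: dict[str, int]
    dropped_ambiguous: int

    def telescopes(self) -> bool:
        """Each stage's output must feed the next stage unchanged."""
        sc = self.stage_counts
        return (sc["sites_high_confidence"] == sc["sites_quantified"]
                == sc["sites_annotated"])


def _read_bed_positions(path: str) -> set[tuple[str, int]]:
    out = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            for pos in range(int(f[1]) + 1, int(f[2]) + 1):
                out.add((f[0], pos))
    return out


def _read_bed_intervals(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def _read_vcf_positions(path: str) -> set[tuple[str, int]]:
    out = set()
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            out.add((rec.chrom, rec.pos))
    return out


def _provenance(config: PipelineConfig) -> str:
    return f"# editome config_hash={config.config_hash()} seed={config.seed}\n"


def _write_table(df: pd.DataFrame, path: str, config: PipelineConfig,
                 index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: PipelineConfig):
    """Execute call -> filter -> quantify -> annotate -> diff -> correlate ->
    summarize; returns (RunReport, dict of output paths)."""
    os.makedirs(config.out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    try:
        fa = pyfaidx.Fasta(config.fasta)
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
    except Exception as exc:
        raise PipelineError(f"stage=load_genome file={config.fasta}: {exc}") from exc
    try:
        genes = read_gtf(config.gtf)
    except Exception as exc:
        raise PipelineError(f"stage=load_annotation file={config.gtf}: {exc}") from exc
    annotation = AnnotationIndex(genes)
    design = pd.read_csv(config.design, sep="\t")
    samples = list(design["sample"])
    groups = list(design["group"])

    dbsnp = _read_vcf_positions(config.dbsnp_vcf) if config.dbsnp_vcf else None
    whitelist = _read_bed_positions(config.whitelist_bed) if config.whitelist_bed else None
    repeats = _read_bed_intervals(config.repeat_bed) if config.repeat_bed else None

    try:
        result = disc.discover_editing_sites(
            config.sam_paths, sequences, annotation, config.thresholds,
            mito_chrom=config.mito_chrom, repeat_intervals=repeats,
            dbsnp=dbsnp, whitelist=whitelist)
    except disc.ReferenceMismatchError as exc:
        raise PipelineError(f"stage=discovery: {exc}") from exc

    th = config.thresholds
    sites = result.sites

    # candidate calls VCF
    paths["candidates_vcf"] = os.path.join(config.out_dir, "candidates.vcf")
    with open(paths["candidates_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##editome_config_hash={config.config_hash()}\n")
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Pooled alt depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in result.candidates:
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t"
                     f"DP={c.depth};AD={c.alt_depth}\n")

    # final sites BED + per-sample level TSV
    paths["sites_bed"] = os.path.join(config.out_dir, "sites.bed")
    with open(paths["sites_bed"], "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.gene_id or '.'}\t0\t{s.strand}\n")

    matrix = qt.EditingMatrix.from_sites(sites, samples, groups, th.min_depth)
    paths["levels"] = os.path.join(config.out_dir, "levels.tsv")
    _write_table(matrix.levels, paths["levels"], config, index_label="site")
    paths["coverage"] = os.path.join(config.out_dir, "coverage.tsv")
    _write_table(matrix.total if matrix.total is not None else matrix.mask,
                 paths["coverage"], config, index_label="site")

    paths["attrition"] = os.path.join(config.out_dir, "attrition.tsv")
    _write_table(pd.DataFrame(sorted(result.attrition.items()),
                              columns=["stage_or_rule", "count"]),
                 paths["attrition"], config)

    # expression
    tpm = None
    if config.counts:
        ct = pd.read_csv(config.counts, sep="\t", index_col=0)
        lengths = ct["exonic_length"]
        counts = ct[samples]
        tpm = qt.compute_tpm(counts, lengths)
        paths["tpm"] = os.path.join(config.out_dir, "tpm.tsv")
        _write_table(tpm, paths["tpm"], config, index_label="gene_id")

    # annotation
    records = [qt.annotate_site(s.chrom, s.pos, s.strand, annotation, sequences)
               for s in sites]
    ann_df = pd.DataFrame([{
        "site": f"{r.chrom}:{r.pos}:{r.strand}", "gene_id": r.gene_id or ".",
        "region": r.region, "ref_codon": r.ref_codon or ".",
        "alt_codon": r.alt_codon or ".", "ref_aa": r.ref_aa or ".",
        "alt_aa": r.alt_aa or ".", "consequence": r.consequence or "."}
        for r in records],
        columns=["site", "gene_id", "region", "ref_codon", "alt_codon",
                 "ref_aa", "alt_aa", "consequence"])
    paths["annotation"] = os.path.join(config.out_dir, "annotation.tsv")
    _write_table(ann_df, paths["annotation"], config)

    if records:
        dist = qt.annotation_distribution(records)
        dist_df = pd.DataFrame(sorted(dist.items()), columns=["region", "fraction"])
    else:
        dist_df = pd.DataFrame(columns=["region", "fraction"])
    paths["region_distribution"] = os.path.join(config.out_dir, "region_distribution.tsv")
    _write_table(dist_df, paths["region_distribution"], config)

    # differential editing
    rows = []
    garr = np.asarray(groups)
    if len(set(groups)) >= 2:
        for s in sites:
            r = st.lrt_differential(s.edited, s.total, garr, th.min_depth,
                                    site=f"{s.chrom}:{s.pos}:{s.strand}")
            rows.append(r)
    pvals = [r.p_value for r in rows]
    qvals = st.adjust_fdr(pvals) if rows else np.array([])
    diff_df = pd.DataFrame([{
        "site": r.site, "lrt_statistic": r.lrt_statistic, "df": r.df,
        "p_value": r.p_value, "q_value": q,
        **{f"mean_{g}": m for g, m in r.group_means.items()}}
        for r, q in zip(rows, qvals)],
        columns=(["site", "lrt_statistic", "df", "p_value", "q_value"]
                 + [f"mean_{g}" for g in dict.fromkeys(groups)]))
    paths["differential"] = os.path.join(config.out_dir, "differential.tsv")
    _write_table(diff_df, paths["differential"], config)

    # editing-expression correlation
    corr_rows = []
    if tpm is not None:
        site_gene = {f"{s.chrom}:{s.pos}:{s.strand}": s.gene_id
                     for s in sites if s.gene_id}
        for c in st.editing_expression_correlation(
                matrix, tpm, site_gene, config.stats.min_corr_pairs,
                config.stats.alpha):
            corr_rows.append({"site": c.site, "gene_id": c.gene_id, "rho": c.rho,
                              "p_value": c.p_value, "n_pairs": c.n_pairs,
                              "significant": c.significant})
    corr_df = pd.DataFrame(corr_rows, columns=["site", "gene_id", "rho",
                                               "p_value", "n_pairs", "significant"])
    paths["correlation"] = os.path.join(config.out_dir, "correlation.tsv")
    _write_table(corr_df, paths["correlation"], config)

    # summaries: overall editing, PCA
    overall = st.overall_editing_level(matrix) if sites else pd.DataFrame(
        columns=["mean_level", "weighted_level"])
    paths["overall_editing"] = os.path.join(config.out_dir, "overall_editing.tsv")
    _write_table(overall, paths["overall_editing"], config, index_label="sample")

    if len(sites) >= 2 and len(samples) >= 2:
        pca = st.pca_editing(matrix, config.stats.pca_components or None)
        paths["pca_scores"] = os.path.join(config.out_dir, "pca_scores.tsv")
        _write_table(pca.scores, paths["pca_scores"], config, index_label="sample")
        paths["pca_variance"] = os.path.join(config.out_dir, "pca_variance.tsv")
        _write_table(pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(pca.variance_fraction.size)],
            "variance_fraction": pca.variance_fraction}),
            paths["pca_variance"], config)

    report = RunReport(
        config.config_hash(), config.seed,
        {
            "candidates": result.attrition["candidates"],
            "a_to_i": result.attrition["a_to_i"],
            "sites_filtered_pass": result.attrition["filtered_pass"],
            "sites_high_confidence": len(sites),
            "sites_quantified": int(matrix.levels.shape[0]),
            "sites_annotated": len(records),
            "differential_tested": len(rows),
        },
        result.attrition, result.dropped_ambiguous)
    paths["report"] = os.path.join(config.out_dir, "report.json")
    with open(paths["report"], "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report, paths


def demo_end_to_end(seed: int = 0, out_dir: str | None = None):
    """Simulate a compact fixture, run the full pipeline on it, and assert
    the headline recovery properties. Returns (report, paths, summary)."""
    from .simulate import SimulationConfig, simulate_dataset

    tmp_ctx = None
    if out_dir is None:
        tmp_ctx = tempfile.TemporaryDirectory(prefix="editome_demo_")
        out_dir = tmp_ctx.name
    try:
        sim_cfg = SimulationConfig(
            n_true_sites=80, n_het_snps=40, n_hom_snps=20, n_contaminant_sites=12,
            chrom_length=40_000, coverage_mean=50.0, seed=seed)
        ds = simulate_dataset(sim_cfg, os.path.join(out_dir, "sim"))
        cfg = PipelineConfig(
            fasta=ds.paths["fasta"], gtf=ds.paths["gtf"], sam_paths=ds.paths["sams"],
            design=ds.paths["design"], counts=ds.paths["counts"],
            dbsnp_vcf=ds.paths["germline_vcf"], repeat_bed=ds.paths["repeats_bed"],
            out_dir=os.path.join(out_dir, "out"), seed=seed)
        report, paths = run_pipeline(cfg)

        found = {(s[0], int(s[1])) for s in
                 (line.split("\t") for line in open(paths["sites_bed"]))}
        found = {(c, p + 1) for c, p in found}
        truth = {(s.chrom, s.pos) for s in ds.truth.true_sites}
        germ = {(v.chrom, v.pos) for v in ds.truth.germline_variants}
        cont = {(c.chrom, c.pos) for c in ds.truth.contaminants}
        tp = len(found & truth)
        precision = tp / len(found) if found else 0.0
        recall = tp / len(truth) if truth else 1.0
        summary = {"precision": precision, "recall": recall,
                   "germline_survivors": len(found & germ),
                   "contaminant_survivors": len(found & cont),
                   "n_sites": len(found)}
        checks = {
            "precision >= 0.95": precision >= 0.95,
            "recall >= 0.85": recall >= 0.85,
            "zero germline survivors": summary["germline_survivors"] == 0,
            "zero contaminant survivors": summary["contaminant_survivors"] == 0,
        }
        failed = [name for name, ok in checks.items() if not ok]
        if failed:
            raise PipelineError(f"demo checks failed: {failed} ({summary})")
        return report, paths, summary
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()
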