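"""Ground-truthed retinal-editome simulator.

Generates a toy genome with multi-exon genes on both strands, plants A-to-I
editing sites whose per-sample levels follow ``activity_s x beta(a, b)`` (a
latent per-sample deaminase activity scaling a per-site base level), plus
heterozygous/homozygous germline SNPs and three classes of artifact-prone
contaminant signals (homopolymer-internal, splice-junction-proximal and
read-end-biased mismatches). Reads are drawn from spliced transcripts and
placed back in genomic coordinates with gapped (M/N) alignments, so
junction-proximity filters are meaningful downstream.

All randomness flows from ``SimulationConfig.seed``; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation import AnnotationIndex, GeneModel, write_gtf

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
_CODE = {b: i for i, b in enumerate(BASES)}


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


class PlacementError(RuntimeError):
    """Genome too small to place the requested variants legally."""


@dataclass
class SimulationConfig:
    n_samples_per_group: int = 3
    group_labels: tuple[str, ...] = ("control", "model")
    coverage_mean: float = 50.0
    read_length: int = 100
    error_rate: float = 0.001
    n_true_sites: int = 200
    editing_level_alpha: float = 2.0
    editing_level_beta: float = 5.0
    adar_activity: tuple[float, ...] | None = None
    n_het_snps: int = 100
    n_hom_snps: int = 50
    n_contaminant_sites: int = 30
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples_per_group", "n_true_sites", "n_het_snps",
                     "n_hom_snps", "n_contaminant_sites"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_samples_per_group < 1:
            raise ConfigError("n_samples_per_group must be >= 1")
        if len(self.group_labels) < 1:
            raise ConfigError("group_labels must be non-empty")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigError("error_rate must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be > 0")
        if self.read_length < 20:
            raise ConfigError("read_length must be >= 20")
        if self.editing_level_alpha <= 0 or self.editing_level_beta <= 0:
            raise ConfigError("editing_level_distribution parameters must be > 0")
        if self.n_chromosomes < 2:
            raise ConfigError("n_chromosomes must be >= 2 (one is mitochondrial)")
        if self.chrom_length < 10_000:
            raise ConfigError("chrom_length must be >= 10000")
        acts = self.activities()
        if len(acts) != self.n_samples:
            raise ConfigError("adar_activity length must equal the sample count")
        if any(not 0.0 < a <= 1.0 for a in acts):
            raise ConfigError("adar_activity values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(self.group_labels)

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.group_labels
                for i in range(self.n_samples_per_group)]

    @property
    def sample_groups(self) -> list[str]:
        return [g for g in self.group_labels for _ in range(self.n_samples_per_group)]

    def activities(self) -> list[float]:
        """Per-sample deaminase activity; graded defaults mirror group-wise
        enzyme-expression differences (lower in the first group)."""
        if self.adar_activity is not None:
            return list(self.adar_activity)
        n_groups = len(self.group_labels)
        acts = []
        for gi in range(n_groups):
            base = 0.9 if n_groups == 1 else 0.6 + 0.3 * gi / (n_groups - 1)
            n = self.n_samples_per_group
            if n == 1:
                acts.append(base)
            else:
                for i in range(n):
                    acts.append(base + 0.12 * (i / (n - 1) - 0.5))
        return [min(1.0, round(a, 6)) for a in acts]


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, str]]
    genes: list[GeneModel]
    repeat_intervals: list[tuple[str, int, int]]  # 1-based inclusive
    mito_chrom_name: str

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def codes(self, chrom: str) -> np.ndarray:
        return seq_to_codes(self.sequence(chrom))


@dataclass(frozen=True)
class TrueSite:
    chrom: str
    pos: int  # 1-based
    strand: str
    gene_id: str
    base_level: float
    levels: tuple[float, ...]  # per sample, config.sample_names order


@dataclass(frozen=True)
class GermlineVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" or "hom", identical across samples (inbred strain)


@dataclass(frozen=True)
class Contaminant:
    chrom: str
    pos: int
    strand: str
    gene_id: str
    klass: str  # homopolymer | splice_junction | read_end


@dataclass
class TruthSet:
    true_sites: list[TrueSite]
    germline_variants: list[GermlineVariant]
    contaminants: list[Contaminant]

    def __post_init__(self):
        pos = [(s.chrom, s.pos) for s in self.true_sites]
        pos += [(v.chrom, v.pos) for v in self.germline_variants]
        pos += [(c.chrom, c.pos) for c in self.contaminants]
        if len(pos) != len(set(pos)):
            raise PlacementError("truth positions are not unique across categories")


def seq_to_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode()


def run_lengths(codes: np.ndarray) -> np.ndarray:
    """Length of the maximal equal-base run containing each position."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    out = np.empty(n, dtype=np.int64)
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(config: SimulationConfig) -> GenomeModel:
    """Random toy genome with tiled multi-exon genes on both strands.

    Guarantees by construction: the last chromosome is mitochondrial (two
    single-exon noncoding genes), at least one homopolymer run of >= 5 bases
    sits inside an exon on each strand, and each non-mito chromosome carries
    a simple-repeat interval overlapping an exon plus an intergenic one.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes - 1)] + ["chrM"]
    seqs = {n: rng.integers(0, 4, size=config.chrom_length).astype(np.int8) for n in names}

    genes: list[GeneModel] = []
    repeat_intervals: list[tuple[str, int, int]] = []
    gene_counter = 0
    adar_named = False

    for name in names[:-1]:
        cursor = 1000
        L = config.chrom_length
        chrom_gene_idx = 0
        while True:
            n_exons = int(rng.integers(3, 7))
            exon_lens = rng.integers(160, 420, size=n_exons)
            intron_lens = rng.integers(250, 650, size=n_exons - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 1500 > L:
                break
            exons = []
            p = cursor
            for i in range(n_exons):
                exons.append((p, p + int(exon_lens[i]) - 1))
                p = exons[-1][1] + 1 + (int(intron_lens[i]) if i < n_exons - 1 else 0)
            strand = "+" if chrom_gene_idx % 2 == 0 else "-"
            coding = chrom_gene_idx % 5 != 4
            cs = ce = None
            if coding:
                cs = exons[1][0] + 30
                ce_raw = exons[-2][1] - 30
                # trim so the exonic CDS length is a multiple of three
                cds_len = 0
                for s, e in exons:
                    lo, hi = max(s, cs), min(e, ce_raw)
                    if lo <= hi:
                        cds_len += hi - lo + 1
                ce = ce_raw - (cds_len % 3)
            gene_counter += 1
            if coding and not adar_named:
                gid = "Adar"
                adar_named = True
            else:
                gid = f"gene_{gene_counter:04d}"
            genes.append(GeneModel(gid, name, strand, tuple(exons), cs, ce))
            chrom_gene_idx += 1
            cursor = exons[-1][1] + 1 + int(rng.integers(600, 1400))

        # simple repeat overlapping an exon of the second gene on this chromosome,
        # plus an intergenic repeat near the chromosome start
        chrom_genes = [g for g in genes if g.chrom == name]
        if chrom_genes:
            tgt = chrom_genes[min(1, len(chrom_genes) - 1)]
            ex_s, ex_e = tgt.exons[0]
            rep_s = ex_s + 20
            rep_e = min(ex_e, rep_s + 199)
            pat = np.tile(np.array([A, C], dtype=np.int8), (rep_e - rep_s + 1) // 2 + 1)
            seqs[name][rep_s - 1 : rep_e] = pat[: rep_e - rep_s + 1]
            repeat_intervals.append((name, rep_s, rep_e))
        repeat_intervals.append((name, 200, 399))

    # mitochondrial chromosome: two single-exon noncoding genes
    mito = names[-1]
    genes.append(GeneModel("mt_gene_plus", mito, "+", ((1001, 2000),)))
    genes.append(GeneModel("mt_gene_minus", mito, "-", ((3001, 4000),)))

    # guaranteed exonic homopolymers: an A-run in a plus gene, a T-run in a minus gene
    def _inject_run(strand: str, code: int) -> None:
        for g in genes:
            if g.chrom == mito or g.strand != strand or not g.is_coding:
                continue
            s, e = g.exons[2]
            mid = (s + e) // 2
            seqs[g.chrom][mid - 1 : mid + 7] = code
            return
        raise PlacementError(f"no {strand}-strand gene available for homopolymer injection")

    _inject_run("+", A)
    _inject_run("-", T)

    chromosomes = [(n, codes_to_seq(seqs[n])) for n in names]
    gm = GenomeModel(chromosomes, genes, repeat_intervals, mito)
    # sanity: construction must have produced a long run somewhere
    if not any((run_lengths(seq_to_codes(s)) >= 5).any() for _, s in chromosomes):
        raise PlacementError("no homopolymer run of >= 5 bases was produced")
    return gm


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

def plant_truth(genome: GenomeModel, config: SimulationConfig) -> TruthSet:
    """Place true editing sites, germline SNPs and contaminants.

    True sites land on exonic reference-A positions in transcript orientation
    (genomic T for minus-strand genes), away from homopolymers, repeats,
    splice junctions (> 6 nt) and the mitochondrial chromosome, so every
    planted site is discoverable by the filter cascade.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    index = AnnotationIndex(genome.genes)
    activities = np.array(config.activities())

    chrom_codes = {n: seq_to_codes(s) for n, s in genome.chromosomes}
    hp = {}
    for n, codes in chrom_codes.items():
        inrun = run_lengths(codes) >= 5
        adj = inrun.copy()
        adj[1:] |= inrun[:-1]
        adj[:-1] |= inrun[1:]
        hp[n] = (inrun, adj)
    repeat_mask = {n: np.zeros(codes.size, dtype=bool) for n, codes in chrom_codes.items()}
    for chrom, s, e in genome.repeat_intervals:
        repeat_mask[chrom][s - 1 : e] = True

    clean: list[tuple[str, int, str, str]] = []       # legal true-site positions
    hp_pos: list[tuple[str, int, str, str]] = []      # inside homopolymer runs
    junc_pos: list[tuple[str, int, str, str]] = []    # within 6 nt of a junction
    snp_pool: list[tuple[str, int]] = []

    for g in genome.genes:
        if g.chrom == genome.mito_chrom_name:
            continue
        codes = chrom_codes[g.chrom]
        inrun, adj = hp[g.chrom]
        want = A if g.strand == "+" else T
        for s, e in g.exons:
            for pos in range(s, e + 1):
                i = pos - 1
                snp_pool.append((g.chrom, pos))
                if codes[i] != want:
                    continue
                jd = index.junction_distance(g.chrom, pos)
                entry = (g.chrom, pos, g.strand, g.gene_id)
                if inrun[i]:
                    hp_pos.append(entry)
                elif jd <= 6 and not adj[i] and not repeat_mask[g.chrom][i]:
                    junc_pos.append(entry)
                elif jd >= 7 and not adj[i] and not repeat_mask[g.chrom][i]:
                    clean.append(entry)

    need_clean = config.n_true_sites + (config.n_contaminant_sites + 2) // 3
    if len(clean) < need_clean:
        raise PlacementError(
            f"only {len(clean)} legal exonic positions for {need_clean} requested sites")

    order = rng.permutation(len(clean))
    picked = [clean[i] for i in order]
    true_entries = picked[: config.n_true_sites]
    read_end_pool = picked[config.n_true_sites :]

    base_levels = rng.beta(config.editing_level_alpha, config.editing_level_beta,
                           size=config.n_true_sites)
    true_sites = []
    for (chrom, pos, strand, gid), bl in zip(true_entries, base_levels):
        lv = np.minimum(1.0, activities * bl)
        true_sites.append(TrueSite(chrom, pos, strand, gid, float(bl), tuple(lv.tolist())))

    used = {(s.chrom, s.pos) for s in true_sites}

    # contaminants: cycle the three artifact classes
    contaminants = []
    pools = {"homopolymer": hp_pos, "splice_junction": junc_pos, "read_end": read_end_pool}
    cursors = {k: 0 for k in pools}
    for i in range(config.n_contaminant_sites):
        klass = ("homopolymer", "splice_junction", "read_end")[i % 3]
        pool = pools[klass]
        j = cursors[klass]
        while j < len(pool) and (pool[j][0], pool[j][1]) in used:
            j += 1
        if j >= len(pool):
            raise PlacementError(f"not enough positions for {klass} contaminants")
        chrom, pos, strand, gid = pool[j]
        cursors[klass] = j + 1
        contaminants.append(Contaminant(chrom, pos, strand, gid, klass))
        used.add((chrom, pos))

    # germline SNPs on exonic positions, any reference base
    snp_pool = [p for p in snp_pool if p not in used]
    n_snps = config.n_het_snps + config.n_hom_snps
    if len(snp_pool) < n_snps:
        raise PlacementError("not enough exonic positions for the requested SNPs")
    idx = rng.choice(len(snp_pool), size=n_snps, replace=False)
    variants = []
    for k, i in enumerate(idx):
        chrom, pos = snp_pool[i]
        ref = BASES[chrom_codes[chrom][pos - 1]]
        alt = BASES[(int(chrom_codes[chrom][pos - 1]) + int(rng.integers(1, 4))) % 4]
        geno = "het" if k < config.n_het_snps else "hom"
        variants.append(GermlineVariant(chrom, pos, ref, alt, geno))

    return TruthSet(true_sites, variants, contaminants)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class _GeneLayout:
    gene: GeneModel
    spliced: np.ndarray           # forward-orientation spliced codes
    tstarts: np.ndarray           # transcript offset of each exon
    gstarts: np.ndarray           # genomic start (1-based) of each exon
    glens: np.ndarray
    planted: list[tuple[int, int, object, str]]  # (t_pos, alt_code, prob, kind)


def _layout(gene: GeneModel, chrom_codes: np.ndarray) -> _GeneLayout:
    segs = [chrom_codes[s - 1 : e] for s, e in gene.exons]
    lens = np.array([seg.size for seg in segs])
    return _GeneLayout(
        gene,
        np.concatenate(segs),
        np.concatenate(([0], np.cumsum(lens)))[:-1],
        np.array([s for s, _ in gene.exons]),
        lens,
        [],
    )


def _cigar_for(layout: _GeneLayout, t0: int, rl: int) -> tuple[int, str]:
    """Genomic 1-based start and M/N cigar for a read at transcript offset t0."""
    i = int(np.searchsorted(layout.tstarts, t0, side="right")) - 1
    gpos = int(layout.gstarts[i] + (t0 - layout.tstarts[i]))
    parts = []
    t = t0
    remaining = rl
    while remaining > 0:
        cap = int(layout.tstarts[i] + layout.glens[i] - t)
        m = min(cap, remaining)
        parts.append(f"{m}M")
        remaining -= m
        t += m
        if remaining > 0:
            gap = int(layout.gstarts[i + 1] - (layout.gstarts[i] + layout.glens[i]))
            parts.append(f"{gap}N")
            i += 1
    return gpos, "".join(parts)


def simulate_alignments(genome: GenomeModel, truth: TruthSet, config: SimulationConfig,
                        out_dir: str):
    """Write one coordinate-sorted SAM per sample; return (sam_paths, counts).

    Reads are sampled uniformly from spliced transcripts at depth ~
    ``coverage_mean`` modulated by a per-gene log-normal expression factor
    (the gene named ``Adar`` additionally tracks per-sample activity). A read
    overlapping a true site carries the edited base with probability equal to
    the site's per-sample level; het/hom SNPs alternate with probability
    0.5/1.0; independent per-base errors at ``error_rate``. ``counts`` is the
    per-gene x per-sample read-count table (a featureCounts stand-in).
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    rng = _rng(config.seed, 2)
    rl = config.read_length
    names = [n for n, _ in genome.chromosomes]
    lengths = [len(s) for _, s in genome.chromosomes]
    chrom_codes = {n: seq_to_codes(s) for n, s in genome.chromosomes}

    layouts = {}
    for g in genome.genes:
        if g.exonic_length >= rl:
            layouts[g.gene_id] = _layout(g, chrom_codes[g.chrom])

    activities = np.array(config.activities())
    n_samples = config.n_samples

    def register(chrom, pos, strand_alt_code, prob, kind, gene_id=None):
        for g in genome.genes:
            if g.gene_id not in layouts or g.chrom != chrom:
                continue
            t = layouts[g.gene_id].gene.genomic_to_transcript_fwd(pos)
            if t is not None:
                layouts[g.gene_id].planted.append((t, strand_alt_code, prob, kind))

    for s in truth.true_sites:
        alt = G if s.strand == "+" else C
        register(s.chrom, s.pos, alt, np.array(s.levels), "edit")
    for v in truth.germline_variants:
        register(v.chrom, v.pos, _CODE[v.alt], 0.5 if v.genotype == "het" else 1.0, "snp")
    for c in truth.contaminants:
        alt = G if c.strand == "+" else C
        if c.klass == "read_end":
            register(c.chrom, c.pos, alt, 0.9, "read_end")
        else:
            register(c.chrom, c.pos, alt, 0.25, "artifact")

    # per-gene expression factors, mean-normalized; Adar tracks activity
    gene_ids = sorted(layouts)
    expr = rng.lognormal(mean=0.0, sigma=0.5, size=len(gene_ids))
    expr /= expr.mean()
    expr_by_gene = dict(zip(gene_ids, expr))
    mean_act = activities.mean()

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": L} for n, L in zip(names, lengths)],
    })
    ref_index = {n: i for i, n in enumerate(names)}
    quals = np.full(rl, 37, dtype=np.uint8)
    end_zone = int(np.floor(0.04 * rl))

    sam_paths = []
    counts = np.zeros((len(gene_ids), n_samples), dtype=np.int64)

    for si, sample in enumerate(config.sample_names):
        records = []
        for gi, gid in enumerate(gene_ids):
            lay = layouts[gid]
            tlen = lay.spliced.size
            adar_mult = activities[si] / mean_act if gid == "Adar" else 1.0
            lam = config.coverage_mean * tlen / rl * expr_by_gene[gid] * adar_mult
            n_reads = int(rng.poisson(lam))
            counts[gi, si] = n_reads
            if n_reads == 0:
                continue
            starts = rng.integers(0, tlen - rl + 1, size=n_reads)
            windows = lay.spliced[starts[:, None] + np.arange(rl)].copy()

            for t, alt_code, prob, kind in lay.planted:
                rows = np.flatnonzero((starts <= t) & (t < starts + rl))
                if rows.size == 0:
                    continue
                cols = t - starts[rows]
                p = prob[si] if isinstance(prob, np.ndarray) else prob
                take = rng.random(rows.size) < p
                if kind == "read_end":
                    take &= (cols < end_zone) | (cols >= rl - end_zone)
                windows[rows[take], cols[take]] = alt_code

            if config.error_rate > 0:
                err = rng.random(windows.shape) < config.error_rate
                n_err = int(err.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.int8)
                    windows[err] = (windows[err] + shift) % 4

            cigar_cache: dict[int, tuple[int, str]] = {}
            chrom = lay.gene.chrom
            rid = ref_index[chrom]
            for ri in range(n_reads):
                t0 = int(starts[ri])
                hit = cigar_cache.get(t0)
                if hit is None:
                    hit = _cigar_for(lay, t0, rl)
                    cigar_cache[t0] = hit
                gpos, cig = hit
                records.append((rid, gpos, f"{gid}:{sample}:{ri}", cig,
                                codes_to_seq(windows[ri])))

        records.sort(key=lambda r: (r[0], r[1], r[2]))
        path = os.path.join(out_dir, f"reads_{sample}.sam")
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for rid, gpos, qname, cig, seq in records:
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.reference_id = rid
                a.reference_start = gpos - 1
                a.cigarstring = cig
                a.query_sequence = seq
                a.query_qualities = quals
                a.mapping_quality = 60
                a.flag = 0
                fh.write(a)
        sam_paths.append(path)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=config.sample_names)
    return sam_paths, counts_df


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeModel
    truth: TruthSet
    counts: "object"
    paths: dict


def write_fasta(genome: GenomeModel, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(config: SimulationConfig, out_dir: str) -> SimulatedDataset:
    """Run the full generator and write every artifact the pipeline consumes."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    genome = build_genome(config)
    truth = plant_truth(genome, config)
    sam_paths, counts = simulate_alignments(genome, truth, config, out_dir)

    paths = {"sams": sam_paths}
    paths["fasta"] = os.path.join(out_dir, "genome.fa")
    write_fasta(genome, paths["fasta"])
    paths["gtf"] = os.path.join(out_dir, "annotation.gtf")
    write_gtf(genome.genes, paths["gtf"])

    paths["truth_bed"] = os.path.join(out_dir, "truth_sites.bed")
    with open(paths["truth_bed"], "w") as fh:
        for s in sorted(truth.true_sites, key=lambda x: (x.chrom, x.pos)):
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.gene_id}\t0\t{s.strand}\n")

    paths["truth_levels"] = os.path.join(out_dir, "truth_levels.tsv")
    with open(paths["truth_levels"], "w") as fh:
        fh.write("chrom\tpos\tstrand\tgene_id\tbase_level\t"
                 + "\t".join(config.sample_names) + "\n")
        for s in sorted(truth.true_sites, key=lambda x: (x.chrom, x.pos)):
            lv = "\t".join(f"{x:.6f}" for x in s.levels)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.gene_id}\t{s.base_level:.6f}\t{lv}\n")

    paths["germline_vcf"] = os.path.join(out_dir, "germline.vcf")
    with open(paths["germline_vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.chromosomes:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=GENO,Number=1,Type=String,Description="Simulated genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(truth.germline_variants, key=lambda x: (x.chrom, x.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\tGENO={v.genotype}\n")

    paths["contaminants"] = os.path.join(out_dir, "contaminants.tsv")
    with open(paths["contaminants"], "w") as fh:
        fh.write("chrom\tpos\tstrand\tgene_id\tclass\n")
        for c in sorted(truth.contaminants, key=lambda x: (x.chrom, x.pos)):
            fh.write(f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.gene_id}\t{c.klass}\n")

    paths["repeats_bed"] = os.path.join(out_dir, "repeats.bed")
    with open(paths["repeats_bed"], "w") as fh:
        for chrom, s, e in genome.repeat_intervals:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")

    paths["design"] = os.path.join(out_dir, "design.tsv")
    with open(paths["design"], "w") as fh:
        fh.write("sample\tgroup\tadar_activity\n")
        for name, grp, act in zip(config.sample_names, config.sample_groups,
                                  config.activities()):
            fh.write(f"{name}\t{grp}\t{act:.6f}\n")

    paths["counts"] = os.path.join(out_dir, "gene_counts.tsv")
    lengths = {g.gene_id: g.exonic_length for g in genome.genes}
    with open(paths["counts"], "w") as fh:
        fh.write("gene_id\texonic_length\t" + "\t".join(config.sample_names) + "\n")
        for gid in counts.index:
            row = "\t".join(str(int(x)) for x in counts.loc[gid])
            fh.write(f"{gid}\t{lengths[gid]}\t{row}\n")

    return SimulatedDataset(config, genome, truth, counts, paths)
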