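"""Candidate SNV calling and the high-confidence A-to-I filter cascade.

The discovery contract follows a VarScan-style caller: qualifying bases (base
quality >= 25) are piled up per position; a candidate is emitted where total
depth >= 10, alternate depth >= 2 and alternate allele frequency (AAF) >= 1%.
Candidates oriented as A>G on a plus-strand gene or T>C on a minus-strand
gene are A-to-I; the rest are discarded. Surviving calls then pass a fixed
cascade of exclusion rules — homopolymer (>= 5 nt, including immediately
adjacent positions), simple repeat, mitochondrial chromosome, <= 6 nt from a
splice junction, <= 1 nt from an observed indel, mismatches confined to the
terminal 4% of reads, known-SNP catalogue membership, and a germline AAF
pattern (AAF = 100% or 40-60% in > 90% of covered samples) — with a
known-editing whitelist exempting a site from all of them. Finally a site is
retained only if its editing level is >= 1% in at least two samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import AnnotationIndex
from .simulate import A, BASES, C, G, GenomeModel, T, run_lengths, seq_to_codes

logger = logging.getLogger(__name__)

FILTER_RULES = (
    "homopolymer",
    "simple_repeat",
    "mitochondrial",
    "splice_junction",
    "indel_proximity",
    "read_end",
    "dbsnp",
    "germline_pattern",
)


class ReferenceMismatchError(ValueError):
    """Alignment refers to a chromosome absent from the reference."""


@dataclass
class DiscoveryThresholds:
    min_base_quality: int = 25
    min_depth: int = 10
    min_alt_depth: int = 2
    min_aaf: float = 0.01
    homopolymer_len: int = 5
    splice_junction_dist: int = 6
    indel_dist: int = 1
    read_end_frac: float = 0.04
    germline_sample_frac: float = 0.90
    het_band: tuple[float, float] = (0.40, 0.60)
    min_level: float = 0.01
    min_samples: int = 2


@dataclass
class SiteObservation:
    """One pileup column: qualifying allele counts plus, for every
    non-reference supporting read, its mismatch offsets from both read ends."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    allele_counts: dict[str, int]
    end_offsets: list[tuple[int, int, int]]  # (dist from 5' end, dist from 3' end, read len)

    @property
    def depth(self) -> int:
        return sum(self.allele_counts.values())


@dataclass
class VariantCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int
    per_sample: list[tuple[int, int]] = field(default_factory=list)  # (depth, alt_depth)
    end_offsets: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def aaf(self) -> float:
        return self.alt_depth / self.depth if self.depth else 0.0

    def sample_aafs(self) -> np.ndarray:
        return np.array([ad / d if d else 0.0 for d, ad in self.per_sample])


@dataclass
class FilterVerdict:
    status: str  # "pass" | "fail"
    failed_rule: str | None = None
    whitelisted: bool = False


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

class SamplePileup:
    """Per-sample qualifying-base pileup over one reference.

    Arrays: ``counts[chrom]`` has shape (4, L) of base-quality-qualifying
    read counts; mismatch read-end offsets and indel anchors are kept in
    sparse dictionaries. Deletions and reference skips contribute nothing.
    """

    def __init__(self, ref_codes: dict[str, np.ndarray]):
        self.ref_codes = ref_codes
        self.counts = {c: np.zeros((4, a.size), dtype=np.int32) for c, a in ref_codes.items()}
        # (chrom, pos0) -> list of (base_code, dist5, dist3, read_len)
        self.mismatch_offsets: dict[tuple[str, int], list[tuple[int, int, int, int]]] = {}
        # (chrom, pos0) -> supporting-read count for an indel anchored there
        self.indels: dict[tuple[str, int], int] = {}

    def add_read(self, read: pysam.AlignedSegment, chrom: str, min_bq: int) -> None:
        seq = read.query_sequence
        if seq is None:
            return
        codes = seq_to_codes(seq)
        quals = np.asarray(read.query_qualities, dtype=np.int32) \
            if read.query_qualities is not None else np.full(len(seq), 60, dtype=np.int32)
        rlen = len(seq)
        ref = self.ref_codes[chrom]
        cnt = self.counts[chrom]
        qpos = 0
        rpos = read.reference_start  # 0-based
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):  # M, =, X
                block = codes[qpos : qpos + ln]
                bq = quals[qpos : qpos + ln]
                ok = (bq >= min_bq) & (block < 4)
                positions = np.arange(rpos, rpos + ln)
                gp = positions[ok]
                bc = block[ok]
                np.add.at(cnt, (bc, gp), 1)
                mism = bc != ref[gp]
                if mism.any():
                    qoff = (np.arange(qpos, qpos + ln))[ok][mism]
                    for gpos, code, qo in zip(gp[mism], bc[mism], qoff):
                        self.mismatch_offsets.setdefault((chrom, int(gpos)), []).append(
                            (int(code), int(qo), rlen - 1 - int(qo), rlen))
                qpos += ln
                rpos += ln
            elif op == 1:  # I: anchor at the base after the insertion point
                self.indels[(chrom, rpos)] = self.indels.get((chrom, rpos), 0) + 1
                qpos += ln
            elif op == 2:  # D
                for d in range(ln):
                    self.indels[(chrom, rpos + d)] = self.indels.get((chrom, rpos + d), 0) + 1
                rpos += ln
            elif op == 3:  # N
                rpos += ln
            elif op == 4:  # S
                qpos += ln
            elif op == 5:  # H
                pass
            else:
                qpos += ln

    def observation(self, chrom: str, pos: int) -> SiteObservation:
        """Build the per-column observation view at a 1-based position."""
        i = pos - 1
        col = self.counts[chrom][:, i]
        ref_code = int(self.ref_codes[chrom][i])
        offsets = [(d5, d3, rl) for code, d5, d3, rl in
                   self.mismatch_offsets.get((chrom, i), [])]
        return SiteObservation(
            chrom, pos, BASES[ref_code] if ref_code < 4 else "N",
            {BASES[b]: int(col[b]) for b in range(4)}, offsets)

    def alt_offsets(self, chrom: str, pos: int, alt_code: int):
        return [(d5, d3, rl) for code, d5, d3, rl in
                self.mismatch_offsets.get((chrom, pos - 1), []) if code == alt_code]


def pileup_sample(sam_path: str, genome: GenomeModel | dict[str, str],
                  min_base_quality: int = 25) -> SamplePileup:
    """Stream a coordinate-sorted SAM/BAM into a :class:`SamplePileup`."""
    seqs = dict(genome.chromosomes) if isinstance(genome, GenomeModel) else dict(genome)
    ref_codes = {c: seq_to_codes(s) for c, s in seqs.items()}
    pu = SamplePileup(ref_codes)
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            chrom = read.reference_name
            if chrom not in ref_codes:
                raise ReferenceMismatchError(
                    f"chromosome {chrom!r} in {sam_path} absent from reference")
            pu.add_read(read, chrom, min_base_quality)
    return pu


def pileup(sam_path: str, genome, min_base_quality: int = 25):
    """Yield one :class:`SiteObservation` per covered position."""
    pu = pileup_sample(sam_path, genome, min_base_quality)
    for chrom in pu.counts:
        covered = np.flatnonzero(pu.counts[chrom].sum(axis=0) > 0)
        for i in covered:
            yield pu.observation(chrom, int(i) + 1)


# ---------------------------------------------------------------------------
# Candidate calling
# ---------------------------------------------------------------------------

def call_candidate_snvs(observations, thresholds: DiscoveryThresholds) -> list[VariantCall]:
    """Emit a call where depth >= 10, alt depth >= 2 and AAF >= 1% hold for
    the highest-count alternate base of the column."""
    calls = []
    for obs in observations:
        depth = obs.depth
        if depth < thresholds.min_depth:
            continue
        alts = [(n, b) for b, n in obs.allele_counts.items() if b != obs.ref_base]
        if not alts:
            continue
        n_alt, alt = max(alts)
        if n_alt < thresholds.min_alt_depth or n_alt / depth < thresholds.min_aaf:
            continue
        calls.append(VariantCall(obs.chrom, obs.pos, obs.ref_base, alt, depth, n_alt,
                                 end_offsets=list(obs.end_offsets)))
    return calls


def merge_candidates(pileups: list[SamplePileup], thresholds: DiscoveryThresholds
                     ) -> list[VariantCall]:
    """Union of per-sample candidates with per-sample (depth, alt) replicates.

    A position qualifies if any single sample meets the calling thresholds;
    the alternate allele is the pooled-majority alternate at that position.
    """
    candidate_pos: set[tuple[str, int]] = set()
    for pu in pileups:
        for chrom, codes in pu.ref_codes.items():
            cnt = pu.counts[chrom]
            depth = cnt.sum(axis=0)
            ref = codes.copy()
            ref[ref > 3] = 0
            alt_cnt = cnt.copy()
            alt_cnt[ref, np.arange(ref.size)] = 0
            best_alt = alt_cnt.max(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                aaf = np.where(depth > 0, best_alt / np.maximum(depth, 1), 0.0)
            ok = (depth >= thresholds.min_depth) & (best_alt >= thresholds.min_alt_depth) \
                & (aaf >= thresholds.min_aaf) & (codes <= 3)
            for i in np.flatnonzero(ok):
                candidate_pos.add((chrom, int(i) + 1))

    calls = []
    for chrom, pos in sorted(candidate_pos):
        i = pos - 1
        ref_code = int(pileups[0].ref_codes[chrom][i])
        pooled = np.zeros(4, dtype=np.int64)
        for pu in pileups:
            pooled += pu.counts[chrom][:, i]
        alt_order = np.argsort(pooled, kind="stable")[::-1]
        alt_code = next(int(b) for b in alt_order if int(b) != ref_code)
        per_sample = []
        offsets = []
        for pu in pileups:
            col = pu.counts[chrom][:, i]
            per_sample.append((int(col.sum()), int(col[alt_code])))
            offsets.extend(pu.alt_offsets(chrom, pos, alt_code))
        calls.append(VariantCall(chrom, pos, BASES[ref_code], BASES[alt_code],
                                 int(pooled.sum()), int(pooled[alt_code]),
                                 per_sample, offsets))
    return calls


def orient_substitution(call: VariantCall, annotation: AnnotationIndex) -> str:
    """Classify a substitution as ``A_to_I`` / ``other`` / ``ambiguous``
    from the strands of the genes overlapping its position."""
    strands = {g.strand for g in annotation.genes_at(call.chrom, call.pos)}
    plus_ok = call.ref == "A" and call.alt == "G"
    minus_ok = call.ref == "T" and call.alt == "C"
    if strands == {"+", "-"}:
        return "ambiguous" if (plus_ok or minus_ok) else "other"
    if strands == {"+"}:
        return "A_to_I" if plus_ok else "other"
    if strands == {"-"}:
        return "A_to_I" if minus_ok else "other"
    return "other"


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterContext:
    """Reference context shared by the site filters."""

    sequences: dict[str, str]
    annotation: AnnotationIndex
    mito_chrom: str
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    dbsnp: set[tuple[str, int]] | None = None
    whitelist: set[tuple[str, int]] | None = None
    indels: dict[tuple[str, int], int] | None = None  # (chrom, pos0) -> read support
    _run_adj: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _repeat_mask: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def in_homopolymer(self, chrom: str, pos: int, min_len: int) -> bool:
        """Inside, or immediately adjacent to, a reference run of >= min_len."""
        mask = self._run_adj.get(chrom)
        if mask is None:
            inrun = run_lengths(seq_to_codes(self.sequences[chrom])) >= min_len
            mask = inrun.copy()
            mask[1:] |= inrun[:-1]
            mask[:-1] |= inrun[1:]
            self._run_adj[chrom] = mask
        return bool(mask[pos - 1])

    def in_repeat(self, chrom: str, pos: int) -> bool:
        mask = self._repeat_mask.get(chrom)
        if mask is None:
            mask = np.zeros(len(self.sequences[chrom]), dtype=bool)
            for c, s, e in self.repeat_intervals:
                if c == chrom:
                    mask[s - 1 : e] = True
            self._repeat_mask[chrom] = mask
        return bool(mask[pos - 1])

    def indel_near(self, chrom: str, pos: int, dist: int, min_support: int = 2) -> bool:
        if not self.indels:
            return False
        for d in range(-dist, dist + 1):
            if self.indels.get((chrom, pos - 1 + d), 0) >= min_support:
                return True
        return False


def apply_site_filters(call: VariantCall, ctx: FilterContext,
                       thresholds: DiscoveryThresholds) -> FilterVerdict:
    """Exclusion rules in fixed order; whitelisted sites bypass all of them.

    The read-end rule discards alternate-supporting reads whose mismatch lies
    within ``floor(read_end_frac x read length)`` bases of either end and
    fails the call if fewer than ``min_alt_depth`` supporters survive; level
    estimates elsewhere keep the full qualifying counts.
    """
    key = (call.chrom, call.pos)
    if ctx.whitelist is not None and key in ctx.whitelist:
        return FilterVerdict("pass", whitelisted=True)

    if ctx.in_homopolymer(call.chrom, call.pos, thresholds.homopolymer_len):
        return FilterVerdict("fail", "homopolymer")
    if ctx.in_repeat(call.chrom, call.pos):
        return FilterVerdict("fail", "simple_repeat")
    if call.chrom == ctx.mito_chrom:
        return FilterVerdict("fail", "mitochondrial")
    if ctx.annotation.junction_distance(call.chrom, call.pos) <= thresholds.splice_junction_dist:
        return FilterVerdict("fail", "splice_junction")
    if ctx.indel_near(call.chrom, call.pos, thresholds.indel_dist):
        return FilterVerdict("fail", "indel_proximity")

    surviving = 0
    for d5, d3, rlen in call.end_offsets:
        zone = math.floor(thresholds.read_end_frac * rlen)
        if min(d5, d3) >= zone:
            surviving += 1
    if call.end_offsets and surviving < thresholds.min_alt_depth:
        return FilterVerdict("fail", "read_end")

    if ctx.dbsnp is not None and key in ctx.dbsnp:
        return FilterVerdict("fail", "dbsnp")
    return FilterVerdict("pass")


def germline_pattern_filter(aafs: np.ndarray, covered: np.ndarray,
                            thresholds: DiscoveryThresholds) -> FilterVerdict | None:
    """Fail a site whose covered-sample AAF profile looks genotypic.

    Returns ``None`` (indeterminate; caller drops and logs the site) when no
    sample is covered.
    """
    aafs = np.asarray(aafs, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    if not covered.any():
        return None
    a = aafs[covered]
    lo, hi = thresholds.het_band
    eps = 1e-9
    frac_hom = float(np.mean(a >= 1.0 - eps))
    frac_het = float(np.mean((a >= lo - eps) & (a <= hi + eps)))
    if frac_hom > thresholds.germline_sample_frac or frac_het > thresholds.germline_sample_frac:
        return FilterVerdict("fail", "germline_pattern")
    return FilterVerdict("pass")


# ---------------------------------------------------------------------------
# High-confidence selection and the discovery driver
# ---------------------------------------------------------------------------

@dataclass
class EditingSite:
    chrom: str
    pos: int
    strand: str
    gene_id: str | None
    edited: tuple[int, ...]   # per-sample edited-read counts
    total: tuple[int, ...]    # per-sample qualifying depth
    whitelisted: bool = False

    def levels(self, min_depth: int = 10) -> np.ndarray:
        """Per-sample editing level; NaN where depth < min_depth."""
        tot = np.array(self.total, dtype=float)
        ed = np.array(self.edited, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(tot >= min_depth, ed / np.maximum(tot, 1), np.nan)
        return lv


def select_high_confidence(sites: list[EditingSite],
                           thresholds: DiscoveryThresholds) -> list[EditingSite]:
    """Retain sites with editing level >= min_level in >= min_samples samples."""
    kept = []
    for s in sites:
        lv = s.levels(thresholds.min_depth)
        n_ok = int(np.sum(lv[~np.isnan(lv)] >= thresholds.min_level))
        if n_ok >= thresholds.min_samples:
            kept.append(s)
    kept.sort(key=lambda s: (s.chrom, s.pos))
    return kept


@dataclass
class DiscoveryResult:
    sites: list[EditingSite]
    attrition: dict[str, int]
    dropped_ambiguous: int
    candidates: list[VariantCall] = field(default_factory=list)


def discover_editing_sites(sam_paths: list[str], genome, annotation: AnnotationIndex,
                           thresholds: DiscoveryThresholds | None = None,
                           mito_chrom: str = "chrM",
                           repeat_intervals: list[tuple[str, int, int]] | None = None,
                           dbsnp: set[tuple[str, int]] | None = None,
                           whitelist: set[tuple[str, int]] | None = None,
                           ) -> DiscoveryResult:
    """End-to-end discovery: pileup -> call -> orient -> filter -> select."""
    thresholds = thresholds or DiscoveryThresholds()
    if dbsnp is None:
        logger.info("no known-SNP catalogue supplied; dbsnp rule skipped")
    if whitelist is None:
        logger.info("no known-editing whitelist supplied; no exemptions applied")
    if repeat_intervals is None:
        logger.info("no repeat mask supplied; simple_repeat rule skipped")

    pileups = [pileup_sample(p, genome, thresholds.min_base_quality) for p in sam_paths]
    calls = merge_candidates(pileups, thresholds)

    sequences = dict(genome.chromosomes) if isinstance(genome, GenomeModel) else dict(genome)
    indels: dict[tuple[str, int], int] = {}
    for pu in pileups:
        for k, v in pu.indels.items():
            indels[k] = indels.get(k, 0) + v
    ctx = FilterContext(sequences, annotation, mito_chrom,
                        repeat_intervals or [], dbsnp, whitelist, indels)

    attrition = {"candidates": len(calls), "a_to_i": 0}
    attrition.update({r: 0 for r in FILTER_RULES})
    attrition["indeterminate"] = 0
    dropped_ambiguous = 0
    sites: list[EditingSite] = []

    for call in calls:
        klass = orient_substitution(call, annotation)
        if klass == "ambiguous":
            dropped_ambiguous += 1
            logger.info("ambiguous-strand site dropped at %s:%d", call.chrom, call.pos)
            continue
        if klass != "A_to_I":
            continue
        attrition["a_to_i"] += 1
        verdict = apply_site_filters(call, ctx, thresholds)
        if verdict.status == "fail":
            attrition[verdict.failed_rule] += 1
            continue
        if not verdict.whitelisted:
            covered = np.array([d >= thresholds.min_depth for d, _ in call.per_sample])
            gv = germline_pattern_filter(call.sample_aafs(), covered, thresholds)
            if gv is None:
                attrition["indeterminate"] += 1
                logger.info("no covered sample at %s:%d; dropped", call.chrom, call.pos)
                continue
            if gv.status == "fail":
                attrition["germline_pattern"] += 1
                continue
        genes = annotation.genes_at(call.chrom, call.pos)
        strand = genes[0].strand if genes else "+"
        gene_id = genes[0].gene_id if genes else None
        sites.append(EditingSite(call.chrom, call.pos, strand, gene_id,
                                 tuple(ad for _, ad in call.per_sample),
                                 tuple(d for d, _ in call.per_sample),
                                 verdict.whitelisted))

    attrition["filtered_pass"] = len(sites)
    high_conf = select_high_confidence(sites, thresholds)
    attrition["high_confidence"] = len(high_conf)
    return DiscoveryResult(high_conf, attrition, dropped_ambiguous, calls)
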