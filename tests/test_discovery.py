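"""Calling thresholds, substitution orientation and the filter cascade."""

import numpy as np
import pysam
import pytest

from editome.annotation import AnnotationIndex, GeneModel
from editome.discovery import (
    DiscoveryThresholds,
    EditingSite,
    FilterContext,
    SiteObservation,
    VariantCall,
    apply_site_filters,
    call_candidate_snvs,
    discover_editing_sites,
    germline_pattern_filter,
    orient_substitution,
    pileup_sample,
    select_high_confidence,
)
from _oracles import naive_cascade_verdict
from _sitegen import make_random_site

TH = DiscoveryThresholds()


def _write_sam(path, ref_len, reads):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": "chr1", "LN": ref_len}]})
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, pos0, cigar, seq, quals in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = pos0
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(quals)
            a.mapping_quality = 60
            fh.write(a)


class TestPileup:
    def test_single_mismatch_and_quality_threshold(self, tmp_path):
        ref = "ACGT" * 50
        # read 1: G over reference A at ref index 0 (pos 1), high quality
        # read 2: same mismatch but base quality 24 -> excluded
        reads = [
            ("r1", 0, "8M", "G" + ref[1:8], "I" * 8),
            ("r2", 0, "8M", "G" + ref[1:8], chr(24 + 33) + "I" * 7),
        ]
        sam = tmp_path / "t.sam"
        _write_sam(sam, len(ref), reads)
        pu = pileup_sample(str(sam), {"chr1": ref}, min_base_quality=25)
        obs = pu.observation("chr1", 1)
        assert obs.allele_counts == {"A": 0, "C": 0, "G": 1, "T": 0}
        # the qualifying mismatch carries its end offsets
        assert obs.end_offsets == [(0, 7, 8)]

    def test_gapped_alignment_offsets_match_manual_cigar_walk(self, tmp_path):
        ref = "ACGT" * 50
        # 10M50N10M starting at ref index 0: covers ref 0-9 then 60-69
        q = ref[0:10] + ref[60:70]
        qi = 12  # mismatch at query index 12 -> ref index 60 + (12 - 10) = 62
        q = q[:qi] + ("G" if q[qi] != "G" else "C") + q[qi + 1 :]
        sam = tmp_path / "g.sam"
        _write_sam(sam, len(ref), [("r1", 0, "10M50N10M", q, "I" * 20)])
        pu = pileup_sample(str(sam), {"chr1": ref}, 25)
        obs = pu.observation("chr1", 63)
        assert obs.end_offsets == [(12, 20 - 1 - 12, 20)]
        # skipped region contributes no counts
        assert pu.counts["chr1"][:, 30].sum() == 0
        # manual CIGAR walk over aligned (non-skipped) bases
        covered = list(range(0, 10)) + list(range(60, 70))
        for i in covered:
            assert pu.counts["chr1"][:, i].sum() == 1

    def test_deletions_uncounted_and_indel_recorded(self, tmp_path):
        ref = "ACGT" * 10
        sam = tmp_path / "d.sam"
        _write_sam(sam, len(ref), [
            ("r1", 0, "5M2D5M", ref[0:5] + ref[7:12], "I" * 10),
            ("r2", 0, "5M2D5M", ref[0:5] + ref[7:12], "I" * 10),
        ])
        pu = pileup_sample(str(sam), {"chr1": ref}, 25)
        assert pu.counts["chr1"][:, 5].sum() == 0  # deleted base
        assert pu.indels[("chr1", 5)] == 2


class TestCandidateCalling:
    @pytest.mark.parametrize("depth, alt, called", [
        (10, 2, True),    # at the boundary of all three thresholds
        (9, 3, False),    # depth below 10
        (300, 2, False),  # AAF ~0.67% below 1%
        (200, 3, True),   # AAF 1.5%
    ])
    def test_thresholds(self, depth, alt, called):
        obs = SiteObservation("chr1", 100, "A",
                              {"A": depth - alt, "C": 0, "G": alt, "T": 0}, [])
        calls = call_candidate_snvs([obs], TH)
        assert bool(calls) is called
        if called:
            assert calls[0].alt == "G" and calls[0].alt_depth == alt

    def test_multiallelic_keeps_majority_alternate(self):
        obs = SiteObservation("chr1", 100, "A",
                              {"A": 40, "C": 3, "G": 7, "T": 0}, [])
        (call,) = call_candidate_snvs([obs], TH)
        assert call.alt == "G" and call.alt_depth == 7


class TestOrientation:
    plus = GeneModel("gp", "chr1", "+", ((1, 1000),))
    minus = GeneModel("gm", "chr1", "-", ((2001, 3000),))
    both_a = GeneModel("ga", "chr2", "+", ((1, 1000),))
    both_b = GeneModel("gb", "chr2", "-", ((500, 1500),))
    index = AnnotationIndex([plus, minus, both_a, both_b])

    @pytest.mark.parametrize("chrom, pos, ref, alt, expected", [
        ("chr1", 500, "A", "G", "A_to_I"),
        ("chr1", 2500, "T", "C", "A_to_I"),
        ("chr1", 500, "C", "T", "other"),
        ("chr1", 500, "T", "C", "other"),     # T>C needs a minus-strand gene
        ("chr2", 700, "A", "G", "ambiguous"),  # genes on both strands
        ("chr2", 700, "C", "T", "other"),
        ("chr1", 5000, "A", "G", "other"),     # intergenic
    ])
    def test_classes(self, chrom, pos, ref, alt, expected):
        call = VariantCall(chrom, pos, ref, alt, 50, 10)
        assert orient_substitution(call, self.index) == expected


def _ctx(seq="ACGT" * 250, chrom="chr1", **kw):
    gene = kw.pop("gene", GeneModel("g", chrom, "+", ((1, 400), (501, 1000))))
    defaults = dict(sequences={chrom: seq}, annotation=AnnotationIndex([gene]),
                    mito_chrom="chrM", repeat_intervals=[], dbsnp=set(),
                    whitelist=set(), indels={})
    defaults.update(kw)
    return FilterContext(**defaults)


def _call(chrom="chr1", pos=200, offsets=None):
    return VariantCall(chrom, pos, "A", "G", 50, 10,
                       [(50, 10)], offsets or [(50, 49, 100)] * 10)


class TestFilterRules:
    def test_homopolymer_inside_and_adjacent(self):
        seq = "ACGT" * 40 + "AAAAA" + "CGTC" * 40
        ctx = _ctx(seq=seq)
        for pos in (161, 163, 165):  # run occupies 161-165 (1-based)
            assert apply_site_filters(_call(pos=pos), ctx, TH).failed_rule == "homopolymer"
        assert apply_site_filters(_call(pos=160), ctx, TH).failed_rule == "homopolymer"
        assert apply_site_filters(_call(pos=166), ctx, TH).failed_rule == "homopolymer"
        assert apply_site_filters(_call(pos=158), ctx, TH).failed_rule != "homopolymer"

    def test_splice_junction_distance_boundary(self):
        # junction boundaries at 400 and 501
        ctx = _ctx()
        v6 = apply_site_filters(_call(pos=394), ctx, TH)  # 6 nt from 400
        v7 = apply_site_filters(_call(pos=393), ctx, TH)  # 7 nt
        assert v6.failed_rule == "splice_junction"
        assert v7.status == "pass"

    def test_mitochondrial_and_repeat(self):
        gene = GeneModel("g", "chrM", "+", ((1, 1000),))
        ctx = _ctx(chrom="chrM", gene=gene)
        assert apply_site_filters(_call(chrom="chrM"), ctx, TH).failed_rule == "mitochondrial"
        ctx2 = _ctx(repeat_intervals=[("chr1", 190, 210)])
        assert apply_site_filters(_call(pos=200), ctx2, TH).failed_rule == "simple_repeat"

    def test_indel_proximity(self):
        ctx = _ctx(indels={("chr1", 199): 2})  # 0-based anchor at the site
        assert apply_site_filters(_call(pos=200), ctx, TH).failed_rule == "indel_proximity"
        weak = _ctx(indels={("chr1", 199): 1})  # below the 2-read support floor
        assert apply_site_filters(_call(pos=200), weak, TH).status == "pass"

    def test_read_end_rule_discards_terminal_mismatches(self):
        # all alternate mismatches within floor(0.04*100)=4 bases of an end
        bad = [(2, 97, 100), (98, 1, 100), (3, 96, 100)]
        ctx = _ctx()
        assert apply_site_filters(_call(offsets=bad), ctx, TH).failed_rule == "read_end"
        mixed = bad + [(40, 59, 100), (10, 89, 100)]
        assert apply_site_filters(_call(offsets=mixed), ctx, TH).status == "pass"

    def test_whitelist_exempts_even_dbsnp(self):
        ctx = _ctx(dbsnp={("chr1", 200)}, whitelist={("chr1", 200)})
        v = apply_site_filters(_call(pos=200), ctx, TH)
        assert v.status == "pass" and v.whitelisted
        ctx2 = _ctx(dbsnp={("chr1", 200)})
        assert apply_site_filters(_call(pos=200), ctx2, TH).failed_rule == "dbsnp"


class TestGermlinePattern:
    @pytest.mark.parametrize("aafs, expected", [
        ([0.50, 0.48, 0.55], "fail"),
        ([1.0, 1.0, 1.0], "fail"),
        ([0.15, 0.22, 0.18], "pass"),
        ([0.50, 0.48, 0.20], "pass"),  # only 2/3 in the het band
    ])
    def test_bands(self, aafs, expected):
        v = germline_pattern_filter(np.array(aafs), np.ones(len(aafs), bool), TH)
        assert v.status == expected

    def test_no_covered_samples_is_indeterminate(self):
        assert germline_pattern_filter(np.array([0.5]), np.array([False]), TH) is None


class TestSelection:
    def _site(self, edited, total):
        return EditingSite("chr1", 1, "+", "g", tuple(edited), tuple(total))

    def test_min_level_in_min_samples(self):
        keep = self._site([1, 2, 0], [80, 100, 90])      # 1.25%, 2%, 0%
        drop = self._site([2, 0, 0], [100, 100, 100])    # one qualifying sample
        zero = self._site([0, 0, 0], [100, 100, 100])
        out = select_high_confidence([drop, keep, zero], TH)
        assert out == [keep]

    def test_low_coverage_samples_do_not_qualify(self):
        s = self._site([1, 1, 0], [9, 9, 100])  # levels undefined below depth 10
        assert select_high_confidence([s], TH) == []


def impl_verdict(call, ctx, th):
    v = apply_site_filters(call, ctx, th)
    if v.status == "fail" or v.whitelisted:
        return v.status, v.failed_rule, v.whitelisted
    covered = np.array([d >= th.min_depth for d, _ in call.per_sample])
    gv = germline_pattern_filter(call.sample_aafs(), covered, th)
    if gv is None:
        return "indeterminate", None, False
    return gv.status, gv.failed_rule, False


def test_cascade_matches_naive_oracle_on_random_sites():
    """On hundreds of randomized contexts the cascade agrees with a literal
    re-implementation of the exclusion rules on every verdict."""
    rng = np.random.default_rng(2024)
    for i in range(500):
        call, ctx, naive = make_random_site(rng)
        got = impl_verdict(call, ctx, TH)
        want = naive_cascade_verdict(naive, TH)
        assert got == want, f"site {i}: {got} != {want}\n{naive}"


def test_discovery_is_deterministic(small_dataset):
    ds = small_dataset
    index = AnnotationIndex(ds.genome.genes)
    kw = dict(mito_chrom=ds.genome.mito_chrom_name,
              repeat_intervals=ds.genome.repeat_intervals)
    r1 = discover_editing_sites(ds.paths["sams"], ds.genome, index, TH, **kw)
    r2 = discover_editing_sites(ds.paths["sams"], ds.genome, index, TH, **kw)
    assert r1.attrition == r2.attrition
    assert [(s.chrom, s.pos) for s in r1.sites] == [(s.chrom, s.pos) for s in r2.sites]
    # every retained site is A-to-I oriented: A on plus genes, T on minus genes
    for s in r1.sites:
        ref = ds.genome.sequence(s.chrom)[s.pos - 1]
        assert ref == ("A" if s.strand == "+" else "T")
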