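"""Editing-level quantification, TPM expression, and site annotation.

Editing level is the edited-read fraction at a site in one sample; TPM is the
within-sample length-normalized expression unit (column sums equal 1e6);
region annotation resolves each site to one of CDS / 5'UTR / 3'UTR /
noncoding exon / intron / intergenic by a fixed precedence, and CDS sites get
a codon-substitution consequence (A->G in transcript orientation, inosine
read as guanosine by the translation machinery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import AnnotationIndex, GeneModel, revcomp
from .discovery import EditingSite

REGION_PRECEDENCE = ("CDS", "three_prime_UTR", "five_prime_UTR",
                     "noncoding_exon", "intron", "intergenic")


class DataIntegrityError(ValueError):
    pass


def editing_level(edited_count: int, total_count: int) -> float:
    """Edited-read fraction; NaN when the site has no coverage."""
    if edited_count < 0 or total_count < 0:
        raise DataIntegrityError("negative count")
    if edited_count > total_count:
        raise DataIntegrityError(f"edited {edited_count} exceeds total {total_count}")
    if total_count == 0:
        return float("nan")
    return edited_count / total_count


@dataclass
class EditingMatrix:
    """Sites x samples editing levels with a coverage mask and group labels."""

    levels: pd.DataFrame        # NaN where masked
    mask: pd.DataFrame          # True where the level is defined
    groups: pd.Series           # sample -> group label
    edited: pd.DataFrame | None = None
    total: pd.DataFrame | None = None

    @classmethod
    def from_sites(cls, sites: list[EditingSite], sample_names: list[str],
                   groups: list[str], min_depth: int = 10) -> "EditingMatrix":
        idx = [f"{s.chrom}:{s.pos}:{s.strand}" for s in sites]
        ed = pd.DataFrame([s.edited for s in sites], index=idx, columns=sample_names)
        tot = pd.DataFrame([s.total for s in sites], index=idx, columns=sample_names)
        lv = pd.DataFrame([s.levels(min_depth) for s in sites], index=idx,
                          columns=sample_names)
        return cls(lv, ~lv.isna(), pd.Series(groups, index=sample_names), ed, tot)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw per-gene counts and exonic lengths."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise DataIntegrityError("gene lengths must be positive")
    rate = counts.div(lengths / 1000.0, axis=0)
    total = rate.sum(axis=0)
    tpm = rate.div(total.where(total > 0, np.nan), axis=1) * 1e6
    zero_cols = total[total == 0].index
    if len(zero_cols):
        import warnings
        warnings.warn(f"samples with zero total count: {list(zero_cols)}")
        tpm[zero_cols] = 0.0
    return tpm


@dataclass
class AnnotationRecord:
    chrom: str
    pos: int
    strand: str
    gene_id: str | None
    region: str
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    consequence: str | None = None  # missense | synonymous | stop_altering


def _cds_consequence(gene: GeneModel, pos: int, chrom_seq: str) -> tuple[str, str, str, str, str]:
    cds_pos = gene.cds_genomic_positions()
    i = cds_pos.index(pos)
    codon_i = i // 3
    codon_positions = cds_pos[3 * codon_i : 3 * codon_i + 3]
    bases = [chrom_seq[p - 1] for p in codon_positions]
    if gene.strand == "-":
        bases = [revcomp(b) for b in bases]
    ref_codon = "".join(bases)
    within = i % 3
    alt = list(ref_codon)
    alt[within] = "G"  # inosine decoded as G in transcript orientation
    alt_codon = "".join(alt)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        cons = "synonymous"
    elif ref_aa == "*" or alt_aa == "*":
        cons = "stop_altering"
    else:
        cons = "missense"
    return ref_codon, alt_codon, ref_aa, alt_aa, cons


def annotate_site(chrom: str, pos: int, strand: str, annotation: AnnotationIndex,
                  sequences: dict[str, str]) -> AnnotationRecord:
    """Region (by precedence across overlapping genes) and CDS consequence."""
    genes = annotation.genes_at(chrom, pos)
    best_region = "intergenic"
    best_gene: GeneModel | None = None
    rank = {r: i for i, r in enumerate(REGION_PRECEDENCE)}
    for g in genes:
        r = g.region_of(pos)
        if r is not None and rank[r] < rank[best_region]:
            best_region, best_gene = r, g
    rec = AnnotationRecord(chrom, pos, strand,
                           best_gene.gene_id if best_gene else None, best_region)
    if best_region == "CDS":
        seq = sequences[chrom]
        rec.ref_codon, rec.alt_codon, rec.ref_aa, rec.alt_aa, rec.consequence = \
            _cds_consequence(best_gene, pos, seq)
    return rec


def annotation_distribution(records: list[AnnotationRecord]) -> dict[str, float]:
    """Fraction of sites per region category (sums to 1)."""
    if not records:
        raise ValueError("no annotation records")
    counts: dict[str, int] = {}
    for r in records:
        counts[r.region] = counts.get(r.region, 0) + 1
    n = len(records)
    return {k: v / n for k, v in sorted(counts.items())}
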