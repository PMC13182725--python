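"""Gene models, annotation indexing and GTF round-trip.

Coordinates are 1-based inclusive throughout the in-memory model; BED output
elsewhere converts to 0-based half-open. A gene carries exactly one transcript
(isoform handling is out of scope for this pipeline): its exons, and optionally
a CDS span from which 5'/3' UTR intervals are derived in a strand-aware way.
"""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene: ordered disjoint exons plus an optional CDS.

    ``cds_start``/``cds_end`` are genomic bounds (inclusive) regardless of
    strand; the exonic length between them must be a multiple of three.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(f"{self.gene_id}: exon {s}-{e} inverted")
            if s <= prev_end:
                raise AnnotationError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(f"{self.gene_id}: partial CDS bounds")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start <= self.cds_end <= self.end):
                raise AnnotationError(f"{self.gene_id}: CDS outside gene span")
            if not self.in_exon(self.cds_start) or not self.in_exon(self.cds_end):
                raise AnnotationError(f"{self.gene_id}: CDS bounds not exonic")
            if len(self.cds_genomic_positions()) % 3 != 0:
                raise AnnotationError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def junctions(self) -> list[int]:
        """Genomic coordinates flanking each intron (donor/acceptor exonic bases)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.extend((e1, s2))
        return out

    def region_of(self, pos: int) -> str | None:
        """Region class of a genomic position within this gene, else ``None``."""
        if not self.contains(pos):
            return None
        if not self.in_exon(pos):
            return "intron"
        if not self.is_coding:
            return "noncoding_exon"
        if self.cds_start <= pos <= self.cds_end:
            return "CDS"
        if self.strand == "+":
            return "five_prime_UTR" if pos < self.cds_start else "three_prime_UTR"
        return "five_prime_UTR" if pos > self.cds_end else "three_prime_UTR"

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcript (5'→3') order."""
        if not self.is_coding:
            return []
        pos = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                pos.extend(range(lo, hi + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    def spliced_sequence_fwd(self, chrom_seq: str) -> str:
        """Exon-concatenated sequence in genome (forward) orientation."""
        return "".join(chrom_seq[s - 1 : e] for s, e in self.exons)

    def genomic_to_transcript_fwd(self, pos: int) -> int | None:
        """Offset of ``pos`` in the forward-orientation spliced sequence."""
        off = 0
        for s, e in self.exons:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
        return None


class AnnotationIndex:
    """Position lookups over a set of gene models on one reference."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        junc: dict[str, list[int]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
            junc.setdefault(g.chrom, []).extend(g.junctions())
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)
        self._junctions = {c: np.array(sorted(set(v)), dtype=np.int64) for c, v in junc.items()}

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return [g for g in self._by_chrom.get(chrom, []) if g.contains(pos)]

    def junction_distance(self, chrom: str, pos: int) -> int:
        """Genomic distance to the nearest annotated splice-junction boundary."""
        arr = self._junctions.get(chrom)
        if arr is None or arr.size == 0:
            return 10**9
        i = int(np.searchsorted(arr, pos))
        best = 10**9
        if i < arr.size:
            best = min(best, int(arr[i] - pos))
        if i > 0:
            best = min(best, int(pos - arr[i - 1]))
        return abs(best)

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _cds_frames(gene: GeneModel) -> list[tuple[int, int, int]]:
    """CDS chunks as (start, end, frame) in genomic order with GTF frame codes."""
    chunks = []
    for s, e in gene.exons:
        lo, hi = max(s, gene.cds_start), min(e, gene.cds_end)
        if lo <= hi:
            chunks.append((lo, hi))
    frames = []
    order = chunks if gene.strand == "+" else chunks[::-1]
    cum = 0
    for lo, hi in order:
        frames.append((lo, hi, (3 - cum % 3) % 3))
        cum += hi - lo + 1
    if gene.strand == "-":
        frames.reverse()
    return frames


def write_gtf(genes: list[GeneModel], path: str, source: str = "editome") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            base = [g.chrom, source]
            fh.write("\t".join(map(str, base + ["gene", g.start, g.end, ".", g.strand, ".", f'gene_id "{g.gene_id}";'])) + "\n")
            fh.write("\t".join(map(str, base + ["transcript", g.start, g.end, ".", g.strand, ".", attrs])) + "\n")
            for s, e in g.exons:
                fh.write("\t".join(map(str, base + ["exon", s, e, ".", g.strand, ".", attrs])) + "\n")
            if g.is_coding:
                for lo, hi, fr in _cds_frames(g):
                    fh.write("\t".join(map(str, base + ["CDS", lo, hi, ".", g.strand, fr, attrs])) + "\n")


def read_gtf(path: str) -> list[GeneModel]:
    """Parse a gene/transcript/exon/CDS GTF into gene models (one isoform each)."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes = []
    for grec in db.features_of_type("gene"):
        gid = grec.attributes["gene_id"][0]
        exons = sorted(
            (f.start, f.end)
            for f in db.region(region=(grec.seqid, grec.start, grec.end), featuretype="exon")
            if f.attributes["gene_id"][0] == gid
        )
        cds = [
            (f.start, f.end)
            for f in db.region(region=(grec.seqid, grec.start, grec.end), featuretype="CDS")
            if f.attributes["gene_id"][0] == gid
        ]
        cs = min(s for s, _ in cds) if cds else None
        ce = max(e for _, e in cds) if cds else None
        genes.append(GeneModel(gid, grec.seqid, grec.strand, tuple(exons), cs, ce))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
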