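"""Independent brute-force oracles used by the test suite.

Everything here is implemented naively and directly from the rule statements,
deliberately sharing no code with the package, so that agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# Filter-cascade oracle: literal transcription of the exclusion rules
# ---------------------------------------------------------------------------


def naive_homopolymer(seq: str, pos: int, min_len: int) -> bool:
    """Site inside or immediately adjacent to a run of >= min_len bases."""
    n = len(seq)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            # run occupies 1-based [i+1, j]; adjacency widens by one
            if i <= pos - 1 <= j - 1 or pos - 1 == i - 1 or pos - 1 == j:
                return True
        i = j
    return False


def naive_junction_distance(exon_lists: list[list[tuple[int, int]]], pos: int) -> int:
    best = 10**9
    for exons in exon_lists:
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            best = min(best, abs(pos - e1), abs(pos - s2))
    return best


def naive_cascade_verdict(site: dict, th) -> tuple[str, str | None, bool]:
    """(status, failed_rule, whitelisted) for one randomized site context.

    ``site`` keys: chrom, pos, seq, exon_lists, repeats, mito, in_dbsnp,
    in_whitelist, end_offsets [(d5, d3, rlen)], indels {0-based pos: support},
    depths, alts (per sample).
    """
    if site["in_whitelist"]:
        return "pass", None, True
    if naive_homopolymer(site["seq"], site["pos"], th.homopolymer_len):
        return "fail", "homopolymer", False
    if any(s <= site["pos"] <= e for s, e in site["repeats"]):
        return "fail", "simple_repeat", False
    if site["chrom"] == site["mito"]:
        return "fail", "mitochondrial", False
    if naive_junction_distance(site["exon_lists"], site["pos"]) <= th.splice_junction_dist:
        return "fail", "splice_junction", False
    for p0, support in site["indels"].items():
        if support >= 2 and abs(p0 - (site["pos"] - 1)) <= th.indel_dist:
            return "fail", "indel_proximity", False
    if site["end_offsets"]:
        surviving = 0
        for d5, d3, rlen in site["end_offsets"]:
            if min(d5, d3) >= math.floor(th.read_end_frac * rlen):
                surviving += 1
        if surviving < th.min_alt_depth:
            return "fail", "read_end", False
    if site["in_dbsnp"]:
        return "fail", "dbsnp", False
    covered = [(d, a) for d, a in zip(site["depths"], site["alts"]) if d >= th.min_depth]
    if not covered:
        return "indeterminate", None, False
    aafs = [a / d for d, a in covered]
    eps = 1e-9
    frac_hom = sum(a >= 1.0 - eps for a in aafs) / len(aafs)
    lo, hi = th.het_band
    frac_het = sum(lo - eps <= a <= hi + eps for a in aafs) / len(aafs)
    if frac_hom > th.germline_sample_frac or frac_het > th.germline_sample_frac:
        return "fail", "germline_pattern", False
    return "pass", None, False


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------


def midrank(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0  # average of 1-based ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_oracle(x, y) -> float:
    return pearson(midrank(list(x)), midrank(list(y)))


def bh_oracle(pvals) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = min(1.0, running)
    return q


def lrt_oracle(edited_a, total_a, edited_b, total_b) -> tuple[float, float]:
    """Pooled-vs-per-group binomial log-likelihoods and chi-square tail."""
    from scipy.stats import chi2

    def ll(es, ts, p):
        out = 0.0
        for e, t in zip(es, ts):
            if e:
                out += e * math.log(p)
            if t - e:
                out += (t - e) * math.log(1 - p)
        return out

    ea, ta, eb, tb = sum(edited_a), sum(total_a), sum(edited_b), sum(total_b)
    p_pool = (ea + eb) / (ta + tb)
    stat = 2 * (ll(edited_a, total_a, ea / ta) + ll(edited_b, total_b, eb / tb)
                - ll(list(edited_a) + list(edited_b), list(total_a) + list(total_b), p_pool))
    return stat, float(chi2.sf(stat, 1))


def pca_eig_oracle(X: np.ndarray):
    """Sample scores and variance fractions from the eigendecomposition of
    the (sites x sites is big; use samples-space) covariance of centered X."""
    Xc = X - X.mean(axis=1, keepdims=True)
    # Gram matrix over samples carries the same nonzero spectrum
    Gram = Xc.T @ Xc
    w, V = np.linalg.eigh(Gram)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0, None)
    V = V[:, order]
    scores = V * np.sqrt(w)
    frac = w / w.sum()
    return scores, frac


def overlap_oracle(sets: dict[str, set]):
    names = list(sets)
    universe = set().union(*sets.values())
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            regions[frozenset(combo)] = len(inside)
    return regions


# ---------------------------------------------------------------------------
# Codon-consequence oracle (hand-written genetic code)
# ---------------------------------------------------------------------------

_GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def consequence_oracle(gene, chrom_seq: str, pos: int):
    """(ref_aa, alt_aa, class) for an A->G edit at a CDS position, computed
    by rebuilding the coding sequence base by base."""
    cds_positions = []
    for s, e in gene.exons:
        for p in range(max(s, gene.cds_start), min(e, gene.cds_end) + 1):
            cds_positions.append(p)
    if gene.strand == "-":
        cds_positions = cds_positions[::-1]
    cds = ""
    for p in cds_positions:
        b = chrom_seq[p - 1]
        cds += _RC[b] if gene.strand == "-" else b
    i = cds_positions.index(pos)
    codon_start = (i // 3) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = list(ref_codon)
    alt_codon[i % 3] = "G"
    alt_codon = "".join(alt_codon)
    ref_aa = _GENETIC_CODE[ref_codon]
    alt_aa = _GENETIC_CODE[alt_codon]
    if ref_aa == alt_aa:
        klass = "synonymous"
    elif "*" in (ref_aa, alt_aa):
        klass = "stop_altering"
    else:
        klass = "missense"
    return ref_aa, alt_aa, klass
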