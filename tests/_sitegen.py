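"""Randomized candidate-site contexts for the cascade-equivalence check."""

import numpy as np

from editome.annotation import AnnotationIndex, GeneModel
from editome.discovery import FilterContext, VariantCall

SEQ_LEN = 600
POS = 300
BASES = "ACGT"


def make_random_site(rng: np.random.Generator):
    """Return (VariantCall, FilterContext, naive-site dict) for one context."""
    chrom = "chrM" if rng.random() < 0.1 else "chr1"
    seq = "".join(rng.choice(list(BASES), size=SEQ_LEN))
    if rng.random() < 0.3:  # maybe drop a homopolymer run near the site
        run_len = int(rng.integers(4, 8))
        offset = int(rng.integers(-run_len - 1, 2))
        start = POS - 1 + offset
        base = BASES[int(rng.integers(4))]
        seq = seq[:start] + base * run_len + seq[start + run_len :]
        seq = seq[:SEQ_LEN]

    # one two-exon gene whose intron boundary sits at a random distance
    a = POS + int(rng.integers(-40, 41))
    a = max(2, min(SEQ_LEN - 10, a))
    b = a + int(rng.integers(2, 30))
    exons = ((1, a), (b + 1, SEQ_LEN))
    gene = GeneModel("g1", chrom, "+", exons)

    repeats = []
    if rng.random() < 0.2:
        s = POS - int(rng.integers(0, 5))
        repeats.append((chrom, s, s + int(rng.integers(1, 30))))
    if rng.random() < 0.3:
        repeats.append((chrom, 10, 40))

    in_dbsnp = rng.random() < 0.2
    in_whitelist = rng.random() < 0.1

    n_alt_reads = int(rng.integers(2, 12))
    end_offsets = []
    for _ in range(n_alt_reads):
        rlen = 100
        d5 = int(rng.integers(0, rlen))
        end_offsets.append((d5, rlen - 1 - d5, rlen))

    indels = {}
    if rng.random() < 0.2:
        p0 = POS - 1 + int(rng.integers(-3, 4))
        indels[(chrom, p0)] = int(rng.integers(1, 4))

    depths = rng.integers(0, 60, size=6)
    mode = rng.random()
    alts = np.zeros(6, dtype=int)
    for i, d in enumerate(depths):
        if d == 0:
            continue
        if mode < 0.25:        # homozygous-looking
            alts[i] = d
        elif mode < 0.5:       # heterozygous-looking
            alts[i] = int(round(d * rng.uniform(0.38, 0.62)))
        else:                  # editing-like
            alts[i] = int(rng.integers(0, d + 1))

    call = VariantCall(chrom, POS, "A", "G", int(depths.sum()), int(alts.sum()),
                       [(int(d), int(a_)) for d, a_ in zip(depths, alts)],
                       end_offsets)
    ctx = FilterContext(
        sequences={chrom: seq},
        annotation=AnnotationIndex([gene]),
        mito_chrom="chrM",
        repeat_intervals=list(repeats),
        dbsnp={(chrom, POS)} if in_dbsnp else set(),
        whitelist={(chrom, POS)} if in_whitelist else set(),
        indels=dict(indels),
    )
    naive = {
        "chrom": chrom, "pos": POS, "seq": seq, "exon_lists": [list(exons)],
        "repeats": [(s, e) for c, s, e in repeats], "mito": "chrM",
        "in_dbsnp": in_dbsnp, "in_whitelist": in_whitelist,
        "end_offsets": end_offsets,
        "indels": {p0: n for (c, p0), n in indels.items()},
        "depths": depths.tolist(), "alts": alts.tolist(),
    }
    return call, ctx, naive
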