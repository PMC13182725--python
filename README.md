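# editome

Discovery and analysis of adenosine-to-inosine (A-to-I) RNA editing from
bulk RNA-seq alignments, built for retina-style study designs: several
biological replicates per condition (e.g., wild-type versus retinal-
degeneration mouse models), where global editing activity tracks the
expression of the ADAR deaminases.

Inosine base-pairs like guanosine, so A-to-I editing appears in reads as
A→G mismatches (T→C on the genomic minus strand). The hard part is telling
editing apart from germline variation, sequencing error and alignment
artifacts. This package implements that discrimination as a testable
pipeline, together with a ground-truthed simulator so every stage can be
validated without any external data:

- **`editome.simulate`** — generates a toy genome with spliced multi-exon
  genes, plants true editing sites whose per-sample level is
  `activity_s × beta(α, β)` (a latent per-sample deaminase activity scaling
  a per-site base level), heterozygous/homozygous SNPs, and three classes of
  artifact-prone contaminant mismatches (homopolymer-internal,
  splice-junction-proximal, read-end-biased), then writes per-sample SAM
  alignments, FASTA/GTF/VCF/BED/TSV artifacts and full truth tables.
- **`editome.discovery`** — VarScan-style candidate calling (base quality
  ≥ 25, depth ≥ 10, alternate depth ≥ 2, alternate allele frequency ≥ 1%),
  strand-aware A-to-I orientation, and the high-confidence filter cascade:
  homopolymer (≥ 5 nt), simple repeat, mitochondrial chromosome, ≤ 6 nt from
  a splice junction, ≤ 1 nt from an indel, mismatches confined to the
  terminal 4% of reads, known-SNP catalogue membership, and a germline AAF
  pattern (AAF = 100% or 40–60% in > 90% of covered samples), with a
  known-editing whitelist exempting catalogued sites; finally sites are
  retained only with editing level ≥ 1% in ≥ 2 samples.
- **`editome.quantify`** — editing levels (edited/total reads), TPM gene
  expression, and region/consequence annotation (CDS > 3′UTR > 5′UTR >
  noncoding exon > intron > intergenic; codon substitution with A→G in
  transcript orientation).
- **`editome.stats`** — differential editing via a binomial GLM (logit
  link) likelihood-ratio test of a group factor against an intercept-only
  null, with Benjamini–Hochberg FDR; mid-rank Spearman editing–expression
  correlation; per-sample overall-editing summaries; Welch/pooled t-tests;
  PCA of the editing matrix; Venn-style set overlaps.
- **`editome.pipeline`** — a config-driven end-to-end driver
  (`run_pipeline`, `demo_end_to_end`) whose outputs are byte-identical for a
  fixed config and seed.

The differential test: for site *i* with per-sample counts
(edited<sub>s</sub>, total<sub>s</sub>) and groups *g(s)*, the full model
fits one edited fraction per group, the null a single pooled fraction, and

&nbsp;&nbsp;Λ = 2(ℓ̂<sub>full</sub> − ℓ̂<sub>null</sub>) ~ χ²<sub>G−1</sub>

under the null, where G is the number of groups with covered samples.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_discover_sites.py
```

generates the standard fixture (2 × 100 kb chromosomes, 6 samples in 2
groups, 200 true sites, 100 het + 50 hom SNPs, 30 contaminants, 50×
coverage, 0.1% error, seed 1) and prints the recovery scorecard:

```
               metric   value
           candidates 477.000
      a_to_i_oriented 247.000
      high_confidence 191.000
       true_positives 191.000
            precision   1.000
               recall   0.955
   germline_survivors   0.000
contaminant_survivors   0.000
```

All 191 reported sites are planted truth (precision 1.0); 191/200 planted
sites are recovered (recall 0.955 — the misses are sites whose simulated
level fell below the 1%-in-2-samples retention rule); every planted SNP and
artifact was removed, with the attrition table showing which rule caught
what. The remaining drivers (`03`–`05`) quantify level-estimation accuracy
versus depth, calibrate the LRT (type-I error ≈ 0.054 at α = 0.05, power
0.995 for a 0.10 vs 0.30 shift), and recover the planted activity gradient
(Spearman ρ = 1.0 between per-sample overall editing and deaminase
activity; ρ ≈ 0.97 against the activity-tracking enzyme gene's TPM).
Tables land under `results/`; simulated data under `scratch/`.

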