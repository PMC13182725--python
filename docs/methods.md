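# Methods

## The discrimination problem

A-to-I editing is read out as A→G (or minus-strand T→C) mismatches in
RNA-seq alignments. The same signal is produced by germline SNPs,
sequencing error and systematic alignment artifacts, so the pipeline's core
is a calling-and-exclusion procedure whose every rule targets a specific
confounder:

| rule | targets | default |
|---|---|---|
| base quality | miscalls | ≥ 25 to count a base |
| depth / alt depth / AAF | noise floor | ≥ 10 / ≥ 2 / ≥ 1% |
| homopolymer | polymerase slippage | run ≥ 5 nt, site inside or adjacent |
| simple repeat | ambiguous mapping | user-supplied mask intervals |
| mitochondrial | heteroplasmy/NUMT-like signals | chromosome name |
| splice junction | spliced-alignment edge errors | ≤ 6 nt from a junction |
| indel proximity | realignment wobble | ≤ 1 nt from an indel seen in ≥ 2 reads |
| read end | adapter/chemistry artifacts | mismatch within terminal 4% of the read |
| known SNP catalogue | germline variation | membership excludes |
| germline AAF pattern | un-catalogued genotypes | AAF = 100% or 40–60% in > 90% of covered samples |

A known-editing whitelist exempts a site from every rule (catalogued sites
are kept even if, e.g., they coincide with a SNP record). Surviving A-to-I
sites are retained only with editing level ≥ 1% in at least two samples.
Editing level is edited/total qualifying reads, undefined (masked) when
depth < 10.

Interpretation choices where the rules admit more than one reading:

- **Read-end rule.** Implemented at read level: alternate-supporting reads
  with the mismatch within `floor(0.04 × read length)` bases of either end
  are discarded and the call fails if fewer than 2 supporters survive
  (pooled across samples). Level estimates keep the full qualifying counts;
  re-estimating levels from the surviving reads would bias them low by the
  discarded fraction.
- **Homopolymer adjacency.** The site may be inside *or immediately
  adjacent to* the run, because slippage artifacts concentrate at run
  flanks.
- **Junction distance** is genomic distance to the nearest annotated exon
  boundary of a multi-exon transcript (annotation-derived, deterministic),
  not read-derived.
- **"Over 90% of samples"** is strict (> 0.90) and computed among covered
  samples only (depth ≥ 10); uncovered samples carry no genotype evidence.
- **Multi-allelic columns** keep the pooled-majority alternate only.
- **Calling thresholds** are applied per sample; a site is a candidate if
  any one sample qualifies, and pooled counts are carried on the merged
  call. Ambiguous-strand sites (genes on both strands where either
  orientation would be A-to-I) are dropped and counted.

## Statistics

**Differential editing.** Binomial GLM with logit link; the full model is
the group factor, the null an intercept. Because the factor saturates the
group means, both MLEs are closed-form edited fractions (per group and
pooled), and the LRT statistic 2(ℓ̂f − ℓ̂n) is referred to χ² with
(covered groups − 1) df. Samples below the depth floor are excluded;
groups losing all samples are dropped with the df adjusted; fewer than two
covered groups skips the test with a recorded reason. The family is plain
binomial: replicate-to-replicate overdispersion beyond binomial sampling is
not modelled, which anti-conservatively inflates the test when biological
replicates truly disagree — a known limitation, acceptable here because the
generator's replicates share their group's activity. A differentially
edited site (DES) is q < 0.05 after Benjamini–Hochberg (step-up, NaN
p-values propagate and do not count toward m).

**Correlation.** Spearman as Pearson on mid-ranks (average ranks on ties);
p by exact permutation for n ≤ 9 and the t approximation above. Pairs need
≥ 5 covered samples (configurable); zero-variance vectors return an
undefined marker and are excluded.

**Overall editing** per sample is reported both as the unweighted mean of
defined site levels and as the read-weighted pooled fraction
(Σ edited / Σ total); the two can diverge when coverage and level are
correlated, so both are emitted.

**PCA.** Masked cells are imputed with the site mean (complete-case
deletion degenerates on sparse matrices), sites centered, then SVD; sample
scores are Vᵀ-columns scaled by singular values, variance fractions are
s²/Σs². Component signs are arbitrary.

**Expression.** TPM from raw counts with gene length = union of exonic
bases (matching how counts aggregate across isoforms); columns sum to 1e6.
Group comparisons use Welch's t by default (pooled-variance optional).

**Annotation.** Region precedence CDS > 3′UTR > 5′UTR > noncoding exon >
intron > intergenic across all overlapping transcripts — a deliberate,
fixed approximation of consequence-ranking practice. CDS consequences
substitute G at the edited position in transcript orientation (inosine is
decoded as guanosine) and translate with the standard code; stop gain and
stop loss are folded into one `stop_altering` class.

## The simulator

The generator emulates the statistical structure the analysis assumes, not
sequencing physics. Per sample s, a latent deaminase activity
a_s ∈ (0, 1] scales every true site's base level b_i ~ beta(α, β) (defaults
α = 2, β = 5, a right-skewed editome); the default activities are graded
within and between groups (control 0.54/0.60/0.66, model 0.84/0.90/0.96),
mirroring group-wise differences in editing-enzyme expression. Reads
(default 100 nt, 50× mean exonic depth, Poisson per gene with log-normal
σ = 0.5 expression factors) are drawn from spliced transcripts and placed
back with gapped M/N alignments, so junction proximity is meaningful. The
gene named `Adar` additionally scales its expression with a_s, giving the
editing–enzyme-expression correlation a planted counterpart. Het/hom SNPs
alternate with probability 0.5/1.0 in every sample (an inbred-strain
genotype); contaminants mismatch at 25% of reads, except the read-end class
whose mismatches only ever occur in the terminal 4% of a read. Independent
per-base errors at 0.1% substitute a uniformly random other base. A fixed
seed makes every emitted file byte-identical.

What it deliberately does **not** emulate — and what passing tests
therefore cannot show: intronic coverage (reads come from spliced
transcripts, so true sites are exonic and the intron region class is
exercised only through the annotator); PCR/optical duplicates (the
pipeline contract assumes deduplicated input); realistic base-quality
error profiles (qualities are constant Q37; the quality filter is tested on
hand-built alignments); indels; stranded library protocols; mapping
ambiguity beyond the planted artifact classes. Real-data performance on
those axes is untested by construction.

Coordinates are 1-based inclusive internally; BED output is 0-based
half-open.

## Problem sizes and fixtures

The standard fixture is 2 chromosomes × 100 kb (one mitochondrial), 6
samples in 2 groups, 200 true sites, 100 het + 50 hom SNPs, 30 contaminants
at 50×; the analysis scripts and the reproduction script also use a 30 kb
fixture for the 20×/50×/200× estimation sweep, count-level simulations
(2,000 null and 1,000 shifted replicates) for LRT calibration, and a
12-sample fixture with activities graded 0.35–0.95 for the
activity-recovery check. These sizes give stable estimates while keeping a
full run in tens of seconds on one CPU.

## Known limitations

- Binomial-only differential model (no beta-binomial overdispersion
  option).
- One isoform per gene; isoform-aware annotation and quantification are out
  of scope.
- The germline-pattern rule cannot distinguish true ~50% editing from
  heterozygosity without DNA evidence; such sites are sacrificed by design,
  and the simulator's graded activities keep that loss small.
- VarScan's auxiliary filters (strand bias, p-value) are not reproduced;
  the four explicit thresholds are the contract.
- Hyper-editing rescue (clustered mismatches) is not attempted.
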