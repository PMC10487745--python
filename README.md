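# famsv

Family-based structural-variant candidate discovery for
neurodevelopmental-disorder cohorts.

Multiplex families segregating autism spectrum disorder (ASD) and
related language phenotypes carry large structural variants — array
CNVs, sequencing-detected SVs and mobile-element insertions (MEIs) —
that may explain affection status. `famsv` implements the full desk
analysis for such a cohort:

* **Pedigrees and phenotypes.** An extended PED dialect carries three
  binary phenotypes per person (ASD, oral language impairment LI,
  reading impairment RI). Analyses run on ASD and the union phenotypes
  LI\* = ASD∨LI and RI\* = ASD∨RI, so every ASD patient belongs to all
  three groups.
* **CNV pipeline.** Dual-caller array CNV calls are QC'd (length in
  [10 kb, 7.5 Mb], ≥5 probes, log Bayes factor ≥10 for the
  Objective-Bayes caller, sex chromosomes excluded), merged per sample
  at ≥70% *reciprocal overlap*

  > RO(a, b) = min(o/|a|, o/|b|), with o the overlap length,

  taking outermost breakpoints, then clustered across samples into
  cohort loci with integer copy-number genotypes (CN0–CN4). Samples
  with an excess CNV count (> median + 1.5·IQR) are excluded.
* **SV/MEI pipeline.** MEI loci are screened for sample no-call rate,
  locus missingness (>5%), Hardy–Weinberg disequilibrium
  (1-df chi-square p < 1e-20) and MELT-style evidence (ASSESS ≥ 3,
  FILTER PASS/rSD, split reads > 2); the gSV and MEI call sets are then
  merged SURVIVOR-style (both breakpoints within 100 bp, SV type and
  strand agreement, within individuals first and then across the
  cohort).
* **Segregation.** Each variant is tested per family and phenotype
  against strict Mendelian models — de novo, autosomal
  recessive/dominant and their X-linked counterparts — in the spirit of
  GEMINI's "strict" tools (copy numbers map CN1/CN3 → het, CN0/CN4 →
  hom-alt; a missing genotype fails a model rather than relaxing it).
* **Prioritization.** After benign-region exclusion and
  exonic/intronic/intergenic partitioning, two streams produce
  candidates: an allele-frequency-focused stream (brain TPM > 5 in
  GTEx/BrainSpan/HDBR, sample AF ≤ 5%, population AF ≤ 5%, plus
  False-DeNovo and known-NDD-gene filters for intronic variants) and an
  eQTL-focused stream (brain-tissue eQTL with CAVIAR probability > 0.1
  and rank ≤ 5 for SVs, or MEI-origin causal in ≥1 brain tissue, target
  gene brain-expressed). CNV candidates additionally require an
  affected carrier, a protein-coding gene, and ≤2 cohort carriers for
  de novo calls.
* **Reporting.** Candidates aggregate to per-phenotype gene lists with
  family coverage, summary tables, and an interaction subgraph from
  user-supplied edge lists.
* **Synthetic cohorts.** `famsv.simulate` generates a complete study —
  pedigrees, dual-caller CNV tables, gSV/MEI VCFs, every annotation
  sidecar — with planted variants per inheritance pattern and per
  pipeline class, benign/common background, caller breakpoint jitter,
  and a machine-readable truth table, so each stage is testable without
  access-controlled data.

## Worked example

Generate a synthetic 50-family study and run both pipelines:

```text
$ famsv simulate --seed 3 --out demo_study
wrote 13 files to demo_study (187 samples, 815 truth rows)

$ famsv run demo_study
ASD: 25 candidate genes, 25 candidate variants
LIstar: 25 candidate genes, 25 candidate variants
RIstar: 25 candidate genes, 25 candidate variants
unique genes: 25; family coverage: 72%

$ famsv ped-validate demo_study/cohort.ped
OK: 50 families, 187 individuals
```

The 25 ASD candidate variants are exactly the 25 planted candidates (5
per pipeline class: cnv, af_exonic, af_intronic, eqtl_intronic,
eqtl_intergenic); the truth table `demo_study/truth.tsv` records each
planted variant's class, inheritance pattern, carriers, target gene and
expected survival. "Family coverage: 72%" is the share of the 50
families contributing at least one candidate gene.

The same drivers are available as library functions
(`famsv.pipeline.run_study`, `run_cnv_pipeline`, `run_sv_pipeline`)
returning per-phenotype candidate and gene lists.

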