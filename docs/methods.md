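# Methods

## Cohort model and phenotypes

Individuals carry three raw binary phenotypes — ASD, oral language
impairment (LI) and reading impairment (RI) — coded 1/2/0(-9) in an
8-column PED dialect (family, individual, father, mother, sex, ASD,
LI, RI). Analyses run on ASD and the union phenotypes LI\* = ASD∨LI
and RI\* = ASD∨RI. A union flag is true when any contributor is true,
missing when no contributor is true and at least one is untested, and
false otherwise; a confirmed ASD diagnosis therefore suffices for
membership in both unions regardless of untested LI/RI. Individuals
with a missing phenotype are invisible to segregation logic: they can
neither support nor violate a model.

## CNV pipeline

Single-caller calls (two callers per array batch: an HMM caller and an
Objective-Bayes caller reporting a max log Bayes factor) pass QC when
10 kb ≤ length ≤ 7.5 Mb, n_probes ≥ 5, the Bayes factor is ≥ 10
(Objective-Bayes caller only; both boundaries inclusive on the keep
side), and the call is autosomal. Coordinates are 1-based inclusive
throughout; VCF emission follows VCF POS/END with SVLEN = END − POS
(htslib derives END from SVLEN for symbolic alleles).

Merging uses reciprocal overlap RO(a,b) = min(o/|a|, o/|b|) with the
threshold at exactly 0.70 ("at least 70%" merges). Within a
(batch, sample, chromosome, variant class) group, calls cluster by
single linkage over pairwise RO ≥ 0.70 — a nested call covering <70%
of its host stays separate — and the merged call takes the outermost
breakpoints; its copy number comes from the best-supported call (most
probes, then leftmost, then caller A). Deletions (CN<2) and
duplications (CN>2) are distinct alleles and never merge.

Per-sample CNV counts (after within-sample merging) feed outlier
exclusion at median + 1.5·IQR, computed once with linear-interpolation
quartiles (`numpy.percentile`; the convention is configurable because
Tukey hinges give different cutoffs on small cohorts).

Cross-sample locus construction clusters the per-sample merged spans by
the same single-linkage RO ≥ 0.70 rule within (chromosome, class), with
one refinement: two spans of the *same* sample are never linked
directly, so the within-sample merge decisions are final. Transitive
chaining through another sample's span can still join them into one
locus — inherent to any single-linkage cohort locus definition. The
locus takes outermost breakpoints and a genotype map of integer copy
numbers; a sample with no call at a locus is assumed CN2.

## SV/MEI pipeline

MEI QC runs in three layers: (1) samples whose no-call rate across MEI
loci exceeds 20% (default; configurable — this emulates removing a
poorly-called sequencing batch) are dropped cohort-wide; (2) loci with
missingness >5% or a Hardy–Weinberg p-value < 1e-20 are removed. The
HWE test is a 1-df chi-square against genotype proportions expected
from the observed allele frequency; a conditional exact test is
available behind `exact=True`. An all-missing locus has no defined HWE
p and passes that filter by convention, though the missingness rule
removes it first. (3) MEI insertions additionally need ASSESS ≥ 3,
FILTER ∈ {PASS, rSD} and split reads > 2 (interpreted strictly as ≥3);
reference-ME deletions are exempt from the insertion evidence fields.

gSV/MEI merging is two-step: records first link when they represent
the same event in the same individual (share a carrier, both
breakpoints within 100 bp, same coarse SV type — MEI subtypes count as
insertions, the subtype retained as annotation — and compatible strand,
unknown matching anything); the resulting loci then collapse across
individuals under the same distance rule. The merged record keeps the
coordinates of the contributor with the most carriers (ties: leftmost,
gSV before MEI), genotypes union across contributors, and a genotype
conflict resolves to the gSV call with a logged warning.

## Strict segregation models

Genotypes reduce to a biallelic class: CN2→ref, CN1/CN3→het,
CN0/CN4→hom-alt (copy numbers above 4 are an error); sequence-SV
genotypes map directly; an absent CNV call is reference. On chromosome
X a heterozygous male call is coerced to hemizygous-alt with a warning.

Per family and phenotype:

* **de novo** — an affected child is heterozygous (on chrX: a carrier,
  allowing hemizygous sons), both parents are reference and not
  affected, and no unaffected individual carries the allele. The
  carrier clause is evaluated cohort-wide for CNV loci (consistent
  with the separate ≤2-carrier cohort rule) and family-wide for
  sequence SVs; both scopes are configurable.
* **autosomal recessive** — all known parents unaffected heterozygous
  carriers, the affected children homozygous-alt (all affected
  children of the same parent pair, strict reading, configurable). The
  X-linked counterpart expects a heterozygous unaffected mother and a
  reference unaffected father, with hemizygous affected sons.
* **autosomal dominant** — every affected family member carries the
  allele, at least one affected child has an affected parent, no
  affected child lacks one, and no unaffected member carries.

A missing genotype in any individual a model *requires* fails that
model; a missing genotype in a peripheral unaffected individual cannot
demonstrate carriage and does not violate the carrier clauses. The
consequence, verified by the test suite, is strictness: under genotype
noise a planted variant is either recovered with its true pattern or
dropped — never reassigned. Autosomal models are evaluated only on
autosomes and X-linked models only on chrX (the CNV path disables
X-linked models entirely since sex chromosomes are excluded upstream).

## Prioritization

Benign exclusion is class-specific (gain/loss/ins/inv): CNV loci match
a benign region at RO ≥ 0.70; sequence SVs match when both breakpoints
lie within 100 bp of a region's breakpoints (the 100 bp tolerance is
this package's choice).

Location partitioning: intergenic = no overlapped gene; intronic =
overlaps a gene, touches no exon, and both breakpoints sit in one
intron; anything else overlapping a gene is exonic.

The CNV candidate filters apply in order: affected carrier,
protein-coding gene-body overlap (exon-only is configurable),
non-empty segregation, the de novo ≤2-cohort-carrier rule (the de novo
label is withdrawn rather than the variant when other patterns
remain), and a brain-expression gate — at least one overlapped gene
with TPM > 5 in any of three expression resources (GTEx, BrainSpan,
HDBR; the gate uses the maximum across sources).

The AF-focused stream (exonic and intronic) keeps variants in
brain-expressed genes with sample AF ≤ 5% and population AF ≤ 5%; both
boundaries are inclusive on the keep side ("higher than 5%" excludes),
the sample AF denominator excludes missing genotypes, and a variant
absent from the population references is treated as rare (gnomAD-absent
SVs plausibly are; configurable). Population AF lookups try the MEI
reference first for MEIs, then the SV reference, taking the nearest
entry of the same SV class within 100 bp (distance ties resolve to the
smaller position). Intronic variants additionally face the False-DeNovo
filter (de novo in more than one affected individual) and must overlap
a known NDD gene.

The eQTL-focused stream (intronic and intergenic) matches variants to
eQTL records within 100 bp: sequence SVs need a brain-tissue record
with lead variant type SV, CAVIAR probability > 0.1 and rank ≤ 5; MEIs
need a brain-tissue MEI-origin record causal in ≥1 tissue. Candidate
genes are the eQTL target genes passing the TPM gate, not the host
gene.

## Reporting

Gene aggregation is a projection with union semantics over phenotypes,
pipelines and families, so |A∪B| = |A|+|B|−|A∩B| holds for pipeline
cross-tabulations. Family coverage is 100·(covered families)/(cohort
families), rounded to the nearest integer percent. The interaction
subgraph is induced on candidate genes from two-column edge lists;
edges present in several sources are labeled "M", isolated candidates
are omitted.

## Synthetic-cohort generator

The generator emulates a multiplex family study at its default scale:
50 families (40% trios, 40% quads, 20% three-generation extended
families; ~190–230 individuals), split into dominant-type families
(affected mother and first child) and recessive/de-novo-type families
(affected first child, unaffected parents). 100 variants are planted
per inheritance pattern (600 sequence SVs, each realizing exactly one
strict model in one family) and 5 candidates per pipeline class:
de novo CNVs spanning a brain-expressed coding gene, rare de novo
exonic/intronic SVs (intronic ones in known-NDD genes; half emitted as
Alu insertions to exercise the MEI path), and common
(AF 0.15–0.30, Hardy–Weinberg-drawn) intronic/intergenic SVs with
matching brain-eQTL records, segregating dominantly in one clean
family. Background layers guarantee every non-candidate fails at least
one filter by construction: per-sample benign CNVs (4–10 draws from a
40-locus pool mirrored in the benign-region sidecar), common SVs and
MEIs (beta(2,5) allele-frequency spectrum clipped to [0.02, 0.9];
Alu-dominant 70/20/10 subtype mix; ~30% of insertions also emitted as
jittered gSV duplicates to exercise cross-set merging) placed
intergenic or in non-brain genes, plus MEI loci violating exactly one
QC rule each and CNV calls violating each array-QC rule. Dual-caller
CNV emission jitters each breakpoint by up to 5% of length (keeping
reciprocal overlap ≥ ~0.82, safely above the merge threshold) and
benign calls by 2%.

Planted truth is defined with respect to the ASD phenotype; sprinkled
LI/RI-only affection (5% of ASD-unaffected individuals each) makes the
union phenotypes non-degenerate without touching ASD truth. What the
generator does **not** emulate: Mendelian transmission of common
background variants within families (genotypes are drawn per
individual), linkage disequilibrium, realistic breakpoint sequence
context, array intensity noise, and caller-specific false-negative
structure. Passing recovery tests therefore demonstrate the logic of
QC, merging, segregation and filtering — not performance on real
arrays or sequencing.

Determinism: one `numpy` generator seeded from the config/CLI seed
drives all draws in fixed construction order, so identical
(config, seed) reproduces byte-identical files; genotype perturbation
uses its own child seed.

## Numerical and degenerate-input choices

* Quartiles: linear interpolation; the outlier threshold is computed
  once, with no re-iteration after exclusion.
* Boundary semantics are uniformly inclusive on the keep side: RO
  exactly 0.70 merges, Bayes factor exactly 10 survives, sample AF
  exactly 5% survives, split reads exactly 3 survive.
* HWE: chi-square terms only over cells with positive expectation;
  monomorphic loci return p = 1; the exact test sums configurations
  with probability ≤ observed (log-gamma arithmetic, with a 1e-12
  slack against round-off).
* Tie-breaks are total orders (position, then identifier), making
  merging permutation-invariant and outputs deterministic.
* Degenerate inputs: empty candidate lists yield empty tables; a
  family without a complete trio classifies as no pattern with a
  warning; an all-missing locus is handled as described above.

## Problem sizes

The test suite and acceptance script run the generator at its default
scale (50 families, 600 pattern variants, 25 candidates, ~500
background variants) — the full recovery experiment completes in well
under a minute — plus 1,000 random interval sets for the merge oracle
and all 1,326 genotype compositions of n = 50 for the HWE oracle.

## Known limitations

* The segregation models are deliberately strict deterministic rules;
  no probabilistic transmission, phasing or LOD support.
* X-linked recessive affected daughters are effectively unreachable
  under the strict unaffected-parent clause (an unaffected carrier
  father cannot be hemizygous); only affected sons are modeled.
* Cross-sample CNV locus identity is single-linkage and can chain
  loosely overlapping events across many samples into wide loci.
* Gene identity is by symbol string; supply consistent symbols across
  sidecars (an alias map can be applied upstream).
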