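"""Candidate-variant prioritization.

Two families of filters sit downstream of segregation analysis:

* the CNV pipeline — affected carrier, protein-coding overlap,
  segregation, a <=2-carrier rule for de novo calls, and a brain
  expression gate (some overlapped gene with TPM > 5);
* the sequence-SV pipelines — after benign-region exclusion and
  location partitioning (exonic / intronic / intergenic), an
  allele-frequency-focused stream (TPM, sample AF <= 5%, population
  AF <= 5%, plus False-DeNovo and known-NDD filters for intronic
  variants) and an eQTL-focused stream (brain eQTL evidence for a
  brain-expressed target gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

from .annotations import AnnotationDb, BenignSets, EqtlTable, PopAfTable
from .cnv import CnvLocus, VariantClass
from .core import GenotypeClass, reciprocal_overlap
from .pedigree import Cohort, Phenotype
from .segregation import (
    InheritancePattern,
    SegregatedVariant,
    classify_genotype,
)
from .svmei import SvRecord, svtype_class

log = logging.getLogger(__name__)

MAX_SAMPLE_AF = 0.05
MAX_POPULATION_AF = 0.05
BENIGN_CNV_RO = 0.70
BENIGN_SV_DIST = 100

LOCATION_EXONIC = "exonic"
LOCATION_INTRONIC = "intronic"
LOCATION_INTERGENIC = "intergenic"

PIPELINE_CNV = "cnv"
PIPELINE_AF_EXONIC = "af_exonic"
PIPELINE_AF_INTRONIC = "af_intronic"
PIPELINE_EQTL_INTRONIC = "eqtl_intronic"
PIPELINE_EQTL_INTERGENIC = "eqtl_intergenic"


@dataclass
class CandidateVariant:
    variant: object
    variant_id: str
    phenotype: Phenotype
    location: str
    pipeline: str
    genes: List[str]
    families: FrozenSet[str]
    patterns: Dict[str, FrozenSet[InheritancePattern]]
    sample_af: float
    population_af: Optional[float] = None
    tissue_count: Optional[int] = None
    scores: Dict[str, float] = field(default_factory=dict)


def _benign_class(variant) -> str:
    if isinstance(variant, CnvLocus):
        return "loss" if variant.variant_class == VariantClass.DELETION else "gain"
    cls = svtype_class(variant.svtype)
    return {"DEL": "loss", "DUP": "gain", "INS": "ins", "INV": "inv"}[cls]


def filter_benign(
    variants: Iterable,
    benign_sets: BenignSets,
    *,
    cnv_ro: float = BENIGN_CNV_RO,
    sv_dist: int = BENIGN_SV_DIST,
) -> List:
    """Drop variants matching a benign region of their own class.

    CNV loci match at >=70% reciprocal overlap; sequence SVs match when
    both breakpoints lie within 100 bp of a benign region's breakpoints.
    """
    kept = []
    for variant in variants:
        regions = benign_sets.get(_benign_class(variant), [])
        if isinstance(variant, CnvLocus):
            hit = any(
                chrom == variant.chrom
                and reciprocal_overlap(variant.interval, (chrom, s, e)) >= cnv_ro
                for chrom, s, e in regions
            )
        else:
            hit = any(
                chrom == variant.chrom
                and abs(variant.pos - s) <= sv_dist
                and abs(variant.end - e) <= sv_dist
                for chrom, s, e in regions
            )
        if hit:
            log.debug("benign drop %s", getattr(variant, "record_id", None)
                      or getattr(variant, "locus_id", "?"))
        else:
            kept.append(variant)
    return kept


def partition_by_location(variant, annotation: AnnotationDb) -> str:
    """Exonic / intronic / intergenic location of a variant.

    Intergenic: no overlapped gene.  Intronic: overlaps a gene, touches no
    exon, and both breakpoints fall inside one intron of some overlapped
    gene.  Everything else that overlaps a gene is exonic (touches an exon
    or spans multiple introns/exons).
    """
    start = variant.start if isinstance(variant, CnvLocus) else variant.pos
    end = variant.end
    genes = annotation.overlapping_genes(variant.chrom, start, end)
    if not genes:
        return LOCATION_INTERGENIC
    for g in genes:
        if any(es <= end and ee >= start for es, ee in g.exons):
            return LOCATION_EXONIC
    for g in genes:
        for is_, ie in g.introns():
            if is_ <= start and end <= ie:
                return LOCATION_INTRONIC
    return LOCATION_EXONIC


def lookup_population_af(
    variant: SvRecord,
    mei_ref: Optional[PopAfTable],
    sv_ref: Optional[PopAfTable],
    max_dist: int = 100,
) -> Optional[float]:
    """Population AF from the MEI reference (MEIs first), else the SV
    reference, nearest entry within 100 bp; ``None`` when unmatched."""
    if variant.is_mei and mei_ref is not None:
        af = mei_ref.lookup(variant.chrom, variant.pos, variant.svtype, max_dist)
        if af is not None:
            return af
    if sv_ref is not None:
        return sv_ref.lookup(variant.chrom, variant.pos, variant.svtype, max_dist)
    return None


def _cnv_sample_af(locus: CnvLocus, cohort: Cohort) -> float:
    alt = 0
    n = 0
    for sid in cohort.sample_ids:
        g = classify_genotype(locus, sid)
        n += 2
        if g == GenotypeClass.HET:
            alt += 1
        elif g == GenotypeClass.HOM_ALT:
            alt += 2
    return alt / n if n else 0.0


def prioritize_cnvs(
    segregated: Sequence[SegregatedVariant],
    cohort: Cohort,
    phenotype: Phenotype,
    annotation: AnnotationDb,
    *,
    max_denovo_carriers: int = 2,
    scores: Optional[Dict[str, Dict[str, float]]] = None,
) -> List[CandidateVariant]:
    """CNV candidate filters, applied in order.

    1. carried by at least one affected individual;
    2. overlaps a protein-coding gene;
    3. satisfies a strict inheritance pattern (guaranteed upstream);
    4. de novo calls present in more than two cohort individuals are
       dropped (the de novo label is withdrawn when other patterns remain);
    5. at least one overlapped gene expressed in brain (TPM > 5).
    """
    counts = {"input": len(segregated)}
    stage1 = []
    for sv in segregated:
        locus: CnvLocus = sv.variant  # type: ignore[assignment]
        affected_carrier = any(
            ind.affected(phenotype) is True
            and classify_genotype(locus, ind.individual_id).is_carrier
            for ind in cohort.individuals()
        )
        if affected_carrier:
            stage1.append(sv)
    counts["affected_carrier"] = len(stage1)

    stage2 = []
    for sv in stage1:
        genes = [
            g for g in annotation.overlapping_genes(*sv.variant.interval)
            if g.is_protein_coding
        ]
        if genes:
            stage2.append((sv, genes))
    counts["protein_coding"] = len(stage2)

    stage3 = [(sv, genes) for sv, genes in stage2 if sv.patterns]
    counts["segregation"] = len(stage3)

    stage4 = []
    dn = {InheritancePattern.DE_NOVO, InheritancePattern.X_LINKED_DE_NOVO}
    for sv, genes in stage3:
        assignments = sv.assignments
        if sv.patterns & dn:
            n_carriers = len(sv.variant.carriers())
            if n_carriers > max_denovo_carriers:
                assignments = {
                    fam: pats - dn for fam, pats in sv.assignments.items()
                    if pats - dn
                }
                if not assignments:
                    continue
        stage4.append((sv, genes, assignments))
    counts["de_novo_carriers"] = len(stage4)

    candidates = []
    for sv, genes, assignments in stage4:
        if not any(g.is_brain_expressed for g in genes):
            continue
        locus = sv.variant
        score_map = (scores or {}).get(sv.variant_id, {})
        candidates.append(
            CandidateVariant(
                variant=locus,
                variant_id=sv.variant_id,
                phenotype=phenotype,
                location=partition_by_location(locus, annotation),
                pipeline=PIPELINE_CNV,
                genes=sorted(g.gene for g in genes),
                families=frozenset(assignments),
                patterns=dict(assignments),
                sample_af=_cnv_sample_af(locus, cohort),
                scores=score_map,
            )
        )
    counts["brain_expressed"] = len(candidates)
    log.info("CNV prioritization attrition (%s): %s", phenotype.value, counts)
    return candidates


def _false_de_novo(sv: SegregatedVariant, cohort: Cohort, phenotype: Phenotype) -> bool:
    """De novo pattern across multiple affected individuals (likely artifact)."""
    return len(set(sv.de_novo_children(cohort, phenotype))) > 1


def af_focused_filter(
    segregated: Sequence[SegregatedVariant],
    annotation: AnnotationDb,
    cohort: Cohort,
    *,
    mei_ref: Optional[PopAfTable] = None,
    sv_ref: Optional[PopAfTable] = None,
    max_sample_af: float = MAX_SAMPLE_AF,
    max_population_af: float = MAX_POPULATION_AF,
) -> List[CandidateVariant]:
    """Allele-frequency-focused stream over exonic and intronic SVs.

    Keeps variants whose overlapped genes include a brain-expressed one,
    whose sample AF and population AF are both <= 5% (a variant absent
    from the population reference is treated as rare), and — for the
    intronic stream — which are not multi-individual de novo calls and
    overlap a known NDD gene.  AF boundaries are inclusive: exactly 5%
    is retained.
    """
    candidates: List[CandidateVariant] = []
    counts = {"input": len(segregated), "tpm": 0, "sample_af": 0,
              "population_af": 0, "false_de_novo": 0, "ndd": 0}
    for sv in segregated:
        variant: SvRecord = sv.variant  # type: ignore[assignment]
        location = partition_by_location(variant, annotation)
        if location not in (LOCATION_EXONIC, LOCATION_INTRONIC):
            continue
        genes = annotation.overlapping_genes(variant.chrom, variant.pos, variant.end)
        if not any(g.is_brain_expressed for g in genes):
            counts["tpm"] += 1
            continue
        sample_af = variant.sample_af()
        if sample_af > max_sample_af:
            counts["sample_af"] += 1
            continue
        pop_af = lookup_population_af(variant, mei_ref, sv_ref)
        if pop_af is not None and pop_af > max_population_af:
            counts["population_af"] += 1
            continue
        if location == LOCATION_INTRONIC:
            if _false_de_novo(sv, cohort, sv.phenotype):
                counts["false_de_novo"] += 1
                continue
            if not any(g.is_ndd for g in genes):
                counts["ndd"] += 1
                continue
        candidates.append(
            CandidateVariant(
                variant=variant,
                variant_id=sv.variant_id,
                phenotype=sv.phenotype,
                location=location,
                pipeline=(PIPELINE_AF_EXONIC if location == LOCATION_EXONIC
                          else PIPELINE_AF_INTRONIC),
                genes=sorted(g.gene for g in genes),
                families=sv.families,
                patterns=dict(sv.assignments),
                sample_af=sample_af,
                population_af=pop_af,
            )
        )
    log.info("AF-focused attrition: %s -> %d kept", counts, len(candidates))
    return candidates


def eqtl_focused_filter(
    segregated: Sequence[SegregatedVariant],
    eqtl_table: EqtlTable,
    annotation: AnnotationDb,
    *,
    mei_ref: Optional[PopAfTable] = None,
    sv_ref: Optional[PopAfTable] = None,
    max_dist: int = 100,
    min_caviar_prob: float = 0.1,
    max_caviar_rank: int = 5,
) -> List[CandidateVariant]:
    """eQTL-focused stream over intronic and intergenic SVs.

    A variant qualifies when it matches a brain-tissue eQTL record within
    100 bp: for sequence SVs the record must be fine-mapped with a lead SV
    (CAVIAR probability > 0.1, rank <= 5); for MEIs the record must be of
    MEI origin and causal in at least one brain tissue.  The candidate
    genes are the eQTL target genes passing the TPM > 5 gate — not the
    host gene.
    """
    candidates: List[CandidateVariant] = []
    for sv in segregated:
        variant: SvRecord = sv.variant  # type: ignore[assignment]
        location = partition_by_location(variant, annotation)
        if location not in (LOCATION_INTRONIC, LOCATION_INTERGENIC):
            continue
        matches = eqtl_table.match(variant.chrom, variant.pos, variant.svtype,
                                   max_dist)
        if variant.is_mei:
            hits = [
                m for m in matches
                if m.is_brain_tissue and m.origin == "MEI"
                and m.tissue_count_me_is_causal > 0
            ]
        else:
            hits = [
                m for m in matches
                if m.is_brain_tissue and m.lead_variant_type == "SV"
                and m.caviar_prob > min_caviar_prob
                and m.caviar_rank <= max_caviar_rank
            ]
        genes = sorted({
            m.eqtl_gene for m in hits if annotation.is_brain_expressed(m.eqtl_gene)
        })
        if not genes:
            continue
        candidates.append(
            CandidateVariant(
                variant=variant,
                variant_id=sv.variant_id,
                phenotype=sv.phenotype,
                location=location,
                pipeline=(PIPELINE_EQTL_INTRONIC if location == LOCATION_INTRONIC
                          else PIPELINE_EQTL_INTERGENIC),
                genes=genes,
                families=sv.families,
                patterns=dict(sv.assignments),
                sample_af=variant.sample_af(),
                population_af=lookup_population_af(variant, mei_ref, sv_ref),
                tissue_count=max(
                    (m.tissue_count_me_is_causal for m in hits), default=None
                ),
            )
        )
    return candidates
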