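"""End-to-end drivers tying QC, merging, segregation and prioritization
together over a study directory of standard-format inputs."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

from .annotations import (
    AnnotationDb,
    BenignSets,
    EqtlTable,
    PopAfTable,
    load_annotation,
    load_benign_regions,
    load_eqtl_table,
    load_pop_af_table,
)
from .cnv import (
    CnvLocus,
    cluster_loci,
    merge_within_samples,
    qc_filter_cnvs,
    remove_outlier_samples,
)
from .pedigree import Cohort, Phenotype, parse_ped
from .prioritization import (
    CandidateVariant,
    af_focused_filter,
    eqtl_focused_filter,
    filter_benign,
    prioritize_cnvs,
)
from .reporting import CandidateGene, aggregate_genes, family_coverage
from .segregation import SegregatedVariant, filter_by_segregation
from .svmei import MergedSvSet, SvRecord, merge_sv_mei, qc_filter_meis
from .vcfio import read_cnv_calls_tsv, read_sv_vcf

log = logging.getLogger(__name__)

ALL_PHENOTYPES = (Phenotype.ASD, Phenotype.LI_STAR, Phenotype.RI_STAR)

_STUDY_FILES = {
    "ped": "cohort.ped",
    "cnv_callerA": "cnv_callerA.tsv",
    "cnv_callerB": "cnv_callerB.tsv",
    "gsv_vcf": "gsv.vcf",
    "mei_vcf": "mei.vcf",
    "genes": "genes.tsv",
    "expression": "expression.tsv",
    "eqtl": "eqtl.tsv",
    "pop_af_mei": "pop_af_mei.tsv",
    "pop_af_sv": "pop_af_sv.tsv",
    "benign": "benign_regions.tsv",
    "ndd": "ndd_genes.txt",
}


def study_paths(directory) -> Dict[str, Path]:
    directory = Path(directory)
    return {key: directory / name for key, name in _STUDY_FILES.items()}


@dataclass
class CnvPipelineResult:
    loci: List[CnvLocus]
    retained_samples: Set[str]
    segregated: Dict[Phenotype, List[SegregatedVariant]]
    candidates: Dict[Phenotype, List[CandidateVariant]]


@dataclass
class SvPipelineResult:
    merged: MergedSvSet
    removed_samples: Set[str]
    segregated: Dict[Phenotype, List[SegregatedVariant]]
    candidates: Dict[Phenotype, List[CandidateVariant]]


@dataclass
class StudyResult:
    cohort: Cohort
    cnv: CnvPipelineResult
    sv: SvPipelineResult
    genes: Dict[Phenotype, List[CandidateGene]]
    all_genes: List[CandidateGene]
    coverage_percent: int

    def candidates(self, phenotype: Phenotype) -> List[CandidateVariant]:
        return self.cnv.candidates[phenotype] + self.sv.candidates[phenotype]


def run_cnv_pipeline(
    paths: Dict[str, Path],
    cohort: Cohort,
    annotation: AnnotationDb,
    benign: BenignSets,
    phenotypes: Sequence[Phenotype] = ALL_PHENOTYPES,
) -> CnvPipelineResult:
    """QC -> within-sample merge -> outlier exclusion -> cohort loci ->
    benign exclusion -> per-phenotype segregation and prioritization."""
    calls = read_cnv_calls_tsv(paths["cnv_callerA"]) + read_cnv_calls_tsv(
        paths["cnv_callerB"])
    calls = qc_filter_cnvs(calls)
    sample_cnvs = merge_within_samples(calls)
    counts = Counter(sc.sample_id for sc in sample_cnvs)
    for sid in cohort.sample_ids:
        counts.setdefault(sid, 0)
    retained = remove_outlier_samples(counts)
    sample_cnvs = [sc for sc in sample_cnvs if sc.sample_id in retained]
    cohort_cnv = cohort.restrict_samples(retained)
    loci = cluster_loci(sample_cnvs)
    loci = filter_benign(loci, benign)
    segregated: Dict[Phenotype, List[SegregatedVariant]] = {}
    candidates: Dict[Phenotype, List[CandidateVariant]] = {}
    for ph in phenotypes:
        seg = filter_by_segregation(
            loci, cohort_cnv, ph,
            denovo_carrier_scope="cohort", enable_x_linked=False,
        )
        segregated[ph] = seg
        candidates[ph] = prioritize_cnvs(seg, cohort_cnv, ph, annotation)
    return CnvPipelineResult(loci=loci, retained_samples=retained,
                             segregated=segregated, candidates=candidates)


def run_sv_pipeline(
    paths: Dict[str, Path],
    cohort: Cohort,
    annotation: AnnotationDb,
    benign: BenignSets,
    eqtl: EqtlTable,
    mei_ref: Optional[PopAfTable] = None,
    sv_ref: Optional[PopAfTable] = None,
    phenotypes: Sequence[Phenotype] = ALL_PHENOTYPES,
) -> SvPipelineResult:
    """MEI QC -> gSV/MEI merge -> benign exclusion -> per-phenotype
    segregation -> AF-focused and eQTL-focused candidate streams."""
    gsvs = read_sv_vcf(paths["gsv_vcf"])
    meis = read_sv_vcf(paths["mei_vcf"])
    qc = qc_filter_meis(meis)
    if qc.removed_samples:
        gsvs = [
            replace(r, genotypes={s: g for s, g in r.genotypes.items()
                                  if s not in qc.removed_samples})
            for r in gsvs
        ]
    cohort_sv = cohort.restrict_samples(
        set(cohort.sample_ids) - qc.removed_samples)
    merged = merge_sv_mei(gsvs, qc.records)
    kept = filter_benign(merged.loci, benign)
    segregated: Dict[Phenotype, List[SegregatedVariant]] = {}
    candidates: Dict[Phenotype, List[CandidateVariant]] = {}
    for ph in phenotypes:
        seg = filter_by_segregation(
            kept, cohort_sv, ph,
            denovo_carrier_scope="family", enable_x_linked=True,
        )
        segregated[ph] = seg
        candidates[ph] = (
            af_focused_filter(seg, annotation, cohort_sv,
                              mei_ref=mei_ref, sv_ref=sv_ref)
            + eqtl_focused_filter(seg, eqtl, annotation,
                                  mei_ref=mei_ref, sv_ref=sv_ref)
        )
    return SvPipelineResult(merged=merged, removed_samples=qc.removed_samples,
                            segregated=segregated, candidates=candidates)


def run_study(directory, phenotypes: Sequence[Phenotype] = ALL_PHENOTYPES
              ) -> StudyResult:
    """Run both pipelines over a study directory and aggregate gene lists."""
    paths = study_paths(directory)
    cohort = parse_ped(paths["ped"])
    annotation = load_annotation(paths["genes"], paths["expression"],
                                 paths["ndd"])
    benign = load_benign_regions(paths["benign"])
    eqtl = load_eqtl_table(paths["eqtl"])
    mei_ref = load_pop_af_table(paths["pop_af_mei"])
    sv_ref = load_pop_af_table(paths["pop_af_sv"])

    cnv = run_cnv_pipeline(paths, cohort, annotation, benign, phenotypes)
    sv = run_sv_pipeline(paths, cohort, annotation, benign, eqtl,
                         mei_ref, sv_ref, phenotypes)

    ndd = {g.gene for g in annotation.genes.values() if g.is_ndd}
    genes = {
        ph: aggregate_genes(cnv.candidates[ph] + sv.candidates[ph], ndd)
        for ph in phenotypes
    }
    all_candidates = [c for ph in phenotypes
                      for c in cnv.candidates[ph] + sv.candidates[ph]]
    all_genes = aggregate_genes(all_candidates, ndd)
    coverage = family_coverage(all_genes, len(cohort.families))
    return StudyResult(cohort=cohort, cnv=cnv, sv=sv, genes=genes,
                       all_genes=all_genes, coverage_percent=coverage)
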