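"""Strict per-family inheritance-pattern classification.

Each variant is tested, family by family and phenotype by phenotype,
against strict Mendelian models in the spirit of GEMINI's "strict"
inheritance tools:

* **de novo** — an affected child is heterozygous, both parents are
  reference and not affected, and no unaffected individual (family- or
  cohort-wide, configurable) carries the alternative allele.
* **autosomal recessive** — all known parents are unaffected
  heterozygous carriers and the affected children are homozygous for
  the alternative allele.
* **autosomal dominant** — every affected individual carries the
  allele, affected children have at least one affected parent, and no
  unaffected individual is heterozygous or homozygous for the allele.
* X-linked counterparts apply the same logic on chromosome X, with
  hemizygous carrier males treated as homozygous-alternative.

Individuals with a missing phenotype are invisible to the models
(they can neither support nor violate a pattern).  A missing genotype
in any individual a model *requires* makes that model fail — under
genotype noise a variant is dropped rather than ever reassigned.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .cnv import CnvLocus
from .core import GenotypeClass, is_x_chrom
from .pedigree import Cohort, Individual, Phenotype, Sex, trios
from .svmei import SvRecord

log = logging.getLogger(__name__)

REF = GenotypeClass.REF
HET = GenotypeClass.HET
HOM_ALT = GenotypeClass.HOM_ALT
MISSING = GenotypeClass.MISSING

_CN_TO_CLASS = {0: HOM_ALT, 1: HET, 2: REF, 3: HET, 4: HOM_ALT}


class InheritancePattern(str, enum.Enum):
    DE_NOVO = "de_novo"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    X_LINKED_RECESSIVE = "x_linked_recessive"
    X_LINKED_DOMINANT = "x_linked_dominant"
    X_LINKED_DE_NOVO = "x_linked_de_novo"


@dataclass
class SegregationResult:
    variant_id: str
    family_id: str
    phenotype: Phenotype
    patterns: FrozenSet[InheritancePattern]


def classify_genotype(variant, sample_id: str) -> GenotypeClass:
    """Biallelic genotype class of one sample at a CNV locus or SV record.

    Copy numbers map CN2 -> ref, CN1/CN3 -> het, CN0/CN4 -> hom_alt within
    the locus's own allele (deletion or duplication); a sample with no
    call at a CNV locus is reference.  SV genotypes map directly.
    """
    if isinstance(variant, CnvLocus):
        cn = variant.copy_number(sample_id)
        if cn > 4 or cn < 0:
            raise ValueError(f"copy number {cn} outside the supported 0-4 range")
        return _CN_TO_CLASS[cn]
    if isinstance(variant, SvRecord):
        return variant.genotype(sample_id)
    raise TypeError(f"cannot classify genotype for {type(variant).__name__}")


def _variant_id(variant) -> str:
    return variant.locus_id if isinstance(variant, CnvLocus) else variant.record_id


def classify_inheritance(
    variant,
    family: Sequence[Individual],
    phenotype: Phenotype,
    *,
    cohort: Optional[Cohort] = None,
    denovo_carrier_scope: str = "family",
    require_all_affected_children: bool = True,
    enable_x_linked: bool = True,
) -> SegregationResult:
    """Strict inheritance patterns a variant satisfies in one family.

    ``denovo_carrier_scope`` controls where the "no unaffected individual
    carries the allele" clause of the de novo model is evaluated:
    ``"family"`` (sequence SVs) or ``"cohort"`` (CNVs; requires ``cohort``).
    On chromosome X only the X-linked models are evaluated, elsewhere only
    the autosomal ones.
    """
    family = list(family)
    fam_id = family[0].family_id if family else "?"
    on_x = is_x_chrom(variant.chrom)

    def gt(ind: Individual) -> GenotypeClass:
        g = classify_genotype(variant, ind.individual_id)
        if on_x and ind.sex == Sex.MALE and g == HET:
            log.warning("male %s het on chrX at %s; treated as hemizygous alt",
                        ind.individual_id, _variant_id(variant))
            return HOM_ALT
        return g

    def aff(ind: Individual) -> Optional[bool]:
        return ind.affected(phenotype)

    if denovo_carrier_scope == "cohort":
        if cohort is None:
            raise ValueError("cohort-wide de novo carrier scope needs a cohort")
        scope: List[Individual] = list(cohort.individuals())
    elif denovo_carrier_scope == "family":
        scope = family
    else:
        raise ValueError(f"unknown denovo_carrier_scope {denovo_carrier_scope!r}")

    trio_list = list(trios(family))
    patterns: Set[InheritancePattern] = set()

    if on_x:
        if enable_x_linked:
            if _de_novo(trio_list, scope, gt, aff, x_linked=True):
                patterns.add(InheritancePattern.X_LINKED_DE_NOVO)
            if _recessive(trio_list, family, gt, aff,
                          require_all_affected_children, x_linked=True):
                patterns.add(InheritancePattern.X_LINKED_RECESSIVE)
            if _dominant(family, gt, aff):
                patterns.add(InheritancePattern.X_LINKED_DOMINANT)
    else:
        if _de_novo(trio_list, scope, gt, aff, x_linked=False):
            patterns.add(InheritancePattern.DE_NOVO)
        if _recessive(trio_list, family, gt, aff,
                      require_all_affected_children, x_linked=False):
            patterns.add(InheritancePattern.AUTOSOMAL_RECESSIVE)
        if _dominant(family, gt, aff):
            patterns.add(InheritancePattern.AUTOSOMAL_DOMINANT)

    return SegregationResult(
        variant_id=_variant_id(variant),
        family_id=fam_id,
        phenotype=phenotype,
        patterns=frozenset(patterns),
    )


def _de_novo(trio_list, scope, gt, aff, *, x_linked: bool) -> bool:
    found = False
    for child, father, mother in trio_list:
        if aff(child) is not True:
            continue
        g_child = gt(child)
        # autosomal: the affected child must be heterozygous; on chrX a
        # hemizygous carrier male (coerced hom_alt) also qualifies
        if x_linked:
            if not g_child.is_carrier:
                continue
        elif g_child != HET:
            continue
        if gt(father) != REF or gt(mother) != REF:
            continue
        if aff(father) is True or aff(mother) is True:
            continue
        found = True
        break
    if not found:
        return False
    # no unaffected individual may carry the alternative allele; a missing
    # genotype cannot demonstrate carriage and does not violate
    for ind in scope:
        if aff(ind) is False and gt(ind).is_carrier:
            return False
    return True


def _recessive(trio_list, family, gt, aff, require_all_affected_children: bool,
               *, x_linked: bool) -> bool:
    for child, father, mother in trio_list:
        if aff(child) is not True or gt(child) != HOM_ALT:
            continue
        if aff(father) is not False or aff(mother) is not False:
            continue
        if x_linked:
            # carrier mother; the father cannot be an unaffected hemizygous
            # carrier, so he must be reference
            if gt(mother) != HET or gt(father) != REF:
                continue
        else:
            if gt(father) != HET or gt(mother) != HET:
                continue
        if require_all_affected_children:
            sibs = [
                c for c, f, m in trio_list
                if f.individual_id == father.individual_id
                and m.individual_id == mother.individual_id
                and aff(c) is True
            ]
            if any(gt(s) != HOM_ALT for s in sibs):
                continue
        return True
    return False


def _dominant(family, gt, aff) -> bool:
    by_id = {m.individual_id: m for m in family}
    affecteds = [m for m in family if aff(m) is True]
    if not affecteds:
        return False
    # every affected individual carries the allele (missing genotype fails)
    if any(not gt(a).is_carrier for a in affecteds):
        return False
    # affected children need an affected parent; founders are exempt, but
    # at least one affected parent-child pair must exist
    any_pair = False
    for a in affecteds:
        parents = [by_id[p] for p in (a.father_id, a.mother_id) if p in by_id]
        if not parents:
            continue
        if not any(aff(p) is True for p in parents):
            return False
        any_pair = True
    if not any_pair:
        return False
    # no unaffected individual may carry
    for m in family:
        if aff(m) is False and gt(m).is_carrier:
            return False
    return True


@dataclass
class SegregatedVariant:
    """A variant annotated with its per-family pattern assignments."""

    variant: object  # CnvLocus or SvRecord
    phenotype: Phenotype
    assignments: Dict[str, FrozenSet[InheritancePattern]] = field(default_factory=dict)

    @property
    def variant_id(self) -> str:
        return _variant_id(self.variant)

    @property
    def patterns(self) -> FrozenSet[InheritancePattern]:
        out: Set[InheritancePattern] = set()
        for pats in self.assignments.values():
            out |= pats
        return frozenset(out)

    @property
    def families(self) -> FrozenSet[str]:
        return frozenset(self.assignments)

    def de_novo_children(self, cohort: Cohort, phenotype: Phenotype) -> List[str]:
        """Affected carrier children in families where de novo was assigned."""
        children: List[str] = []
        dn = {InheritancePattern.DE_NOVO, InheritancePattern.X_LINKED_DE_NOVO}
        for fam_id, pats in self.assignments.items():
            if not (pats & dn):
                continue
            for child, father, mother in trios(cohort.families[fam_id]):
                if child.affected(phenotype) is True and classify_genotype(
                    self.variant, child.individual_id
                ).is_carrier:
                    children.append(child.individual_id)
        return children


def filter_by_segregation(
    variants: Iterable,
    cohort: Cohort,
    phenotype: Phenotype,
    **options,
) -> List[SegregatedVariant]:
    """Variants satisfying at least one strict pattern in at least one family.

    Each retained variant carries its (family -> patterns) assignments;
    keyword options are forwarded to :func:`classify_inheritance`.
    """
    kept: List[SegregatedVariant] = []
    for variant in variants:
        assignments: Dict[str, FrozenSet[InheritancePattern]] = {}
        for fam_id in sorted(cohort.families):
            result = classify_inheritance(
                variant, cohort.families[fam_id], phenotype,
                cohort=cohort, **options,
            )
            if result.patterns:
                assignments[fam_id] = result.patterns
        if assignments:
            kept.append(SegregatedVariant(variant=variant, phenotype=phenotype,
                                          assignments=assignments))
    return kept
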