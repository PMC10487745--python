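"""Pedigree parsing, union phenotypes and family segregation-type classification.

The cohort model carries three binary phenotypes per person: autism
spectrum disorder (ASD), oral language impairment (LI) and reading
impairment (RI).  Analyses run on ASD and the two *union* phenotypes
LI* (ASD or LI) and RI* (ASD or RI), so that every ASD patient is a
member of all three analysis groups.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set

import pandas as pd

log = logging.getLogger(__name__)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(str, enum.Enum):
    """The three analysis phenotypes."""

    ASD = "ASD"
    LI_STAR = "LIstar"
    RI_STAR = "RIstar"


class FamilyPattern(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE_OR_DENOVO = "recessive_or_denovo"


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    asd: Optional[bool]
    li: Optional[bool]
    ri: Optional[bool]

    def affected(self, phenotype: Phenotype) -> Optional[bool]:
        """Affection status under a (union) phenotype; ``None`` = unknown."""
        return derive_union_phenotypes(self)[phenotype]


def _union(*flags: Optional[bool]) -> Optional[bool]:
    # A single confirmed diagnosis suffices for union membership; the
    # union is unknown only when nothing is true and something is untested.
    if any(f is True for f in flags):
        return True
    if any(f is None for f in flags):
        return None
    return False


def derive_union_phenotypes(ind: Individual) -> Dict[Phenotype, Optional[bool]]:
    """ASD plus the union phenotypes LI* = ASD|LI and RI* = ASD|RI."""
    return {
        Phenotype.ASD: ind.asd,
        Phenotype.LI_STAR: _union(ind.asd, ind.li),
        Phenotype.RI_STAR: _union(ind.asd, ind.ri),
    }


@dataclass
class Cohort:
    families: Dict[str, List[Individual]] = field(default_factory=dict)

    def individuals(self) -> Iterator[Individual]:
        for members in self.families.values():
            yield from members

    @property
    def sample_ids(self) -> List[str]:
        return [ind.individual_id for ind in self.individuals()]

    def family_of(self, individual_id: str) -> Optional[str]:
        for fam_id, members in self.families.items():
            if any(m.individual_id == individual_id for m in members):
                return fam_id
        return None

    def restrict_samples(self, keep: Set[str]) -> "Cohort":
        """Cohort containing only the listed individuals (families kept)."""
        fams: Dict[str, List[Individual]] = {}
        for fam_id, members in self.families.items():
            kept = [m for m in members if m.individual_id in keep]
            if kept:
                fams[fam_id] = kept
        return Cohort(families=fams)


_PHENO_CODE = {"1": False, "2": True, "0": None, "-9": None}
_SEX_CODE = {"1": Sex.MALE, "2": Sex.FEMALE}


def parse_ped(path) -> Cohort:
    """Parse an extended 8-column PED file.

    Columns: family, individual, father, mother, sex, ASD, LI, RI.
    Phenotypes are coded 1 = unaffected, 2 = affected, 0 or -9 = missing;
    parent code "0" means the parent is not in the pedigree.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] < 8:
        raise ValueError(
            f"{path}: expected >=8 columns (fam, id, father, mother, sex, "
            f"ASD, LI, RI); got {df.shape[1]}"
        )
    cohort = Cohort()
    seen: Set[str] = set()
    for row in df.itertuples(index=False):
        fam, iid, fid, mid, sex = row[0], row[1], row[2], row[3], row[4]
        if iid in seen:
            raise ValueError(f"duplicate individual ID {iid!r} in {path}")
        seen.add(iid)
        ind = Individual(
            individual_id=iid,
            family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_CODE.get(sex, Sex.UNKNOWN),
            asd=_pheno(row[5], iid, "ASD"),
            li=_pheno(row[6], iid, "LI"),
            ri=_pheno(row[7], iid, "RI"),
        )
        cohort.families.setdefault(fam, []).append(ind)
    _validate(cohort)
    return cohort


def _pheno(code: str, iid: str, name: str) -> Optional[bool]:
    try:
        return _PHENO_CODE[code]
    except KeyError:
        raise ValueError(f"bad {name} phenotype code {code!r} for {iid!r}") from None


def _validate(cohort: Cohort) -> None:
    for fam_id, members in cohort.families.items():
        ids = {m.individual_id for m in members}
        for m in members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"parent {parent!r} of {m.individual_id!r} not defined "
                        f"in family {fam_id!r}"
                    )
        _check_acyclic(members)


def _check_acyclic(members: List[Individual]) -> None:
    by_id = {m.individual_id: m for m in members}
    for m in members:
        seen = set()
        stack = [p for p in (m.father_id, m.mother_id) if p]
        while stack:
            cur = stack.pop()
            if cur == m.individual_id:
                raise ValueError(f"pedigree cycle: {m.individual_id!r} is its own ancestor")
            if cur in seen:
                continue
            seen.add(cur)
            anc = by_id.get(cur)
            if anc is not None:
                stack.extend(p for p in (anc.father_id, anc.mother_id) if p)


def trios(family: List[Individual]):
    """Yield (child, father, mother) for every child with both parents present."""
    by_id = {m.individual_id: m for m in family}
    for m in family:
        if m.father_id in by_id and m.mother_id in by_id:
            yield m, by_id[m.father_id], by_id[m.mother_id]


def classify_family_pattern(
    family: List[Individual], phenotype: Phenotype
) -> Set[FamilyPattern]:
    """Segregation type(s) of a family's phenotype, over its complete trios.

    ``dominant`` when some affected child has an affected parent;
    ``recessive_or_denovo`` when some affected child has two unaffected
    parents.  Multi-trio families can fall in both categories.
    """
    patterns: Set[FamilyPattern] = set()
    trio_list = list(trios(family))
    if not trio_list:
        fam = family[0].family_id if family else "?"
        log.warning("family %s has no complete trio; pattern not classifiable", fam)
        return patterns
    for child, father, mother in trio_list:
        if child.affected(phenotype) is not True:
            continue
        pats = (father.affected(phenotype), mother.affected(phenotype))
        if any(p is True for p in pats):
            patterns.add(FamilyPattern.DOMINANT)
        if all(p is False for p in pats):
            patterns.add(FamilyPattern.RECESSIVE_OR_DENOVO)
    return patterns
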