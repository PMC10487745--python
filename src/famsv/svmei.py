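"""Sequence-resolved SV / mobile-element-insertion QC and cross-set merging.

The cohort carries two sequencing-derived call sets: a general SV set
("gSV": deletions, insertions, duplications, inversions) and a
mobile-element set from a MELT-style caller (Alu / LINE-1 / SVA
insertions and reference-ME deletions).  MEI loci are screened for
sample-level no-call rate, locus missingness, Hardy-Weinberg
disequilibrium and caller evidence; the two sets are then merged by
breakpoint proximity (<=100 bp at both ends) with SV-type and strand
agreement, first within individuals and then across the cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from scipy import stats
from scipy.special import gammaln

from .core import GenotypeClass, chrom_sort_key

log = logging.getLogger(__name__)

BREAKPOINT_TOLERANCE = 100  # bp, both breakpoints

MEI_SUBTYPES = ("MEI_ALU", "MEI_LINE1", "MEI_SVA")
SV_TYPES = ("DEL", "INS", "DUP", "INV") + MEI_SUBTYPES

ALLOWED_MEI_FILTERS = frozenset({"PASS", "rSD"})


def svtype_class(svtype: str) -> str:
    """Coarse SV class used for merging: MEI insertions are insertions."""
    return "INS" if svtype in MEI_SUBTYPES else svtype


@dataclass
class SvRecord:
    """A sequence-resolved SV or MEI with cohort-wide biallelic genotypes."""

    record_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    strand: str  # "+", "-" or "." (unknown)
    genotypes: Dict[str, GenotypeClass]
    source: str  # gsv_callset | mei_insertion | mei_deletion
    assess: Optional[int] = None
    filter_field: str = "PASS"
    split_reads: Optional[int] = None

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.pos > self.end:
            raise ValueError(f"SV with pos > end: {self.record_id}")

    @property
    def is_mei(self) -> bool:
        return self.svtype in MEI_SUBTYPES or self.source.startswith("mei")

    def genotype(self, sample_id: str) -> GenotypeClass:
        return self.genotypes.get(sample_id, GenotypeClass.MISSING)

    def carriers(self) -> List[str]:
        return [s for s, g in self.genotypes.items() if g.is_carrier]

    def missing_rate(self) -> float:
        if not self.genotypes:
            return 1.0
        n_miss = sum(1 for g in self.genotypes.values() if g == GenotypeClass.MISSING)
        return n_miss / len(self.genotypes)

    def genotype_counts(self) -> Tuple[int, int, int]:
        """(hom_ref, het, hom_alt) counts over non-missing genotypes."""
        c = {GenotypeClass.REF: 0, GenotypeClass.HET: 0, GenotypeClass.HOM_ALT: 0}
        for g in self.genotypes.values():
            if g != GenotypeClass.MISSING:
                c[g] += 1
        return c[GenotypeClass.REF], c[GenotypeClass.HET], c[GenotypeClass.HOM_ALT]

    def sample_af(self) -> float:
        """Alternative-allele frequency over called alleles."""
        n_rr, n_het, n_aa = self.genotype_counts()
        n_called = n_rr + n_het + n_aa
        if n_called == 0:
            return 0.0
        return (n_het + 2 * n_aa) / (2 * n_called)


@dataclass
class MergedSvSet:
    loci: List[SvRecord]
    provenance: Dict[str, List[str]] = field(default_factory=dict)


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, *, exact: bool = False) -> float:
    """Hardy-Weinberg equilibrium p-value for one biallelic locus.

    Default is the 1-df chi-square goodness-of-fit test against genotype
    frequencies expected from the observed allele frequency; monomorphic
    loci and exact HWE proportions return 1.0.  ``exact=True`` switches to
    the conditional exact test (sum over heterozygote counts with
    probability <= that of the observed configuration).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("HWE test needs at least one called genotype")
    if exact:
        return _hwe_exact(n_hom_ref, n_het, n_hom_alt)
    p_alt = (n_het + 2 * n_hom_alt) / (2 * n)
    if p_alt in (0.0, 1.0):
        return 1.0
    expected = (
        n * (1 - p_alt) ** 2,
        n * 2 * p_alt * (1 - p_alt),
        n * p_alt**2,
    )
    observed = (n_hom_ref, n_het, n_hom_alt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_rr: int, n_het: int, n_aa: int) -> float:
    n = n_rr + n_het + n_aa
    n_alt = n_het + 2 * n_aa
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0

    def log_prob(k_het: int) -> float:
        k_aa2 = n_alt - k_het
        if k_aa2 < 0 or k_aa2 % 2:
            return -math.inf
        k_aa = k_aa2 // 2
        k_rr = n - k_het - k_aa
        if k_rr < 0:
            return -math.inf
        return (
            gammaln(n + 1) - gammaln(k_rr + 1) - gammaln(k_het + 1) - gammaln(k_aa + 1)
            + k_het * math.log(2)
            + gammaln(n_alt + 1) + gammaln(2 * n - n_alt + 1) - gammaln(2 * n + 1)
        )

    lp_obs = log_prob(n_het)
    total = 0.0
    for k in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        lp = log_prob(k)
        if lp <= lp_obs + 1e-12:
            total += math.exp(lp)
    return min(1.0, total)


@dataclass
class MeiQcResult:
    records: List[SvRecord]
    removed_samples: Set[str]
    dropped: List[Tuple[str, str]]  # (record_id, rule)


def qc_filter_meis(
    records: Sequence[SvRecord],
    *,
    sample_nocall_cutoff: float = 0.20,
    locus_missing_cutoff: float = 0.05,
    hwe_cutoff: float = 1e-20,
    min_assess: int = 3,
    allowed_filters: frozenset = ALLOWED_MEI_FILTERS,
    min_split_reads: int = 3,
) -> MeiQcResult:
    """QC the MEI call set.

    1. Samples whose no-call rate across all MEI loci exceeds
       ``sample_nocall_cutoff`` are removed cohort-wide (poor calling
       quality, e.g. a bad sequencing batch).
    2. Loci with missingness > 5% (over retained samples) or an HWE
       p-value below 1e-20 are removed; an all-missing locus has no
       defined HWE p and passes that filter by convention.
    3. MEI insertions additionally require ASSESS >= 3, a FILTER of
       PASS or rSD, and more than 2 split reads.
    """
    records = list(records)
    dropped: List[Tuple[str, str]] = []

    # 1. sample-level no-call screening
    removed_samples: Set[str] = set()
    if records:
        samples = sorted({s for r in records for s in r.genotypes})
        for s in samples:
            n_miss = sum(
                1 for r in records if r.genotype(s) == GenotypeClass.MISSING
            )
            if n_miss / len(records) > sample_nocall_cutoff:
                removed_samples.add(s)
        if removed_samples:
            log.info("removed %d high-no-call samples: %s",
                     len(removed_samples), sorted(removed_samples))
            records = [
                replace(r, genotypes={s: g for s, g in r.genotypes.items()
                                      if s not in removed_samples})
                for r in records
            ]

    kept: List[SvRecord] = []
    for r in records:
        rule = None
        miss = r.missing_rate()
        n_rr, n_het, n_aa = r.genotype_counts()
        if miss > locus_missing_cutoff:
            rule = f"missingness {miss:.3f} > {locus_missing_cutoff}"
        elif n_rr + n_het + n_aa == 0:
            # all-missing locus: HWE p undefined, passes by convention
            log.warning("locus %s is all-missing; HWE undefined, retained", r.record_id)
        elif hwe_test(n_rr, n_het, n_aa) < hwe_cutoff:
            rule = f"HWE p < {hwe_cutoff}"
        if rule is None and r.source == "mei_insertion":
            if r.assess is None or r.assess < min_assess:
                rule = f"ASSESS {r.assess} < {min_assess}"
            elif r.filter_field not in allowed_filters:
                rule = f"FILTER {r.filter_field!r} not in {sorted(allowed_filters)}"
            elif r.split_reads is None or r.split_reads < min_split_reads:
                rule = f"split reads {r.split_reads} < {min_split_reads}"
        if rule is None:
            kept.append(r)
        else:
            dropped.append((r.record_id, rule))
            log.debug("MEI QC drop %s: %s", r.record_id, rule)
    return MeiQcResult(records=kept, removed_samples=removed_samples, dropped=dropped)


def _compatible(a: SvRecord, b: SvRecord, max_dist: int) -> bool:
    if a.chrom != b.chrom:
        return False
    if svtype_class(a.svtype) != svtype_class(b.svtype):
        return False
    if a.strand != b.strand and "." not in (a.strand, b.strand):
        return False
    return abs(a.pos - b.pos) <= max_dist and abs(a.end - b.end) <= max_dist


def _share_carrier(a: SvRecord, b: SvRecord) -> bool:
    ca = {s for s, g in a.genotypes.items() if g.is_carrier}
    return any(g.is_carrier and s in ca for s, g in b.genotypes.items())


def _cluster(records: List[SvRecord], max_dist: int, require_shared_carrier: bool
             ) -> List[List[SvRecord]]:
    n = len(records)
    order = sorted(range(n), key=lambda i: (records[i].pos, records[i].end,
                                            records[i].record_id))
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_idx in range(n):
        i = order[a_idx]
        for b_idx in range(a_idx + 1, n):
            j = order[b_idx]
            if records[j].pos - records[i].pos > max_dist:
                break
            if not _compatible(records[i], records[j], max_dist):
                continue
            if require_shared_carrier and not _share_carrier(records[i], records[j]):
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    clusters: Dict[int, List[SvRecord]] = {}
    for i in order:
        clusters.setdefault(find(i), []).append(records[i])
    return sorted(clusters.values(), key=lambda c: (c[0].pos, c[0].record_id))


def _merge_cluster(members: List[SvRecord]) -> SvRecord:
    # representative = most carrier evidence, then leftmost, then gSV first
    rep = sorted(
        members,
        key=lambda r: (-len(r.carriers()), r.pos, r.source != "gsv_callset",
                       r.record_id),
    )[0]
    genotypes: Dict[str, GenotypeClass] = {}
    sources: Dict[str, str] = {}
    for r in sorted(members, key=lambda r: (r.source != "gsv_callset", r.pos,
                                            r.record_id)):
        for s, g in r.genotypes.items():
            if g == GenotypeClass.MISSING:
                genotypes.setdefault(s, g)
                continue
            prev = genotypes.get(s)
            if prev is None or prev == GenotypeClass.MISSING:
                genotypes[s] = g
                sources[s] = r.source
            elif prev != g:
                # conflicting non-missing genotypes: the gSV call wins
                if sources.get(s) != "gsv_callset" and r.source == "gsv_callset":
                    genotypes[s] = g
                    sources[s] = r.source
                log.debug("genotype conflict at %s for %s: kept %s",
                          rep.record_id, s, genotypes[s].value)
    return replace(rep, genotypes=genotypes)


def merge_sv_mei(
    gsvs: Sequence[SvRecord],
    meis: Sequence[SvRecord],
    max_dist: int = BREAKPOINT_TOLERANCE,
) -> MergedSvSet:
    """Two-step merge of the gSV and MEI call sets.

    Records are mergeable when both breakpoints lie within ``max_dist``
    (100 bp), coarse SV types agree (MEI subtypes count as insertions)
    and strands are compatible (unknown matches anything).  Step one
    links records representing the same event in the same individual
    (they must share a carrier); step two collapses the resulting loci
    across individuals with the same distance rule.  The merged locus
    keeps the coordinates of the record with the most carrier evidence
    (ties: leftmost) and unions genotypes across contributors.
    """
    all_records = list(gsvs) + list(meis)
    groups: Dict[Tuple[str, str], List[SvRecord]] = {}
    for r in all_records:
        groups.setdefault((r.chrom, svtype_class(r.svtype)), []).append(r)

    loci: List[SvRecord] = []
    provenance: Dict[str, List[str]] = {}
    for key in sorted(groups, key=lambda k: (chrom_sort_key(k[0]), k[1])):
        group = groups[key]
        # step 1: within-individual merge (shared-carrier requirement)
        clusters1 = _cluster(group, max_dist, True)
        step1 = [_merge_cluster(c) for c in clusters1]
        contrib: Dict[str, List[str]] = {}
        for cluster, rep in zip(clusters1, step1):
            contrib[rep.record_id] = sorted(r.record_id for r in cluster)
        # step 2: across individuals
        for cluster in _cluster(step1, max_dist, False):
            merged = _merge_cluster(cluster)
            loci.append(merged)
            provenance[merged.record_id] = sorted(
                rid for r in cluster for rid in contrib.get(r.record_id, [r.record_id])
            )
    loci.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos, r.end, r.record_id))
    return MergedSvSet(loci=loci, provenance=provenance)
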