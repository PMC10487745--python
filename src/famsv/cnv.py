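"""Array-CNV QC, dual-caller merging and cohort locus construction.

Copy-number calls come from two callers run on the same arrays (an
HMM-based caller emulating PennCNV, "callerA", and an Objective-Bayes
caller emulating QuantiSNP, "callerB", which reports a log Bayes
factor).  Calls passing QC are merged per sample at >=70% reciprocal
overlap with outermost breakpoints, then clustered across samples by
the same rule into cohort loci with per-sample integer copy numbers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    chrom_sort_key,
    interval_length,
    is_sex_chrom,
    reciprocal_overlap,
)

log = logging.getLogger(__name__)

MERGE_THRESHOLD = 0.70  # minimum reciprocal overlap for merging


class Caller(str, enum.Enum):
    A = "callerA"  # HMM caller; no per-call Bayes factor
    B = "callerB"  # Objective-Bayes caller; confidence = max log Bayes factor


class VariantClass(str, enum.Enum):
    DELETION = "deletion"      # CN < 2
    DUPLICATION = "duplication"  # CN > 2


@dataclass
class CnvCall:
    """A single-caller copy-number call (1-based inclusive coordinates)."""

    sample_id: str
    caller: Caller
    batch: str
    chrom: str
    start: int
    end: int
    copy_number: int
    n_probes: int
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"CNV call with start > end: {self}")
        if self.copy_number == 2:
            raise ValueError("a CNV call asserts a departure from diploid (CN != 2)")

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    @property
    def variant_class(self) -> VariantClass:
        return VariantClass.DELETION if self.copy_number < 2 else VariantClass.DUPLICATION

    @property
    def interval(self):
        return (self.chrom, self.start, self.end)


@dataclass
class SampleCnv:
    """Per-sample CNV after within-sample (cross-caller) merging."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    variant_class: VariantClass
    supporting_calls: List[CnvCall] = field(default_factory=list)

    @property
    def interval(self):
        return (self.chrom, self.start, self.end)


@dataclass
class CnvLocus:
    """A cohort-level copy-number locus.

    ``genotypes`` stores integer copy numbers for carrier samples only;
    samples without a call at the locus are assumed diploid (CN2).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    variant_class: VariantClass
    genotypes: Dict[str, int] = field(default_factory=dict)
    supporting_calls: List[CnvCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    @property
    def interval(self):
        return (self.chrom, self.start, self.end)

    def copy_number(self, sample_id: str) -> int:
        return self.genotypes.get(sample_id, 2)

    def carriers(self) -> List[str]:
        return [s for s, cn in self.genotypes.items() if cn != 2]


def qc_filter_cnvs(
    calls: Iterable[CnvCall],
    *,
    min_length: int = 10_000,
    max_length: int = 7_500_000,
    min_probes: int = 5,
    min_confidence: float = 10.0,
    exclude_sex_chroms: bool = True,
) -> List[CnvCall]:
    """Drop calls that are too small/large, probe-poor, low-confidence or on
    sex chromosomes.

    Boundary semantics: a 10 kb or 7.5 Mb call is kept; a callerB call with
    log Bayes factor exactly ``min_confidence`` is kept (only scores *below*
    the cutoff are removed).
    """
    kept: List[CnvCall] = []
    for call in calls:
        rule = None
        if call.length < min_length:
            rule = f"length {call.length} < {min_length}"
        elif call.length > max_length:
            rule = f"length {call.length} > {max_length}"
        elif call.n_probes < min_probes:
            rule = f"n_probes {call.n_probes} < {min_probes}"
        elif (
            call.caller == Caller.B
            and call.confidence is not None
            and call.confidence < min_confidence
        ):
            rule = f"confidence {call.confidence} < {min_confidence}"
        elif exclude_sex_chroms and is_sex_chrom(call.chrom):
            rule = f"sex chromosome {call.chrom}"
        if rule is None:
            kept.append(call)
        else:
            log.debug("QC drop %s:%d-%d (%s): %s",
                      call.chrom, call.start, call.end, call.sample_id, rule)
    return kept


def remove_outlier_samples(
    per_sample_counts: Mapping[str, int],
    *,
    multiplier: float = 1.5,
    quartile_method: str = "linear",
) -> Set[str]:
    """Samples retained after excess-CNV-count outlier exclusion.

    A sample is an outlier when its CNV count exceeds median + 1.5 * IQR of
    the cohort distribution; the threshold is computed once on the input
    (no iteration).  Quartiles use linear interpolation by default
    (``quartile_method`` is passed to :func:`numpy.percentile`).
    """
    if len(per_sample_counts) < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    counts = np.array(list(per_sample_counts.values()), dtype=float)
    q1, med, q3 = np.percentile(counts, [25, 50, 75], method=quartile_method)
    cutoff = med + multiplier * (q3 - q1)
    retained = {s for s, c in per_sample_counts.items() if c <= cutoff}
    removed = set(per_sample_counts) - retained
    if removed:
        log.info("removed %d outlier samples (count > %.1f): %s",
                 len(removed), cutoff, sorted(removed))
    return retained


def outlier_cutoff(per_sample_counts: Mapping[str, int], multiplier: float = 1.5,
                   quartile_method: str = "linear") -> float:
    """The median + 1.5*IQR exclusion threshold for a count distribution."""
    counts = np.array(list(per_sample_counts.values()), dtype=float)
    q1, med, q3 = np.percentile(counts, [25, 50, 75], method=quartile_method)
    return float(med + multiplier * (q3 - q1))


def _single_linkage_clusters(
    intervals: Sequence[Tuple[str, int, int]],
    threshold: float,
    keys: Optional[Sequence] = None,
) -> List[List[int]]:
    """Single-linkage clusters of intervals under the reciprocal-overlap rule.

    All intervals must share one chromosome.  Returns clusters as lists of
    input indices; transitive closure over pairwise overlaps >= threshold.
    When ``keys`` is given, intervals sharing a key are never linked
    directly (used to keep within-sample merging decisions final during
    cross-sample clustering).
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (intervals[i][1], intervals[i][2]))
    # sweep: only interval pairs that physically overlap can reach 70% RO
    active: List[int] = []
    for i in order:
        start = intervals[i][1]
        active = [j for j in active if intervals[j][2] >= start]
        for j in active:
            if keys is not None and keys[i] == keys[j]:
                continue
            if reciprocal_overlap(intervals[i], intervals[j]) >= threshold:
                union(i, j)
        active.append(i)
    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted(clusters.values(), key=lambda c: min(c))


def merge_within_samples(
    calls: Sequence[CnvCall], threshold: float = MERGE_THRESHOLD
) -> List[SampleCnv]:
    """Merge calls per (batch, sample, chromosome, variant class).

    Calls merge iff their reciprocal overlap is >= ``threshold``; the
    merged call takes the outermost breakpoints of its supporting calls.
    A call nested inside another but covering <70% of it stays separate.
    Deletions and duplications never merge with each other.
    """
    groups: Dict[Tuple[str, str, str, VariantClass], List[CnvCall]] = {}
    for call in calls:
        key = (call.batch, call.sample_id, call.chrom, call.variant_class)
        groups.setdefault(key, []).append(call)
    merged: List[SampleCnv] = []
    for (batch, sample, chrom, vclass), group in groups.items():
        clusters = _single_linkage_clusters([c.interval for c in group], threshold)
        for idxs in clusters:
            members = [group[i] for i in idxs]
            rep = _representative_call(members)
            merged.append(
                SampleCnv(
                    sample_id=sample,
                    chrom=chrom,
                    start=min(c.start for c in members),
                    end=max(c.end for c in members),
                    copy_number=rep.copy_number,
                    variant_class=vclass,
                    supporting_calls=sorted(
                        members, key=lambda c: (c.start, c.end, c.caller.value)
                    ),
                )
            )
    merged.sort(key=lambda m: (chrom_sort_key(m.chrom), m.start, m.end,
                               m.variant_class.value, m.sample_id))
    return merged


def _representative_call(calls: Sequence[CnvCall]) -> CnvCall:
    # copy number of the best-supported call: most probes, then leftmost,
    # then caller A before B — deterministic under input permutation
    return sorted(calls, key=lambda c: (-c.n_probes, c.start, c.end, c.caller.value))[0]


def cluster_loci(
    sample_cnvs: Sequence[SampleCnv], threshold: float = MERGE_THRESHOLD
) -> List[CnvLocus]:
    """Cluster per-sample CNVs across the cohort into shared loci.

    Uses the same single-linkage >=70% reciprocal-overlap rule within each
    (chromosome, variant class); the locus takes outermost breakpoints and
    assembles the per-sample copy-number genotype map.
    """
    groups: Dict[Tuple[str, VariantClass], List[SampleCnv]] = {}
    for sc in sample_cnvs:
        groups.setdefault((sc.chrom, sc.variant_class), []).append(sc)
    loci: List[CnvLocus] = []
    for (chrom, vclass), group in sorted(
        groups.items(), key=lambda kv: (chrom_sort_key(kv[0][0]), kv[0][1].value)
    ):
        clusters = _single_linkage_clusters(
            [sc.interval for sc in group], threshold,
            keys=[sc.sample_id for sc in group],
        )
        for idxs in clusters:
            members = [group[i] for i in idxs]
            genotypes: Dict[str, int] = {}
            for sc in sorted(members, key=lambda m: -(m.end - m.start)):
                # a sample rarely contributes twice; the longest event wins
                genotypes.setdefault(sc.sample_id, sc.copy_number)
            loci.append(
                CnvLocus(
                    locus_id="",
                    chrom=chrom,
                    start=min(sc.start for sc in members),
                    end=max(sc.end for sc in members),
                    variant_class=vclass,
                    genotypes=genotypes,
                    supporting_calls=[c for sc in members for c in sc.supporting_calls],
                )
            )
    loci.sort(key=lambda l: (chrom_sort_key(l.chrom), l.start, l.end,
                             l.variant_class.value))
    for i, locus in enumerate(loci, 1):
        locus.locus_id = f"CNV{i:06d}"
    return loci


def merge_caller_calls(
    calls: Sequence[CnvCall], threshold: float = MERGE_THRESHOLD
) -> List[CnvLocus]:
    """Full merge: within-sample cross-caller merging, then cohort clustering."""
    return cluster_loci(merge_within_samples(calls, threshold), threshold)
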