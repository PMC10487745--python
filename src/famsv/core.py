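"""Shared primitives: genotype classes, interval arithmetic, chromosome helpers."""

from __future__ import annotations

import enum
from typing import Tuple

Interval = Tuple[str, int, int]  # (chrom, start, end), 1-based inclusive

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


class GenotypeClass(str, enum.Enum):
    """Biallelic genotype class shared by copy-number and sequence variants."""

    REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        return self in (GenotypeClass.HET, GenotypeClass.HOM_ALT)


def is_sex_chrom(chrom: str) -> bool:
    return chrom in SEX_CHROMS


def is_x_chrom(chrom: str) -> bool:
    return chrom in ("X", "chrX")


def chrom_sort_key(chrom: str):
    """Natural ordering: chr1..chr22, chrX, chrY, then lexicographic."""
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name in order:
        return (0, order[name], "")
    return (1, 0, name)


def interval_length(start: int, end: int) -> int:
    return end - start + 1


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """Reciprocal overlap of two 1-based inclusive intervals.

    Returns ``min(o / len(a), o / len(b))`` where ``o`` is the overlap
    length, i.e. the overlap fraction relative to the *larger* interval.
    Disjoint intervals return 0.  The two intervals must lie on the same
    chromosome; callers are expected to pre-partition by chromosome.
    """
    a_chrom, a_start, a_end = a
    b_chrom, b_start, b_end = b
    if a_chrom != b_chrom:
        raise ValueError(
            f"reciprocal_overlap requires intervals on one chromosome, "
            f"got {a_chrom!r} and {b_chrom!r}"
        )
    if a_start > a_end or b_start > b_end:
        raise ValueError("degenerate interval: start > end")
    overlap = min(a_end, b_end) - max(a_start, b_start) + 1
    if overlap <= 0:
        return 0.0
    return min(
        overlap / interval_length(a_start, a_end),
        overlap / interval_length(b_start, b_end),
    )
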