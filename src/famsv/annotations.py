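"""Annotation sidecars: gene models, brain expression, eQTLs, benign
regions, population allele frequencies and the known-NDD gene list.

All sidecars are plain TSV tables keyed by gene symbol or by
(chromosome, position, SV type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .svmei import svtype_class

log = logging.getLogger(__name__)

TPM_SOURCES = ("GTEx", "BrainSpan", "HDBR")
BRAIN_TPM_CUTOFF = 5.0

BENIGN_CLASSES = ("gain", "loss", "ins", "inv")


@dataclass
class GeneAnnotation:
    gene: str
    chrom: str
    start: int
    end: int
    biotype: str
    exons: List[Tuple[int, int]]
    brain_tpm: Dict[str, float] = field(default_factory=dict)
    is_ndd: bool = False

    @property
    def is_protein_coding(self) -> bool:
        return self.biotype == "protein_coding"

    @property
    def max_brain_tpm(self) -> float:
        return max(self.brain_tpm.values(), default=0.0)

    @property
    def is_brain_expressed(self) -> bool:
        """Expressed when any of the three sources reports TPM > 5."""
        return self.max_brain_tpm > BRAIN_TPM_CUTOFF

    def introns(self) -> List[Tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)
            if exons[i + 1][0] - exons[i][1] > 1
        ]


class AnnotationDb:
    """Gene models with expression and NDD flags, indexed by chromosome."""

    def __init__(self, genes: Sequence[GeneAnnotation]):
        self.genes: Dict[str, GeneAnnotation] = {g.gene: g for g in genes}
        self._by_chrom: Dict[str, List[GeneAnnotation]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end))

    def overlapping_genes(self, chrom: str, start: int, end: int
                          ) -> List[GeneAnnotation]:
        return [
            g for g in self._by_chrom.get(chrom, ())
            if g.start <= end and g.end >= start
        ]

    def gene(self, name: str) -> Optional[GeneAnnotation]:
        return self.genes.get(name)

    def is_brain_expressed(self, name: str) -> bool:
        g = self.genes.get(name)
        return g is not None and g.is_brain_expressed

    def is_ndd(self, name: str) -> bool:
        g = self.genes.get(name)
        return g is not None and g.is_ndd


def load_annotation(genes_path, expression_path=None, ndd_path=None) -> AnnotationDb:
    """Build an :class:`AnnotationDb` from the TSV sidecars.

    ``genes_path`` columns: gene, chrom, start, end, biotype, exon_starts,
    exon_ends (comma-separated).  ``expression_path`` columns: gene,
    gtex_tpm, brainspan_tpm, hdbr_tpm.  ``ndd_path``: one symbol per line.
    """
    df = pd.read_csv(genes_path, sep="\t")
    tpm: Dict[str, Dict[str, float]] = {}
    if expression_path is not None:
        edf = pd.read_csv(expression_path, sep="\t")
        for row in edf.itertuples(index=False):
            tpm[row.gene] = {
                "GTEx": float(row.gtex_tpm),
                "BrainSpan": float(row.brainspan_tpm),
                "HDBR": float(row.hdbr_tpm),
            }
    ndd: Set[str] = set()
    if ndd_path is not None:
        ndd = {
            line.strip() for line in Path(ndd_path).read_text().splitlines()
            if line.strip()
        }
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        genes.append(
            GeneAnnotation(
                gene=row.gene,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                biotype=row.biotype,
                exons=list(zip(starts, ends)),
                brain_tpm=tpm.get(row.gene, {}),
                is_ndd=row.gene in ndd,
            )
        )
    return AnnotationDb(genes)


@dataclass
class EqtlRecord:
    """A fine-mapped expression-QTL entry from a reference SV/MEI eQTL map."""

    chrom: str
    pos: int
    svtype: str
    tissue: str
    lead_variant_type: str  # "SV" or "other"
    caviar_prob: float
    caviar_rank: int
    tissue_count_me_is_causal: int
    origin: str  # "SV" or "MEI"
    eqtl_gene: str

    @property
    def is_brain_tissue(self) -> bool:
        return self.tissue.startswith("Brain_")


class EqtlTable:
    def __init__(self, records: Sequence[EqtlRecord]):
        self.records = list(records)
        self._by_chrom: Dict[str, List[EqtlRecord]] = {}
        for r in self.records:
            self._by_chrom.setdefault(r.chrom, []).append(r)

    def match(self, chrom: str, pos: int, svtype: str, max_dist: int = 100
              ) -> List[EqtlRecord]:
        cls = svtype_class(svtype)
        return [
            r for r in self._by_chrom.get(chrom, ())
            if abs(r.pos - pos) <= max_dist and svtype_class(r.svtype) == cls
        ]


def load_eqtl_table(path) -> EqtlTable:
    df = pd.read_csv(path, sep="\t")
    return EqtlTable([
        EqtlRecord(
            chrom=row.chrom, pos=int(row.pos), svtype=row.svtype,
            tissue=row.tissue, lead_variant_type=row.lead_variant_type,
            caviar_prob=float(row.caviar_prob), caviar_rank=int(row.caviar_rank),
            tissue_count_me_is_causal=int(row.tissue_count_me_is_causal),
            origin=row.origin, eqtl_gene=row.eqtl_gene,
        )
        for row in df.itertuples(index=False)
    ])


class PopAfTable:
    """Population allele frequencies keyed by (chrom, pos, SV class)."""

    def __init__(self, entries: Sequence[Tuple[str, int, str, float]]):
        self._by_chrom: Dict[str, List[Tuple[int, str, float]]] = {}
        for chrom, pos, svtype, af in entries:
            self._by_chrom.setdefault(chrom, []).append((pos, svtype, af))
        for lst in self._by_chrom.values():
            lst.sort()

    def lookup(self, chrom: str, pos: int, svtype: str, max_dist: int = 100
               ) -> Optional[float]:
        """Nearest entry of the same SV class within ``max_dist`` bp.

        Distance ties resolve to the smaller reference position.
        """
        cls = svtype_class(svtype)
        best: Optional[Tuple[int, int, float]] = None  # (dist, pos, af)
        for ref_pos, ref_type, af in self._by_chrom.get(chrom, ()):
            if svtype_class(ref_type) != cls:
                continue
            dist = abs(ref_pos - pos)
            if dist > max_dist:
                continue
            key = (dist, ref_pos)
            if best is None or key < (best[0], best[1]):
                best = (dist, ref_pos, af)
        return None if best is None else best[2]


def load_pop_af_table(path) -> PopAfTable:
    df = pd.read_csv(path, sep="\t")
    return PopAfTable([
        (row.chrom, int(row.pos), row.svtype, float(row.af))
        for row in df.itertuples(index=False)
    ])


BenignSets = Dict[str, List[Tuple[str, int, int]]]


def load_benign_regions(path) -> BenignSets:
    """Class-specific benign interval sets (gain / loss / ins / inv)."""
    df = pd.read_csv(path, sep="\t")
    sets: BenignSets = {cls: [] for cls in BENIGN_CLASSES}
    for row in df.itertuples(index=False):
        if row.benign_class not in sets:
            raise ValueError(f"unknown benign class {row.benign_class!r}")
        sets[row.benign_class].append((row.chrom, int(row.start), int(row.end)))
    return sets
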