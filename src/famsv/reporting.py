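"""Gene-level aggregation, family coverage and summary tables.

Candidate variants from the CNV and SV/MEI pipelines are collapsed to
one record per gene with union semantics over phenotypes, pipelines
and families; family coverage is the share of cohort families that
contributed at least one candidate gene.  A candidate-gene interaction
subgraph can be assembled from user-supplied edge lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .cnv import CnvLocus, VariantClass
from .prioritization import CandidateVariant

log = logging.getLogger(__name__)


@dataclass
class CandidateGene:
    gene: str
    phenotypes: Set[str] = field(default_factory=set)
    pipelines: Set[str] = field(default_factory=set)
    families: Set[str] = field(default_factory=set)
    known_ndd: bool = False


def aggregate_genes(candidates: Iterable[CandidateVariant],
                    ndd_genes: Optional[Set[str]] = None) -> List[CandidateGene]:
    """One record per unique gene, union over phenotypes/pipelines/families."""
    by_gene: Dict[str, CandidateGene] = {}
    for cand in candidates:
        for gene in cand.genes:
            rec = by_gene.setdefault(gene, CandidateGene(gene=gene))
            rec.phenotypes.add(cand.phenotype.value
                               if hasattr(cand.phenotype, "value") else cand.phenotype)
            rec.pipelines.add(cand.pipeline)
            rec.families |= set(cand.families)
            if ndd_genes and gene in ndd_genes:
                rec.known_ndd = True
    return [by_gene[g] for g in sorted(by_gene)]


def family_coverage(genes: Sequence[CandidateGene], cohort_families: int) -> int:
    """Percent of cohort families containing >=1 candidate gene (nearest int)."""
    if cohort_families < 1:
        raise ValueError("cohort_families must be >= 1")
    covered: Set[str] = set()
    for g in genes:
        covered |= g.families
    return int(100 * len(covered) / cohort_families + 0.5)


def summarize_candidates(candidates: Sequence[CandidateVariant]) -> pd.DataFrame:
    """Per-phenotype CNV-style summary: count, median length, deletion /
    duplication split and counts with positive pathogenicity scores.

    Score columns report NA when no candidate carries that score.
    """
    rows = []
    by_pheno: Dict[str, List[CandidateVariant]] = {}
    for c in candidates:
        key = c.phenotype.value if hasattr(c.phenotype, "value") else str(c.phenotype)
        by_pheno.setdefault(key, []).append(c)
    for pheno in sorted(by_pheno):
        group = by_pheno[pheno]
        lengths = sorted(
            (c.variant.end - (c.variant.start if isinstance(c.variant, CnvLocus)
                              else c.variant.pos) + 1)
            for c in group
        )
        n = len(lengths)
        median = (lengths[n // 2] if n % 2 else
                  (lengths[n // 2 - 1] + lengths[n // 2]) / 2) if n else 0
        n_del = sum(
            1 for c in group
            if (isinstance(c.variant, CnvLocus)
                and c.variant.variant_class == VariantClass.DELETION)
            or (not isinstance(c.variant, CnvLocus)
                and c.variant.svtype == "DEL")
        )
        def score_count(name: str):
            vals = [c.scores.get(name) for c in group if c.scores.get(name) is not None]
            return sum(1 for v in vals if v > 0) if vals else pd.NA
        rows.append({
            "phenotype": pheno,
            "count": n,
            "median_length_bp": median,
            "deletions": n_del,
            "duplications": n - n_del,
            "strvctvre_gt0": score_count("strvctvre"),
            "svanna_gt0": score_count("svanna"),
        })
    if not rows:
        rows = [{"phenotype": "all", "count": 0, "median_length_bp": 0,
                 "deletions": 0, "duplications": 0,
                 "strvctvre_gt0": pd.NA, "svanna_gt0": pd.NA}]
    return pd.DataFrame(rows).set_index("phenotype")


def build_interaction_subgraph(
    genes: Iterable,
    edge_lists: Sequence[Tuple[str, object]],
) -> nx.Graph:
    """Induced interaction subgraph on the candidate genes.

    ``edge_lists`` are (source_name, path) pairs of two-column gene-pair
    files.  Edges present in several sources are labeled ``"M"``; isolated
    candidates do not appear in the graph.
    """
    names = {g.gene if isinstance(g, CandidateGene) else str(g) for g in genes}
    graph = nx.Graph()
    for source, path in edge_lists:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                log.warning("%s:%d: malformed edge line skipped", path, lineno)
                continue
            a, b = parts[0], parts[1]
            if a == b or a not in names or b not in names:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["sources"].add(source)
            else:
                graph.add_edge(a, b, sources={source})
    for a, b, data in graph.edges(data=True):
        data["label"] = "M" if len(data["sources"]) > 1 else next(iter(data["sources"]))
    return graph
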