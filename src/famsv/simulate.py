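"""Synthetic family-cohort generator with planted ground truth.

Generates a complete synthetic study — pedigrees with three phenotypes,
dual-caller CNV call tables, gSV and MEI VCFs, and every annotation
sidecar the pipelines read — together with a machine-readable truth
table.  Variants are planted in three layers:

* *pattern* variants: sequence SVs whose genotypes realize one strict
  inheritance model (de novo, autosomal recessive/dominant and the
  X-linked counterparts) in one family;
* *candidate* variants: one per prioritization pipeline class (cnv,
  af_exonic, af_intronic, eqtl_intronic, eqtl_intergenic), constructed
  to survive every downstream filter;
* *background* variants: benign CNVs matching benign regions, common
  SVs/MEIs with a beta-distributed allele-frequency spectrum (Alu-
  dominant subtype mix), and MEI loci violating individual QC rules —
  each guaranteed by construction to fail at least one filter.

Identical (config, seed) reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .cnv import Caller, CnvCall
from .core import GenotypeClass
from .pedigree import Cohort, Individual, Sex
from .svmei import SvRecord
from .vcfio import write_cnv_calls_tsv, write_sv_vcf

REF = GenotypeClass.REF
HET = GenotypeClass.HET
HOM_ALT = GenotypeClass.HOM_ALT
MISSING = GenotypeClass.MISSING

PATTERNS = (
    "de_novo",
    "autosomal_recessive",
    "autosomal_dominant",
    "x_linked_recessive",
    "x_linked_dominant",
    "x_linked_de_novo",
)
CANDIDATE_CLASSES = (
    "cnv", "af_exonic", "af_intronic", "eqtl_intronic", "eqtl_intergenic",
)
_DOMINANT_PATTERNS = {"autosomal_dominant", "x_linked_dominant"}
_X_PATTERNS = {"x_linked_recessive", "x_linked_dominant", "x_linked_de_novo"}


@dataclass
class CallerNoise:
    """Array/sequencing caller imperfections applied to planted calls."""

    jitter_frac: float = 0.05        # breakpoint jitter, fraction of length
    split_prob: float = 0.0          # probability callerB splits a CNV in two
    genotype_missing_rate: float = 0.0
    benign_jitter_frac: float = 0.02


@dataclass
class PhenotypeModel:
    dominant_family_fraction: float = 0.4
    extra_li_rate: float = 0.05      # LI-only affection among ASD-unaffected
    extra_ri_rate: float = 0.05


@dataclass
class Background:
    benign_cnv_loci: int = 40
    benign_cnvs_per_sample: Tuple[int, int] = (4, 10)   # uniform inclusive
    n_common_svs: int = 60
    n_background_meis: int = 60
    n_qcfail_meis: int = 30
    common_af_beta: Tuple[float, float] = (2.0, 5.0)
    mei_subtype_mix: Dict[str, float] = field(
        default_factory=lambda: {"MEI_ALU": 0.7, "MEI_LINE1": 0.2, "MEI_SVA": 0.1}
    )
    duplicate_representation_rate: float = 0.3
    n_qcfail_cnv_calls: int = 12


@dataclass
class SimConfig:
    n_families: int = 50
    family_structures: Dict[str, float] = field(
        default_factory=lambda: {"trio": 0.4, "quad": 0.4, "extended": 0.2}
    )
    variants_per_pattern: Dict[str, int] = field(
        default_factory=lambda: {p: 100 for p in PATTERNS}
    )
    candidates_per_class: Dict[str, int] = field(
        default_factory=lambda: {c: 5 for c in CANDIDATE_CLASSES}
    )
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    background: Background = field(default_factory=Background)
    caller_noise: CallerNoise = field(default_factory=CallerNoise)
    seed: int = 0

    def __post_init__(self):
        total = sum(self.family_structures.values())
        if not np.isclose(total, 1.0):
            raise ValueError("family_structures probabilities must sum to 1")
        for rate in (self.phenotype_model.extra_li_rate,
                     self.phenotype_model.extra_ri_rate,
                     self.caller_noise.jitter_frac,
                     self.caller_noise.split_prob,
                     self.caller_noise.genotype_missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if any(v < 0 for v in self.variants_per_pattern.values()):
            raise ValueError("variants_per_pattern counts must be >= 0")
        if any(v < 0 for v in self.candidates_per_class.values()):
            raise ValueError("candidates_per_class counts must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("phenotype_model", PhenotypeModel),
                         ("background", Background),
                         ("caller_noise", CallerNoise)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


@dataclass
class SyntheticStudy:
    config: SimConfig
    outdir: Path
    paths: Dict[str, Path]
    cohort: Cohort
    truth: pd.DataFrame
    samples: List[str]


# ------------------------------------------------------------------ families

@dataclass
class _Family:
    fam_id: str
    members: Dict[str, Individual]   # role -> Individual
    is_dominant: bool
    batch: str

    def trio_child(self) -> Individual:
        return self.members["c1"]

    def all_ids(self) -> List[str]:
        return [m.individual_id for m in self.members.values()]


def _make_families(config: SimConfig, rng: np.random.Generator
                   ) -> Tuple[List[_Family], Cohort]:
    structures = sorted(config.family_structures)
    probs = [config.family_structures[s] for s in structures]
    n_dom = int(round(config.n_families * config.phenotype_model.dominant_family_fraction))
    families: List[_Family] = []
    cohort = Cohort()
    for i in range(config.n_families):
        fam_id = f"FAM{i + 1:03d}"
        structure = rng.choice(structures, p=probs)
        is_dominant = i < n_dom
        members: Dict[str, Individual] = {}

        def add(role, num, sex, father=None, mother=None):
            iid = f"{fam_id}-{num:03d}"
            members[role] = Individual(
                individual_id=iid, family_id=fam_id,
                father_id=father, mother_id=mother, sex=sex,
                asd=False, li=False, ri=False,
            )

        if structure == "extended":
            add("gf", 1, Sex.MALE)
            add("gm", 2, Sex.FEMALE)
            add("father", 3, Sex.MALE,
                father=f"{fam_id}-001", mother=f"{fam_id}-002")
            add("mother", 4, Sex.FEMALE)
            add("c1", 5, Sex.MALE,
                father=f"{fam_id}-003", mother=f"{fam_id}-004")
            add("c2", 6, Sex.FEMALE,
                father=f"{fam_id}-003", mother=f"{fam_id}-004")
        else:
            add("father", 1, Sex.MALE)
            add("mother", 2, Sex.FEMALE)
            add("c1", 3, Sex.MALE,
                father=f"{fam_id}-001", mother=f"{fam_id}-002")
            if structure == "quad":
                add("c2", 4, Sex.FEMALE,
                    father=f"{fam_id}-001", mother=f"{fam_id}-002")

        members["c1"].asd = True
        if is_dominant:
            members["mother"].asd = True
        for m in members.values():
            if m.asd is not True:
                if rng.random() < config.phenotype_model.extra_li_rate:
                    m.li = True
                if rng.random() < config.phenotype_model.extra_ri_rate:
                    m.ri = True
        fam = _Family(fam_id=fam_id, members=members, is_dominant=is_dominant,
                      batch=f"batch{i % 3 + 1}")
        families.append(fam)
        cohort.families[fam_id] = list(members.values())
    return families, cohort


def write_ped(cohort: Cohort, path) -> None:
    code = {True: "2", False: "1", None: "0"}
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    lines = []
    for fam_id in sorted(cohort.families):
        for ind in cohort.families[fam_id]:
            lines.append("\t".join([
                fam_id, ind.individual_id,
                ind.father_id or "0", ind.mother_id or "0",
                sex_code[ind.sex],
                code[ind.asd], code[ind.li], code[ind.ri],
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- genotypes

def _base_genotypes(samples: Sequence[str]) -> Dict[str, GenotypeClass]:
    return {s: REF for s in samples}


def _hwe_genotypes(samples: Sequence[str], af: float, rng: np.random.Generator
                   ) -> Dict[str, GenotypeClass]:
    q = 1.0 - af
    classes = (REF, HET, HOM_ALT)
    idx = rng.choice(3, size=len(samples), p=[q * q, 2 * af * q, af * af])
    return {s: classes[i] for s, i in zip(samples, idx)}


def _pattern_genotypes(pattern: str, fam: _Family,
                       samples: Sequence[str]) -> Dict[str, GenotypeClass]:
    g = _base_genotypes(samples)
    m = fam.members
    c1 = m["c1"].individual_id
    father = m["father"].individual_id
    mother = m["mother"].individual_id
    if pattern == "de_novo":
        g[c1] = HET
    elif pattern == "autosomal_recessive":
        g[c1] = HOM_ALT
        g[father] = HET
        g[mother] = HET
        if "c2" in m:
            g[m["c2"].individual_id] = HET
        if "gf" in m:
            g[m["gf"].individual_id] = HET
    elif pattern == "autosomal_dominant":
        g[mother] = HET
        g[c1] = HET
    elif pattern == "x_linked_recessive":
        g[c1] = HOM_ALT       # hemizygous carrier son
        g[mother] = HET
    elif pattern == "x_linked_dominant":
        g[mother] = HET
        g[c1] = HOM_ALT
    elif pattern == "x_linked_de_novo":
        g[c1] = HOM_ALT
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return g


# ------------------------------------------------------------------ genome

_CHROM = {
    "benign_cnv": "chr1",
    "cnv_candidates": "chr2",
    "patterns_a": "chr3",
    "patterns_b": "chr4",
    "sv_candidates": "chr5",
    "background_genic": "chr6",
    "background_intergenic": "chr7",
    "eqtl_targets": "chr8",
    "x_patterns": "chrX",
}


class _Slots:
    def __init__(self, chrom: str, start: int, step: int):
        self.chrom = chrom
        self.next = start
        self.step = step

    def take(self) -> Tuple[str, int]:
        pos = self.next
        self.next += self.step
        return self.chrom, pos


_GENE_EXON_LEN = 1500
_GENE_INTRON_LEN = 9000
_GENE_N_EXONS = 4
_GENE_SPAN = _GENE_N_EXONS * _GENE_EXON_LEN + (_GENE_N_EXONS - 1) * _GENE_INTRON_LEN


def _gene_row(name: str, chrom: str, start: int, biotype: str = "protein_coding"
              ) -> Dict:
    exon_starts, exon_ends = [], []
    pos = start
    for _ in range(_GENE_N_EXONS):
        exon_starts.append(pos)
        exon_ends.append(pos + _GENE_EXON_LEN - 1)
        pos += _GENE_EXON_LEN + _GENE_INTRON_LEN
    return {
        "gene": name, "chrom": chrom, "start": start,
        "end": start + _GENE_SPAN - 1, "biotype": biotype,
        "exon_starts": ",".join(map(str, exon_starts)),
        "exon_ends": ",".join(map(str, exon_ends)),
    }


def _gene_exon2_start(gene_start: int) -> int:
    return gene_start + _GENE_EXON_LEN + _GENE_INTRON_LEN


def _gene_intron2(gene_start: int) -> Tuple[int, int]:
    e2 = _gene_exon2_start(gene_start)
    return e2 + _GENE_EXON_LEN, e2 + _GENE_EXON_LEN + _GENE_INTRON_LEN - 1


# ----------------------------------------------------------------- simulate

def simulate_cohort(config: SimConfig, outdir, seed: Optional[int] = None
                    ) -> SyntheticStudy:
    """Generate the full synthetic study under ``outdir``.

    Raises at generation time when the requested planted variants cannot be
    hosted (e.g. dominant-pattern variants with no dominant-type family).
    """
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    families, cohort = _make_families(config, rng)
    samples = [ind.individual_id for fam in families
               for ind in fam.members.values()]
    rec_fams = [f for f in families if not f.is_dominant]
    dom_fams = [f for f in families if f.is_dominant]

    needs_dom = any(config.variants_per_pattern.get(p, 0) > 0
                    for p in _DOMINANT_PATTERNS)
    needs_dom |= any(config.candidates_per_class.get(c, 0) > 0
                     for c in ("eqtl_intronic", "eqtl_intergenic"))
    if needs_dom and not dom_fams:
        raise ValueError("planted dominant-pattern variants need at least one "
                         "dominant-type family (affected parent)")
    needs_rec = any(config.variants_per_pattern.get(p, 0) > 0
                    for p in set(PATTERNS) - _DOMINANT_PATTERNS)
    needs_rec |= any(config.candidates_per_class.get(c, 0) > 0
                     for c in ("cnv", "af_exonic", "af_intronic"))
    if needs_rec and not rec_fams:
        raise ValueError("planted recessive/de novo variants need at least one "
                         "family with unaffected parents")

    gene_rows: List[Dict] = []
    expr_rows: List[Dict] = []
    ndd_genes: List[str] = []
    benign_rows: List[Dict] = []
    eqtl_rows: List[Dict] = []
    pop_mei_rows: List[Dict] = []
    pop_sv_rows: List[Dict] = []
    truth_rows: List[Dict] = []
    gsvs: List[SvRecord] = []
    meis: List[SvRecord] = []
    cnv_calls: List[CnvCall] = []

    gene_counter = [0]

    def new_gene(chrom: str, start: int, *, brain: bool, ndd: bool = False,
                 biotype: str = "protein_coding") -> str:
        gene_counter[0] += 1
        name = f"GENE{gene_counter[0]:04d}"
        gene_rows.append(_gene_row(name, chrom, start, biotype))
        if brain:
            tpm = {"gtex_tpm": round(float(rng.uniform(8, 60)), 2),
                   "brainspan_tpm": round(float(rng.uniform(0, 4)), 2),
                   "hdbr_tpm": round(float(rng.uniform(0, 4)), 2)}
        else:
            tpm = {"gtex_tpm": round(float(rng.uniform(0, 4.5)), 2),
                   "brainspan_tpm": round(float(rng.uniform(0, 4.5)), 2),
                   "hdbr_tpm": round(float(rng.uniform(0, 4.5)), 2)}
        expr_rows.append({"gene": name, **tpm})
        if ndd:
            ndd_genes.append(name)
        return name

    var_counter = [0]

    def new_id(prefix: str = "VAR") -> str:
        var_counter[0] += 1
        return f"{prefix}{var_counter[0]:05d}"

    def truth(variant_id, planted_class, pattern, carriers, target_gene,
              expected_pipeline, expected_survival, chrom, start, end,
              n_representations=1):
        truth_rows.append({
            "variant_id": variant_id, "planted_class": planted_class,
            "inheritance_pattern": pattern,
            "carriers": ";".join(carriers),
            "target_gene": target_gene,
            "expected_pipeline": expected_pipeline,
            "expected_survival": expected_survival,
            "chrom": chrom, "start": start, "end": end,
            "n_representations": n_representations,
        })

    noise = config.caller_noise

    # ---------------- planted pattern SVs -------------------------------
    slots_a = _Slots(_CHROM["patterns_a"], 1_000_000, 20_000)
    slots_b = _Slots(_CHROM["patterns_b"], 1_000_000, 20_000)
    slots_x = _Slots(_CHROM["x_patterns"], 1_000_000, 20_000)
    for p_idx, pattern in enumerate(PATTERNS):
        count = config.variants_per_pattern.get(pattern, 0)
        hosts = dom_fams if pattern in _DOMINANT_PATTERNS else rec_fams
        for k in range(count):
            fam = hosts[k % len(hosts)]
            if pattern in _X_PATTERNS:
                chrom, pos = slots_x.take()
            else:
                chrom, pos = (slots_a if p_idx % 2 else slots_b).take()
            svtype = "DEL" if k % 2 else "INS"
            length = int(rng.integers(150, 800))
            end = pos + length - 1 if svtype == "DEL" else pos
            genotypes = _pattern_genotypes(pattern, fam, samples)
            vid = new_id("PAT")
            gsvs.append(SvRecord(
                record_id=vid, chrom=chrom, pos=pos, end=end, svtype=svtype,
                strand="+", genotypes=genotypes, source="gsv_callset",
            ))
            carriers = sorted(s for s, g in genotypes.items() if g.is_carrier)
            truth(vid, "pattern", pattern, carriers, "", "", False,
                  chrom, pos, end)

    # ---------------- planted candidate variants ------------------------
    # CNV candidates: de novo duplication/deletion in an affected child,
    # spanning a brain-expressed protein-coding gene, dual-caller calls.
    cnv_slots = _Slots(_CHROM["cnv_candidates"], 1_000_000, 1_000_000)
    for k in range(config.candidates_per_class.get("cnv", 0)):
        fam = rec_fams[k % len(rec_fams)]
        chrom, start = cnv_slots.take()
        length = 60_000
        end = start + length - 1
        cn = 1 if k % 2 else 3
        gene = new_gene(chrom, start + 5_000, brain=True)
        child = fam.trio_child().individual_id
        vid = new_id("CNVC")
        for caller in (Caller.A, Caller.B):
            j = int(noise.jitter_frac * length)
            s = start + int(rng.integers(-j, j + 1)) if j else start
            e = end + int(rng.integers(-j, j + 1)) if j else end
            cnv_calls.append(CnvCall(
                sample_id=child, caller=caller, batch=fam.batch, chrom=chrom,
                start=s, end=e, copy_number=cn,
                n_probes=max(5, (e - s + 1) // 2000),
                confidence=(None if caller == Caller.A
                            else round(float(rng.uniform(12, 30)), 2)),
            ))
        truth(vid, "cnv", "de_novo", [child], gene, "cnv", True,
              chrom, start, end)

    sv_slots = _Slots(_CHROM["sv_candidates"], 1_000_000, 120_000)

    def plant_denovo_sv(kind: str, k: int):
        fam = rec_fams[(k + 7) % len(rec_fams)]
        chrom, slot = sv_slots.take()
        as_mei = k % 2 == 1
        gene_start = slot
        if kind == "af_exonic":
            gene = new_gene(chrom, gene_start, brain=True)
            pos = _gene_exon2_start(gene_start) + 100
        else:
            gene = new_gene(chrom, gene_start, brain=True, ndd=True)
            pos = _gene_intron2(gene_start)[0] + 500
        if as_mei:
            svtype, source = "MEI_ALU", "mei_insertion"
            end = pos
        else:
            svtype, source = "DEL", "gsv_callset"
            end = pos + int(rng.integers(150, 400))
        genotypes = _base_genotypes(samples)
        child = fam.trio_child().individual_id
        genotypes[child] = HET
        vid = new_id("AFC")
        rec = SvRecord(
            record_id=vid, chrom=chrom, pos=pos, end=end, svtype=svtype,
            strand="+", genotypes=genotypes, source=source,
            assess=5 if as_mei else None, filter_field="PASS",
            split_reads=6 if as_mei else None,
        )
        (meis if as_mei else gsvs).append(rec)
        af = round(float(rng.uniform(0.005, 0.04)), 4)
        row = {"chrom": chrom, "pos": pos + int(rng.integers(-40, 41)),
               "svtype": svtype, "af": af}
        (pop_mei_rows if as_mei else pop_sv_rows).append(row)
        truth(vid, kind, "de_novo", [child], gene, kind, True, chrom, pos, end)

    for k in range(config.candidates_per_class.get("af_exonic", 0)):
        plant_denovo_sv("af_exonic", k)
    for k in range(config.candidates_per_class.get("af_intronic", 0)):
        plant_denovo_sv("af_intronic", k)

    eqtl_target_slots = _Slots(_CHROM["eqtl_targets"], 1_000_000, 100_000)

    def plant_eqtl_sv(kind: str, k: int):
        fam = dom_fams[(k + 3) % len(dom_fams)]
        chrom, slot = sv_slots.take()
        as_mei = k % 2 == 1
        if kind == "eqtl_intronic":
            host_start = slot
            new_gene(chrom, host_start, brain=False)   # host gene, low TPM
            pos = _gene_intron2(host_start)[0] + 400
        else:
            pos = slot + 50_000   # gap well away from any gene model
        if as_mei:
            svtype, source = "MEI_ALU", "mei_insertion"
            end = pos
        else:
            svtype, source = "DEL", "gsv_callset"
            end = pos + int(rng.integers(150, 330))
        af = round(float(rng.uniform(0.15, 0.3)), 3)
        genotypes = _hwe_genotypes(samples, af, rng)
        m = fam.members
        genotypes[m["mother"].individual_id] = HET
        genotypes[m["c1"].individual_id] = HET
        genotypes[m["father"].individual_id] = REF
        for role in ("c2", "gf", "gm"):
            if role in m:
                genotypes[m[role].individual_id] = REF
        target = new_gene(*eqtl_target_slots.take(), brain=True)
        n_tissues = int(rng.integers(3, 16))
        eqtl_rows.append({
            "chrom": chrom, "pos": pos + int(rng.integers(-40, 41)),
            "svtype": svtype, "tissue": "Brain_Cortex",
            "lead_variant_type": "other" if as_mei else "SV",
            "caviar_prob": 0.0 if as_mei else round(float(rng.uniform(0.15, 0.6)), 3),
            "caviar_rank": 99 if as_mei else int(rng.integers(1, 6)),
            "tissue_count_me_is_causal": n_tissues if as_mei else 0,
            "origin": "MEI" if as_mei else "SV",
            "eqtl_gene": target,
        })
        vid = new_id("EQC")
        rec = SvRecord(
            record_id=vid, chrom=chrom, pos=pos, end=end, svtype=svtype,
            strand="+", genotypes=genotypes, source=source,
            assess=5 if as_mei else None, filter_field="PASS",
            split_reads=6 if as_mei else None,
        )
        (meis if as_mei else gsvs).append(rec)
        carriers = sorted(s for s, g in genotypes.items() if g.is_carrier)
        truth(vid, kind, "autosomal_dominant", carriers, target, kind, True,
              chrom, pos, end)

    for k in range(config.candidates_per_class.get("eqtl_intronic", 0)):
        plant_eqtl_sv("eqtl_intronic", k)
    for k in range(config.candidates_per_class.get("eqtl_intergenic", 0)):
        plant_eqtl_sv("eqtl_intergenic", k)

    # ---------------- background: benign CNVs ---------------------------
    bg = config.background
    pool_slots = _Slots(_CHROM["benign_cnv"], 1_000_000, 1_000_000)
    pool: List[Tuple[str, int, int, int]] = []   # chrom, start, end, CN
    for i in range(bg.benign_cnv_loci):
        chrom, start = pool_slots.take()
        length = int(rng.integers(15_000, 80_000))
        cn = 3 if i % 4 == 0 else 1
        pool.append((chrom, start, start + length - 1, cn))
        benign_rows.append({
            "benign_class": "gain" if cn > 2 else "loss",
            "chrom": chrom, "start": start, "end": start + length - 1,
        })
        vid = new_id("BEN")
        truth(vid, "background_benign_cnv", "", [], "", "", False,
              chrom, start, start + length - 1)
    # a few benign regions of the sequence-SV classes
    for i, cls in enumerate(("ins", "inv", "ins")):
        chrom, start = pool_slots.take()
        benign_rows.append({"benign_class": cls, "chrom": chrom,
                            "start": start, "end": start + 500})

    lo, hi = bg.benign_cnvs_per_sample
    for fam in families:
        for ind in fam.members.values():
            k = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
            for idx in sorted(chosen):
                chrom, start, end, cn = pool[idx]
                length = end - start + 1
                j = max(1, int(noise.benign_jitter_frac * length))
                for caller in (Caller.A, Caller.B):
                    if caller == Caller.B and rng.random() > 0.7:
                        continue
                    s = start + int(rng.integers(-j, j + 1))
                    e = end + int(rng.integers(-j, j + 1))
                    cnv_calls.append(CnvCall(
                        sample_id=ind.individual_id, caller=caller,
                        batch=fam.batch, chrom=chrom, start=s, end=e,
                        copy_number=cn, n_probes=max(5, (e - s + 1) // 2000),
                        confidence=(None if caller == Caller.A
                                    else round(float(rng.uniform(11, 28)), 2)),
                    ))

    # QC-fail CNV calls: length, probe, confidence and sex-chromosome rules
    qcfail_specs = [
        {"length": 8_000, "probes": 20, "conf": 20.0, "chrom": "chr1"},
        {"length": 8_000_000, "probes": 400, "conf": 20.0, "chrom": "chr1"},
        {"length": 50_000, "probes": 3, "conf": 20.0, "chrom": "chr1"},
        {"length": 50_000, "probes": 20, "conf": 6.0, "chrom": "chr1"},
        {"length": 50_000, "probes": 20, "conf": 20.0, "chrom": "chrX"},
        {"length": 50_000, "probes": 20, "conf": 20.0, "chrom": "chrY"},
    ]
    for i in range(bg.n_qcfail_cnv_calls):
        spec = qcfail_specs[i % len(qcfail_specs)]
        fam = families[i % len(families)]
        ind = fam.members["father"]
        start = 45_000_000 + i * 10_000_000 % 14_000_000 + i * 97_000
        cnv_calls.append(CnvCall(
            sample_id=ind.individual_id, caller=Caller.B, batch=fam.batch,
            chrom=spec["chrom"], start=start, end=start + spec["length"] - 1,
            copy_number=1, n_probes=spec["probes"], confidence=spec["conf"],
        ))

    # ---------------- background: common SVs and MEIs -------------------
    genic_slots = _Slots(_CHROM["background_genic"], 1_000_000, 60_000)
    inter_slots = _Slots(_CHROM["background_intergenic"], 1_000_000, 20_000)
    a, b = bg.common_af_beta
    sv_cycle = ("DEL", "INS", "DUP", "INV")
    for i in range(bg.n_common_svs):
        genic = i % 2 == 0
        if genic:
            chrom, slot = genic_slots.take()
            new_gene(chrom, slot, brain=False)
            pos = _gene_intron2(slot)[0] + 200
        else:
            chrom, pos = inter_slots.take()
        svtype = sv_cycle[i % 4]
        length = int(rng.integers(100, 2_000))
        end = pos if svtype == "INS" else pos + length - 1
        af = float(np.clip(rng.beta(a, b), 0.02, 0.9))
        vid = new_id("BGS")
        gsvs.append(SvRecord(
            record_id=vid, chrom=chrom, pos=pos, end=end, svtype=svtype,
            strand="+" if i % 2 else "-",
            genotypes=_hwe_genotypes(samples, af, rng), source="gsv_callset",
        ))
        truth(vid, "background_common_sv", "", [], "", "", False,
              chrom, pos, end)

    subtypes = sorted(bg.mei_subtype_mix)
    subtype_p = [bg.mei_subtype_mix[s] for s in subtypes]
    for i in range(bg.n_background_meis):
        chrom, pos = inter_slots.take()
        subtype = str(rng.choice(subtypes, p=subtype_p))
        is_deletion = rng.random() < 0.1
        af = float(np.clip(rng.beta(a, b), 0.02, 0.9))
        genotypes = _hwe_genotypes(samples, af, rng)
        vid = new_id("BGM")
        n_rep = 1
        if is_deletion:
            rec = SvRecord(
                record_id=vid, chrom=chrom, pos=pos, end=pos + 300,
                svtype="DEL", strand="+", genotypes=genotypes,
                source="mei_deletion",
            )
        else:
            rec = SvRecord(
                record_id=vid, chrom=chrom, pos=pos, end=pos,
                svtype=subtype, strand="+", genotypes=genotypes,
                source="mei_insertion", assess=int(rng.integers(3, 6)),
                filter_field="PASS", split_reads=int(rng.integers(3, 12)),
            )
            if rng.random() < bg.duplicate_representation_rate:
                # the same event seen by the general SV caller
                jitter = int(rng.integers(-50, 51))
                gsvs.append(SvRecord(
                    record_id=f"{vid}@gsv", chrom=chrom, pos=pos + jitter,
                    end=pos + jitter, svtype="INS", strand="+",
                    genotypes=dict(genotypes), source="gsv_callset",
                ))
                n_rep = 2
        meis.append(rec)
        pop_mei_rows.append({
            "chrom": chrom, "pos": pos + int(rng.integers(-40, 41)),
            "svtype": subtype if not is_deletion else "DEL",
            "af": round(af, 4),
        })
        truth(vid, "background_common_mei", "", [], "", "", False,
              chrom, pos, rec.end, n_representations=n_rep)

    # MEI loci violating one QC rule each
    qcfail_kinds = ("assess", "filter", "split_reads", "missingness", "hwe")
    for i in range(bg.n_qcfail_meis):
        kind = qcfail_kinds[i % len(qcfail_kinds)]
        chrom, pos = inter_slots.take()
        assess, filt, sr = 5, "PASS", 6
        if kind == "hwe":
            genotypes = _base_genotypes(samples)
            n_alt = max(10, len(samples) // 5)
            for s in samples[:n_alt]:
                genotypes[s] = HOM_ALT
        else:
            genotypes = _hwe_genotypes(samples, 0.05, rng)
            if kind == "assess":
                assess = 2
            elif kind == "filter":
                filt = "lc"
            elif kind == "split_reads":
                sr = 1
            elif kind == "missingness":
                n_miss = int(0.08 * len(samples)) + 1
                for s in samples[:n_miss]:
                    genotypes[s] = MISSING
        vid = new_id("QCF")
        meis.append(SvRecord(
            record_id=vid, chrom=chrom, pos=pos, end=pos, svtype="MEI_ALU",
            strand="+", genotypes=genotypes, source="mei_insertion",
            assess=assess, filter_field=filt, split_reads=sr,
        ))
        truth(vid, f"background_qcfail_{kind}", "", [], "", "", False,
              chrom, pos, pos)

    # a handful of NDD decoy genes not touched by any variant
    for _ in range(5):
        chrom, slot = genic_slots.take()
        new_gene(chrom, slot, brain=True, ndd=True)

    if noise.genotype_missing_rate > 0:
        child_seed = int(rng.integers(0, 2**31 - 1))
        gsvs = perturb_genotypes(gsvs, noise.genotype_missing_rate, child_seed)
        meis = perturb_genotypes(meis, noise.genotype_missing_rate, child_seed + 1)

    # ------------------------------------------------------------- write
    paths = {
        "ped": outdir / "cohort.ped",
        "cnv_callerA": outdir / "cnv_callerA.tsv",
        "cnv_callerB": outdir / "cnv_callerB.tsv",
        "gsv_vcf": outdir / "gsv.vcf",
        "mei_vcf": outdir / "mei.vcf",
        "genes": outdir / "genes.tsv",
        "expression": outdir / "expression.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "pop_af_mei": outdir / "pop_af_mei.tsv",
        "pop_af_sv": outdir / "pop_af_sv.tsv",
        "benign": outdir / "benign_regions.tsv",
        "ndd": outdir / "ndd_genes.txt",
        "truth": outdir / "truth.tsv",
    }
    write_ped(cohort, paths["ped"])
    write_cnv_calls_tsv([c for c in cnv_calls if c.caller == Caller.A],
                        paths["cnv_callerA"])
    write_cnv_calls_tsv([c for c in cnv_calls if c.caller == Caller.B],
                        paths["cnv_callerB"])
    write_sv_vcf(sorted(gsvs, key=lambda r: (r.chrom, r.pos, r.record_id)),
                 samples, paths["gsv_vcf"])
    write_sv_vcf(sorted(meis, key=lambda r: (r.chrom, r.pos, r.record_id)),
                 samples, paths["mei_vcf"])
    pd.DataFrame(gene_rows).to_csv(paths["genes"], sep="\t", index=False)
    pd.DataFrame(expr_rows).to_csv(paths["expression"], sep="\t", index=False)
    eqtl_cols = ["chrom", "pos", "svtype", "tissue", "lead_variant_type",
                 "caviar_prob", "caviar_rank", "tissue_count_me_is_causal",
                 "origin", "eqtl_gene"]
    pd.DataFrame(eqtl_rows, columns=eqtl_cols).to_csv(
        paths["eqtl"], sep="\t", index=False)
    af_cols = ["chrom", "pos", "svtype", "af"]
    pd.DataFrame(pop_mei_rows, columns=af_cols).to_csv(
        paths["pop_af_mei"], sep="\t", index=False)
    pd.DataFrame(pop_sv_rows, columns=af_cols).to_csv(
        paths["pop_af_sv"], sep="\t", index=False)
    pd.DataFrame(benign_rows).to_csv(paths["benign"], sep="\t", index=False)
    Path(paths["ndd"]).write_text("\n".join(sorted(set(ndd_genes))) + "\n")
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(paths["truth"], sep="\t", index=False)

    return SyntheticStudy(config=config, outdir=outdir, paths=paths,
                          cohort=cohort, truth=truth_df, samples=samples)


def perturb_genotypes(callset: Sequence[SvRecord], missing_rate: float,
                      seed: int) -> List[SvRecord]:
    """Independently set each genotype to missing with the given rate."""
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: List[SvRecord] = []
    for rec in callset:
        genotypes = {}
        for s in rec.genotypes:   # dict order is insertion order: stable
            if rng.random() < missing_rate:
                genotypes[s] = MISSING
            else:
                genotypes[s] = rec.genotypes[s]
        out.append(replace(rec, genotypes=genotypes))
    return out
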