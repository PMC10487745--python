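"""Reading and writing the pipeline's interchange formats.

CNV loci and SV/MEI records travel as VCF 4.2 with symbolic ALT
alleles (written and read through pysam); single-caller CNV calls
travel as TSV tables emulating array-caller output.
"""

from __future__ import annotations

import contextlib
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
import pysam

from .cnv import Caller, CnvCall, CnvLocus, VariantClass
from .core import GenotypeClass, chrom_sort_key
from .svmei import SvRecord

_GT_TO_TUPLE = {
    GenotypeClass.REF: (0, 0),
    GenotypeClass.HET: (0, 1),
    GenotypeClass.HOM_ALT: (1, 1),
    GenotypeClass.MISSING: (None, None),
}

_ALT_FOR_SVTYPE = {
    "DEL": "<DEL>", "INS": "<INS>", "DUP": "<DUP>", "INV": "<INV>",
    "MEI_ALU": "<INS:ME:ALU>", "MEI_LINE1": "<INS:ME:LINE1>",
    "MEI_SVA": "<INS:ME:SVA>",
}


@contextlib.contextmanager
def _quiet_htslib():
    # htslib grumbles while pysam fills INFO/END on symbolic records; the
    # emitted END values are correct
    verbosity = pysam.set_verbosity(0)
    try:
        yield
    finally:
        pysam.set_verbosity(verbosity)


def _contig_lines(chrom_ends: Dict[str, int]) -> List[str]:
    return [
        f"##contig=<ID={chrom},length={chrom_ends[chrom] + 10_000}>"
        for chrom in sorted(chrom_ends, key=chrom_sort_key)
    ]


# ---------------------------------------------------------------- CNV VCF

def write_cnv_vcf(loci: Sequence[CnvLocus], samples: Sequence[str], path) -> None:
    """Emit merged CNV loci as a VCF with symbolic <DEL>/<DUP> alleles and a
    per-sample integer CN field; non-carriers are written as CN2."""
    header = pysam.VariantHeader()
    chrom_ends: Dict[str, int] = {}
    for locus in loci:
        chrom_ends[locus.chrom] = max(chrom_ends.get(locus.chrom, 0), locus.end)
    for line in _contig_lines(chrom_ends):
        header.add_line(line)
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">')
    header.add_samples(list(samples))
    with _quiet_htslib(), pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus in loci:
            rec = vcf.new_record(
                contig=locus.chrom, start=locus.start - 1,
                alleles=("N", "<DEL>" if locus.variant_class == VariantClass.DELETION
                         else "<DUP>"),
                id=locus.locus_id,
            )
            rec.info["SVTYPE"] = ("DEL" if locus.variant_class == VariantClass.DELETION
                                  else "DUP")
            # htslib derives END = POS + |SVLEN| for symbolic alleles
            svlen = locus.end - locus.start
            rec.info["SVLEN"] = (-svlen if locus.variant_class == VariantClass.DELETION
                                 else svlen)
            for s in samples:
                rec.samples[s]["CN"] = locus.copy_number(s)
            # set last: later INFO updates would re-derive END from rlen
            rec.stop = locus.end
            vcf.write(rec)


def read_cnv_vcf(path) -> List[CnvLocus]:
    loci: List[CnvLocus] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            vclass = (VariantClass.DELETION if rec.info["SVTYPE"] == "DEL"
                      else VariantClass.DUPLICATION)
            genotypes = {
                s: int(rec.samples[s]["CN"]) for s in rec.samples
                if rec.samples[s]["CN"] is not None and rec.samples[s]["CN"] != 2
            }
            loci.append(CnvLocus(
                locus_id=rec.id or "",
                chrom=rec.contig,
                start=rec.pos,
                end=rec.stop,
                variant_class=vclass,
                genotypes=genotypes,
            ))
    return loci


# ----------------------------------------------------------------- SV VCF

def write_sv_vcf(records: Sequence[SvRecord], samples: Sequence[str], path) -> None:
    header = pysam.VariantHeader()
    chrom_ends: Dict[str, int] = {}
    for r in records:
        chrom_ends[r.chrom] = max(chrom_ends.get(r.chrom, 0), r.end)
    for line in _contig_lines(chrom_ends):
        header.add_line(line)
    for alt in ("DEL", "INS", "DUP", "INV", "INS:ME:ALU", "INS:ME:LINE1",
                "INS:ME:SVA"):
        header.add_line(f'##ALT=<ID={alt},Description="{alt}">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=STRANDS,Number=1,Type=String,Description="Strand">')
    header.add_line('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Call set">')
    header.add_line('##INFO=<ID=ASSESS,Number=1,Type=Integer,'
                    'Description="MELT evidence tier">')
    header.add_line('##INFO=<ID=SR,Number=1,Type=Integer,'
                    'Description="Split-read support">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for filt in ("rSD", "lc", "hDP"):
        header.add_line(f'##FILTER=<ID={filt},Description="{filt}">')
    header.add_samples(list(samples))
    with _quiet_htslib(), pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1,
                alleles=("N", _ALT_FOR_SVTYPE[r.svtype]),
                id=r.record_id,
            )
            rec.info["SVTYPE"] = r.svtype
            rec.info["STRANDS"] = r.strand
            rec.info["SOURCE"] = r.source
            if r.assess is not None:
                rec.info["ASSESS"] = r.assess
            if r.split_reads is not None:
                rec.info["SR"] = r.split_reads
            rec.filter.add(r.filter_field)
            for s in samples:
                rec.samples[s]["GT"] = _GT_TO_TUPLE[r.genotypes.get(
                    s, GenotypeClass.MISSING)]
            # set last: later INFO updates would re-derive END from rlen
            if r.end != r.pos:
                rec.stop = r.end
            vcf.write(rec)


def _gt_class(gt) -> GenotypeClass:
    alleles = [a for a in (gt or ()) if a is not None]
    if not alleles:
        return GenotypeClass.MISSING
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return GenotypeClass.REF
    if n_alt == len(alleles):
        return GenotypeClass.HOM_ALT
    return GenotypeClass.HET


def read_sv_vcf(path) -> List[SvRecord]:
    records: List[SvRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            records.append(SvRecord(
                record_id=rec.id or "",
                chrom=rec.contig,
                pos=rec.pos,
                end=rec.stop,
                svtype=rec.info["SVTYPE"],
                strand=rec.info.get("STRANDS", "."),
                genotypes={
                    s: _gt_class(rec.samples[s].get("GT")) for s in rec.samples
                },
                source=rec.info.get("SOURCE", "gsv_callset"),
                assess=rec.info.get("ASSESS"),
                filter_field=filters[0] if filters else "PASS",
                split_reads=rec.info.get("SR"),
            ))
    return records


# ------------------------------------------------------------- CNV tables

_CNV_COLUMNS = ["sample_id", "caller", "batch", "chrom", "start", "end",
                "copy_number", "n_probes", "confidence"]


def write_cnv_calls_tsv(calls: Sequence[CnvCall], path) -> None:
    df = pd.DataFrame([
        {
            "sample_id": c.sample_id, "caller": c.caller.value, "batch": c.batch,
            "chrom": c.chrom, "start": c.start, "end": c.end,
            "copy_number": c.copy_number, "n_probes": c.n_probes,
            "confidence": "" if c.confidence is None else c.confidence,
        }
        for c in calls
    ], columns=_CNV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cnv_calls_tsv(path) -> List[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str,
                                            "batch": str})
    calls = []
    for row in df.itertuples(index=False):
        conf = row.confidence
        calls.append(CnvCall(
            sample_id=row.sample_id,
            caller=Caller(row.caller),
            batch=row.batch,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            copy_number=int(row.copy_number),
            n_probes=int(row.n_probes),
            confidence=None if pd.isna(conf) else float(conf),
        ))
    return calls
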