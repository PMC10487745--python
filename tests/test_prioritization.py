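import pytest

from famsv.annotations import (
    AnnotationDb,
    EqtlRecord,
    EqtlTable,
    GeneAnnotation,
    PopAfTable,
)
from famsv.cnv import CnvLocus, VariantClass
from famsv.core import GenotypeClass
from famsv.pedigree import Cohort, Individual, Phenotype, Sex
from famsv.prioritization import (
    af_focused_filter,
    eqtl_focused_filter,
    filter_benign,
    lookup_population_af,
    partition_by_location,
    prioritize_cnvs,
)
from famsv.segregation import InheritancePattern, SegregatedVariant
from famsv.svmei import SvRecord

REF = GenotypeClass.REF
HET = GenotypeClass.HET
ASD = Phenotype.ASD
DN = InheritancePattern.DE_NOVO


def _gene(name="GENE1", chrom="chr1", start=10_000, brain=True, ndd=False,
          biotype="protein_coding"):
    # four 1 kb exons separated by 4 kb introns
    exons = [(start + i * 5_000, start + i * 5_000 + 999) for i in range(4)]
    return GeneAnnotation(
        gene=name, chrom=chrom, start=start, end=exons[-1][1],
        biotype=biotype, exons=exons,
        brain_tpm={"GTEx": 20.0 if brain else 1.0, "BrainSpan": 0.5,
                   "HDBR": 0.5},
        is_ndd=ndd,
    )


def _sv(pos, end=None, svtype="DEL", rid="V1", genotypes=None,
        source="gsv_callset", chrom="chr1"):
    return SvRecord(record_id=rid, chrom=chrom, pos=pos,
                    end=pos if end is None else end, svtype=svtype,
                    strand="+", genotypes=genotypes or {"c": HET},
                    source=source)


def _seg(variant, families=("F1",), patterns=(DN,)):
    return SegregatedVariant(
        variant=variant, phenotype=ASD,
        assignments={f: frozenset(patterns) for f in families},
    )


def _trio_cohort():
    fam = [
        Individual("f", "F1", None, None, Sex.MALE, False, False, False),
        Individual("m", "F1", None, None, Sex.FEMALE, False, False, False),
        Individual("c", "F1", "f", "m", Sex.MALE, True, False, False),
    ]
    return Cohort(families={"F1": fam})


class TestPartitionByLocation:
    db = AnnotationDb([_gene()])

    def test_no_gene_overlap_is_intergenic(self):
        assert partition_by_location(_sv(500_000, 500_300), self.db) == "intergenic"

    def test_within_single_intron_is_intronic(self):
        # intron 1 spans 11000..14999
        assert partition_by_location(_sv(12_000, 12_300), self.db) == "intronic"

    def test_touching_exon_is_exonic(self):
        assert partition_by_location(_sv(15_500, 15_600), self.db) == "exonic"

    def test_spanning_multiple_introns_is_exonic(self):
        # starts in intron 1, ends in intron 2: crosses exon 2
        assert partition_by_location(_sv(12_000, 17_000), self.db) == "exonic"

    def test_every_variant_gets_exactly_one_label(self):
        for pos, end in [(10_500, 10_600), (12_000, 12_300), (400_000, 400_100),
                         (9_000, 30_000)]:
            assert partition_by_location(_sv(pos, end), self.db) in (
                "exonic", "intronic", "intergenic")


class TestFilterBenign:
    def test_duplication_matching_benign_gain_dropped(self):
        locus = CnvLocus("L1", "chr1", 100_000, 159_999,
                         VariantClass.DUPLICATION, genotypes={"c": 3})
        benign = {"gain": [("chr1", 100_000, 159_999)], "loss": []}
        assert filter_benign([locus], benign) == []

    def test_class_mismatch_keeps_variant(self):
        locus = CnvLocus("L1", "chr1", 100_000, 159_999,
                         VariantClass.DELETION, genotypes={"c": 1})
        benign = {"gain": [("chr1", 100_000, 159_999)], "loss": []}
        assert filter_benign([locus], benign) == [locus]

    def test_empty_benign_set_is_identity(self):
        locus = CnvLocus("L1", "chr1", 100_000, 159_999,
                         VariantClass.DELETION, genotypes={"c": 1})
        assert filter_benign([locus], {}) == [locus]

    def test_sv_breakpoint_distance_rule(self):
        sv = _sv(1_000, 2_000)
        near = {"loss": [("chr1", 1_050, 2_080)]}
        far = {"loss": [("chr1", 1_200, 2_080)]}
        assert filter_benign([sv], near) == []
        assert filter_benign([sv], far) == [sv]


class TestPopulationAf:
    mei_ref = PopAfTable([("chr1", 1_040, "MEI_ALU", 0.03)])
    sv_ref = PopAfTable([("chr1", 950, "INS", 0.10),
                         ("chr1", 1_050, "INS", 0.20),
                         ("chr1", 5_000, "DEL", 0.40)])

    def test_mei_reference_queried_first(self):
        mei = _sv(1_000, svtype="MEI_ALU", source="mei_insertion")
        assert lookup_population_af(mei, self.mei_ref, self.sv_ref) == 0.03

    def test_mei_falls_back_to_sv_reference(self):
        mei = _sv(950, svtype="MEI_SVA", source="mei_insertion")
        empty = PopAfTable([])
        assert lookup_population_af(mei, empty, self.sv_ref) == 0.10

    def test_distance_tie_resolves_to_smaller_position(self):
        ins = _sv(1_000, svtype="INS")
        assert lookup_population_af(ins, None, self.sv_ref) == 0.10

    def test_no_match_within_window_is_absent(self):
        ins = _sv(10_000, svtype="INS")
        assert lookup_population_af(ins, self.mei_ref, self.sv_ref) is None


class TestAfFocusedFilter:
    def _genotypes(self, n_het, n=20):
        g = {f"s{i}": REF for i in range(n)}
        for i in range(n_het):
            g[f"s{i}"] = HET
        g["c"] = g.pop("s0") if n_het else REF  # keep a carrier child name
        return g

    def _db(self, brain=True, ndd=False):
        return AnnotationDb([_gene(brain=brain, ndd=ndd)])

    def test_exonic_rare_variant_in_brain_gene_retained(self):
        sv = _sv(10_500, 10_600, genotypes=self._genotypes(2))
        out = af_focused_filter([_seg(sv)], self._db(), _trio_cohort())
        assert len(out) == 1
        assert out[0].pipeline == "af_exonic"
        assert out[0].sample_af == pytest.approx(0.05)

    def test_sample_af_boundary_inclusive_at_five_percent(self):
        kept = _sv(10_500, 10_600, genotypes=self._genotypes(2))   # AF 5%
        dropped = _sv(10_500, 10_600, genotypes=self._genotypes(3))  # 7.5%
        out = af_focused_filter([_seg(kept), _seg(dropped)], self._db(),
                                _trio_cohort())
        assert [c.sample_af for c in out] == [pytest.approx(0.05)]

    def test_population_af_above_five_percent_excluded(self):
        sv = _sv(10_500, 10_600, genotypes=self._genotypes(1))
        ref = PopAfTable([("chr1", 10_520, "DEL", 0.06)])
        assert af_focused_filter([_seg(sv)], self._db(), _trio_cohort(),
                                 sv_ref=ref) == []

    def test_absent_population_af_treated_as_rare(self):
        sv = _sv(10_500, 10_600, genotypes=self._genotypes(1))
        assert len(af_focused_filter([_seg(sv)], self._db(), _trio_cohort(),
                                     sv_ref=PopAfTable([]))) == 1

    def test_non_brain_gene_excluded(self):
        sv = _sv(10_500, 10_600, genotypes=self._genotypes(1))
        assert af_focused_filter([_seg(sv)], self._db(brain=False),
                                 _trio_cohort()) == []

    def test_intronic_requires_ndd_gene(self):
        sv = _sv(12_000, 12_300, genotypes=self._genotypes(1))
        assert af_focused_filter([_seg(sv)], self._db(ndd=False),
                                 _trio_cohort()) == []
        out = af_focused_filter([_seg(sv)], self._db(ndd=True), _trio_cohort())
        assert [c.pipeline for c in out] == ["af_intronic"]

    def test_false_de_novo_drops_multi_individual_de_novo(self):
        cohort = _trio_cohort()
        fam2 = [
            Individual("f2", "F2", None, None, Sex.MALE, False, False, False),
            Individual("m2", "F2", None, None, Sex.FEMALE, False, False, False),
            Individual("c2", "F2", "f2", "m2", Sex.MALE, True, False, False),
        ]
        cohort.families["F2"] = fam2
        genotypes = self._genotypes(1, n=40)
        genotypes["c2"] = HET  # second de novo child, AF still < 5%
        sv = _sv(12_000, 12_300, genotypes=genotypes)
        seg = _seg(sv, families=("F1", "F2"))
        assert af_focused_filter([seg], self._db(ndd=True), cohort) == []


class TestEqtlFocusedFilter:
    target = _gene("TARGET", chrom="chr9", start=1_000)
    host = _gene("HOST", brain=False)
    db = AnnotationDb([host, target])

    def _table(self, **kw):
        defaults = dict(chrom="chr1", pos=12_010, svtype="DEL",
                        tissue="Brain_Cortex", lead_variant_type="SV",
                        caviar_prob=0.4, caviar_rank=2,
                        tissue_count_me_is_causal=0, origin="SV",
                        eqtl_gene="TARGET")
        defaults.update(kw)
        return EqtlTable([EqtlRecord(**defaults)])

    def test_intronic_sv_with_brain_eqtl_retained(self):
        sv = _sv(12_000, 12_300)
        out = eqtl_focused_filter([_seg(sv)], self._table(), self.db)
        assert len(out) == 1
        assert out[0].pipeline == "eqtl_intronic"
        assert out[0].genes == ["TARGET"]  # the eQTL gene, not the host

    def test_low_caviar_probability_dropped(self):
        sv = _sv(12_000, 12_300)
        assert eqtl_focused_filter([_seg(sv)], self._table(caviar_prob=0.05),
                                   self.db) == []

    def test_non_brain_tissue_dropped(self):
        sv = _sv(12_000, 12_300)
        assert eqtl_focused_filter([_seg(sv)],
                                   self._table(tissue="Liver"), self.db) == []

    def test_mei_requires_positive_tissue_count(self):
        mei = _sv(500_000, svtype="MEI_ALU", source="mei_insertion")
        table0 = self._table(pos=500_010, svtype="MEI_ALU", origin="MEI",
                             tissue_count_me_is_causal=0)
        table14 = self._table(pos=500_010, svtype="MEI_ALU", origin="MEI",
                              tissue_count_me_is_causal=14)
        assert eqtl_focused_filter([_seg(mei)], table0, self.db) == []
        out = eqtl_focused_filter([_seg(mei)], table14, self.db)
        assert len(out) == 1
        assert out[0].pipeline == "eqtl_intergenic"
        assert out[0].tissue_count == 14

    def test_unexpressed_eqtl_gene_dropped(self):
        sv = _sv(12_000, 12_300)
        assert eqtl_focused_filter([_seg(sv)], self._table(eqtl_gene="HOST"),
                                   self.db) == []


class TestPrioritizeCnvs:
    def _locus(self, genotypes, cn=3):
        return CnvLocus("L1", "chr1", 9_000, 30_000,
                        VariantClass.DUPLICATION, genotypes=genotypes)

    def test_planted_de_novo_candidate_survives(self):
        cohort = _trio_cohort()
        locus = self._locus({"c": 3})
        seg = SegregatedVariant(variant=locus, phenotype=ASD,
                                assignments={"F1": frozenset({DN})})
        out = prioritize_cnvs([seg], cohort, ASD, AnnotationDb([_gene()]))
        assert len(out) == 1
        assert out[0].pipeline == "cnv"
        assert out[0].genes == ["GENE1"]

    def test_de_novo_with_three_carriers_dropped(self):
        cohort = _trio_cohort()
        locus = self._locus({"c": 3, "x1": 3, "x2": 3})
        seg = SegregatedVariant(variant=locus, phenotype=ASD,
                                assignments={"F1": frozenset({DN})})
        assert prioritize_cnvs([seg], cohort, ASD,
                               AnnotationDb([_gene()])) == []

    def test_non_coding_gene_only_dropped(self):
        cohort = _trio_cohort()
        locus = self._locus({"c": 3})
        seg = SegregatedVariant(variant=locus, phenotype=ASD,
                                assignments={"F1": frozenset({DN})})
        db = AnnotationDb([_gene(biotype="lincRNA")])
        assert prioritize_cnvs([seg], cohort, ASD, db) == []

    def test_no_brain_expressed_gene_dropped(self):
        cohort = _trio_cohort()
        locus = self._locus({"c": 3})
        seg = SegregatedVariant(variant=locus, phenotype=ASD,
                                assignments={"F1": frozenset({DN})})
        assert prioritize_cnvs([seg], cohort, ASD,
                               AnnotationDb([_gene(brain=False)])) == []

    def test_unaffected_only_carrier_dropped(self):
        cohort = _trio_cohort()
        locus = self._locus({"f": 3})
        seg = SegregatedVariant(variant=locus, phenotype=ASD,
                                assignments={"F1": frozenset({DN})})
        assert prioritize_cnvs([seg], cohort, ASD,
                               AnnotationDb([_gene()])) == []
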