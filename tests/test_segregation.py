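import pytest

from famsv.cnv import CnvLocus, VariantClass
from famsv.core import GenotypeClass
from famsv.pedigree import Cohort, Individual, Phenotype, Sex
from famsv.segregation import (
    InheritancePattern,
    classify_genotype,
    classify_inheritance,
    filter_by_segregation,
)
from famsv.svmei import SvRecord

REF = GenotypeClass.REF
HET = GenotypeClass.HET
HOM = GenotypeClass.HOM_ALT
MISS = GenotypeClass.MISSING

DN = InheritancePattern.DE_NOVO
AR = InheritancePattern.AUTOSOMAL_RECESSIVE
AD = InheritancePattern.AUTOSOMAL_DOMINANT
XLR = InheritancePattern.X_LINKED_RECESSIVE
XLD = InheritancePattern.X_LINKED_DOMINANT
XLDN = InheritancePattern.X_LINKED_DE_NOVO

ASD = Phenotype.ASD


def _ind(iid, fam="F1", father=None, mother=None, sex=Sex.MALE, asd=False):
    return Individual(iid, fam, father, mother, sex, asd, False, False)


def _trio(child_asd=True, father_asd=False, mother_asd=False):
    return [
        _ind("f", asd=father_asd),
        _ind("m", sex=Sex.FEMALE, asd=mother_asd),
        _ind("c", father="f", mother="m", asd=child_asd),
    ]


def _sv(genotypes, chrom="chr1", rid="V1"):
    return SvRecord(record_id=rid, chrom=chrom, pos=1000, end=1400,
                    svtype="DEL", strand="+", genotypes=genotypes,
                    source="gsv_callset")


def _cnv(genotypes, chrom="chr1"):
    return CnvLocus(locus_id="L1", chrom=chrom, start=100_000, end=160_000,
                    variant_class=VariantClass.DUPLICATION,
                    genotypes=genotypes)


class TestClassifyGenotype:
    @pytest.mark.parametrize("cn,expected", [
        (0, HOM), (1, HET), (2, REF), (3, HET), (4, HOM),
    ])
    def test_copy_number_mapping(self, cn, expected):
        locus = _cnv({"s": cn}) if cn != 2 else _cnv({})
        assert classify_genotype(locus, "s") == expected

    def test_absent_cnv_call_is_reference(self):
        assert classify_genotype(_cnv({}), "anyone") == REF

    def test_copy_number_above_four_is_error(self):
        with pytest.raises(ValueError):
            classify_genotype(_cnv({"s": 5}), "s")

    def test_sv_missing_genotype(self):
        assert classify_genotype(_sv({"s": MISS}), "s") == MISS
        assert classify_genotype(_sv({}), "other") == MISS


class TestStrictModels:
    def test_de_novo_trio(self):
        fam = _trio()
        variant = _cnv({"c": 3})
        res = classify_inheritance(variant, fam, ASD)
        assert res.patterns == {DN}

    def test_de_novo_requires_het_child(self):
        fam = _trio()
        assert classify_inheritance(_cnv({"c": 4}), fam, ASD).patterns == set()

    def test_de_novo_blocked_by_unaffected_carrier(self):
        fam = _trio() + [_ind("sib", father="f", mother="m")]
        variant = _sv({"f": REF, "m": REF, "c": HET, "sib": HET})
        assert classify_inheritance(variant, fam, ASD).patterns == set()

    def test_autosomal_recessive_trio(self):
        fam = _trio()
        variant = _sv({"f": HET, "m": HET, "c": HOM})
        assert classify_inheritance(variant, fam, ASD).patterns == {AR}

    def test_recessive_requires_unaffected_parents(self):
        fam = _trio(father_asd=True)
        variant = _sv({"f": HET, "m": HET, "c": HOM})
        assert AR not in classify_inheritance(variant, fam, ASD).patterns

    def test_autosomal_dominant_and_unaffected_carrier_violation(self):
        fam = [
            _ind("f", asd=True),
            _ind("m", sex=Sex.FEMALE),
            _ind("c", father="f", mother="m", asd=True),
        ]
        variant = _sv({"f": HET, "m": REF, "c": HET})
        assert classify_inheritance(variant, fam, ASD).patterns == {AD}
        fam.append(_ind("sib", father="f", mother="m"))
        variant2 = _sv({"f": HET, "m": REF, "c": HET, "sib": HET})
        assert classify_inheritance(variant2, fam, ASD).patterns == set()

    def test_de_novo_and_dominant_are_mutually_exclusive(self):
        # multi-trio family: whichever structure holds, never both at once
        fam = [
            _ind("gf"), _ind("gm", sex=Sex.FEMALE),
            _ind("f", father="gf", mother="gm", asd=True),
            _ind("m", sex=Sex.FEMALE),
            _ind("c", father="f", mother="m", asd=True),
        ]
        for genotypes in (
            {"gf": REF, "gm": REF, "f": HET, "m": REF, "c": HET},
            {"gf": HET, "gm": REF, "f": HET, "m": REF, "c": HET},
            {"gf": REF, "gm": REF, "f": REF, "m": REF, "c": HET},
        ):
            res = classify_inheritance(_sv(genotypes), fam, ASD)
            assert not ({DN, AD} <= res.patterns)

    def test_missing_genotype_fails_model_never_reassigns(self):
        fam = _trio()
        # a recessive configuration with the father's genotype missing is
        # dropped, not reinterpreted as another pattern
        variant = _sv({"f": MISS, "m": HET, "c": HOM})
        assert classify_inheritance(variant, fam, ASD).patterns == set()

    def test_missing_phenotype_individual_is_ignored(self):
        fam = _trio() + [_ind("sib", father="f", mother="m", asd=None)]
        variant = _sv({"f": REF, "m": REF, "c": HET, "sib": HET})
        # the sibling's phenotype is unknown: cannot violate de novo
        assert classify_inheritance(variant, fam, ASD).patterns == {DN}

    def test_cohort_scope_blocks_de_novo_for_cnvs(self):
        fam = _trio()
        other = [_ind("u", fam="F2")]
        cohort = Cohort(families={"F1": fam, "F2": other})
        variant = _cnv({"c": 3, "u": 3})
        res_family = classify_inheritance(variant, fam, ASD,
                                          denovo_carrier_scope="family")
        res_cohort = classify_inheritance(variant, fam, ASD, cohort=cohort,
                                          denovo_carrier_scope="cohort")
        assert res_family.patterns == {DN}
        assert res_cohort.patterns == set()


class TestXLinked:
    def _xfam(self, mother_asd=False):
        return [
            _ind("f"),
            _ind("m", sex=Sex.FEMALE, asd=mother_asd),
            _ind("c", father="f", mother="m", sex=Sex.MALE, asd=True),
        ]

    def test_x_linked_recessive_carrier_mother(self):
        variant = _sv({"f": REF, "m": HET, "c": HOM}, chrom="chrX")
        res = classify_inheritance(variant, self._xfam(), ASD)
        assert res.patterns == {XLR}

    def test_x_linked_de_novo_hemizygous_son(self):
        variant = _sv({"f": REF, "m": REF, "c": HOM}, chrom="chrX")
        assert classify_inheritance(variant, self._xfam(), ASD).patterns == {XLDN}

    def test_x_linked_dominant_affected_mother(self):
        variant = _sv({"f": REF, "m": HET, "c": HOM}, chrom="chrX")
        res = classify_inheritance(variant, self._xfam(mother_asd=True), ASD)
        assert res.patterns == {XLD}

    def test_male_het_on_x_coerced_to_hemizygous(self, caplog):
        variant = _sv({"f": REF, "m": REF, "c": HET}, chrom="chrX")
        with caplog.at_level("WARNING"):
            res = classify_inheritance(variant, self._xfam(), ASD)
        assert res.patterns == {XLDN}
        assert "hemizygous" in caplog.text

    def test_autosomal_patterns_not_evaluated_on_x(self):
        variant = _sv({"f": HET, "m": HET, "c": HOM}, chrom="chrX")
        res = classify_inheritance(variant, self._xfam(), ASD)
        assert not (res.patterns & {DN, AR, AD})


class TestFilterBySegregation:
    def test_carrier_in_affected_and_unaffected_dropped(self):
        fam = _trio() + [_ind("sib", father="f", mother="m")]
        cohort = Cohort(families={"F1": fam})
        variant = _sv({"f": REF, "m": REF, "c": HET, "sib": HET})
        assert filter_by_segregation([variant], cohort, ASD) == []

    def test_planted_recessive_retained_with_pattern(self):
        fam = _trio()
        cohort = Cohort(families={"F1": fam})
        variant = _sv({"f": HET, "m": HET, "c": HOM})
        kept = filter_by_segregation([variant], cohort, ASD)
        assert len(kept) == 1
        assert kept[0].assignments == {"F1": frozenset({AR})}

    def test_multi_family_de_novo_flagged_for_false_denovo_filter(self):
        fam1 = _trio()
        fam2 = [
            _ind("f2", fam="F2"),
            _ind("m2", fam="F2", sex=Sex.FEMALE),
            _ind("c2", fam="F2", father="f2", mother="m2", asd=True),
        ]
        cohort = Cohort(families={"F1": fam1, "F2": fam2})
        variant = _sv({"f": REF, "m": REF, "c": HET,
                       "f2": REF, "m2": REF, "c2": HET})
        kept = filter_by_segregation([variant], cohort, ASD)
        assert len(kept) == 1
        children = kept[0].de_novo_children(cohort, ASD)
        assert sorted(children) == ["c", "c2"]

    def test_results_stable_under_family_order(self):
        fam1 = _trio()
        fam2 = [
            _ind("f2", fam="F2"), _ind("m2", fam="F2", sex=Sex.FEMALE),
            _ind("c2", fam="F2", father="f2", mother="m2", asd=True),
        ]
        variant = _sv({"f": HET, "m": HET, "c": HOM,
                       "f2": REF, "m2": REF, "c2": REF})
        a = filter_by_segregation([variant],
                                  Cohort(families={"F1": fam1, "F2": fam2}),
                                  ASD)
        b = filter_by_segregation([variant],
                                  Cohort(families={"F2": fam2, "F1": fam1}),
                                  ASD)
        assert a[0].assignments == b[0].assignments
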