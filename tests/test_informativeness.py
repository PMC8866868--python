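"""Trio classification: category rules, paternal attribution, exhaustive oracle."""

import itertools

import pytest

from snpsnp.informativeness import (
    Category,
    MendelianError,
    TrioRecord,
    classify_locus,
    classify_trio,
    expected_informative_count,
    paternal_allele,
)
from snpsnp.panel import HaplotypeGenotype, Panel

from conftest import G


class TestPaternalAttribution:
    def test_unambiguous_attribution(self):
        att = paternal_allele(G("CA-CA"), G("CA-TG"))
        assert att.haplotype == "TG"
        assert not att.ambiguous

    def test_both_child_haplotypes_maternal_compatible_is_flagged(self):
        att = paternal_allele(G("CA-TG"), G("CA-TG"))
        assert att.ambiguous
        assert set(att.candidates) == {"CA", "TG"}

    def test_impossible_inheritance_raises(self):
        with pytest.raises(MendelianError):
            paternal_allele(G("CA-CA"), G("TG-TG"))


class TestCategories:
    def test_opposite_homozygotes_are_type1(self, panel):
        call = classify_locus(G("CA-CA"), G("TG-TG"), G("CA-TG"), panel["MH9"])
        assert call.category is Category.TYPE1
        assert call.informative_allele == "T"
        assert call.primer_id == "MH9-F2"

    def test_unshared_transmitted_allele_is_type2(self, panel):
        call = classify_locus(G("CA-CA"), G("CA-TG"), G("CA-TG"), panel["MH9"])
        assert call.category is Category.TYPE2
        assert call.informative_allele == "T"
        assert call.primer_id == "MH9-F2"

    def test_shared_transmitted_allele_is_type3(self, panel):
        call = classify_locus(G("CA-CA"), G("CA-TG"), G("CA-CA"), panel["MH9"])
        assert call.category is Category.TYPE3
        assert call.informative_allele is None
        assert call.primer_id is None

    def test_heterozygous_mother_is_never_usable(self, panel):
        call = classify_locus(G("CA-TG"), G("TG-TG"), G("CA-TG"), panel["MH9"])
        assert call.category is Category.MATERNAL_HET
        assert not call.informative

    def test_identical_homozygous_parents_are_uninformative(self, panel):
        g = G("CA-CA")
        call = classify_locus(g, g, g, panel["MH9"])
        assert call.category is Category.UNINFORMATIVE

    def test_mendelian_violation_raises_with_locus(self, panel):
        with pytest.raises(MendelianError, match="MH9"):
            classify_locus(G("CA-CA"), G("CA-CA"), G("TG-TG"), panel["MH9"])

    def test_genotype_outside_declared_alleles_rejected(self, panel):
        with pytest.raises(ValueError, match="declared alleles"):
            classify_locus(G("GG-GG"), G("GG-GG"), G("GG-GG"), panel["MH9"])


def _genotypes(haps):
    """All unordered haplotype-pair genotypes over a haplotype set."""
    return [
        HaplotypeGenotype(a, b)
        for a, b in itertools.combinations_with_replacement(sorted(haps), 2)
    ]


class TestExhaustiveOracle:
    """Enumerate every biallelic parental pair and Mendelian child.

    The oracle applies the definition directly: a trio is informative iff
    the mother is SNP1-homozygous and the transmitted paternal SNP1 allele
    is not hers.  The classifier must agree in every single case, and the
    category must match the genotype pattern.
    """

    HAPS = ["CA", "CG", "TA", "TG"]  # SNP1 C/T, SNP2 A/G

    def test_classifier_matches_definition_everywhere(self, panel):
        locus = panel["MH9"]
        n_cases = 0
        for mother in _genotypes(self.HAPS):
            for father in _genotypes(self.HAPS):
                for m_hap in mother.haplotypes:
                    for p_hap in father.haplotypes:
                        child = HaplotypeGenotype(m_hap, p_hap)
                        call = classify_locus(mother, father, child, locus)
                        maternal_snp1 = mother.snp1_alleles()
                        informative_by_definition = (
                            maternal_snp1[0] == maternal_snp1[1]
                            and p_hap[0] != maternal_snp1[0]
                        )
                        assert call.informative == informative_by_definition, (
                            mother, father, child,
                        )
                        if informative_by_definition:
                            assert call.informative_allele == p_hap[0]
                            assert call.informative_allele not in maternal_snp1
                        n_cases += 1
        assert n_cases == 10 * 10 * 4

    def test_type1_verdict_does_not_depend_on_the_child(self, panel):
        locus = panel["MH9"]
        mother, father = G("CA-CG"), G("TA-TG")
        mother_hom = HaplotypeGenotype("CA", "CG")
        for m_hap in mother_hom.haplotypes:
            for p_hap in father.haplotypes:
                call = classify_locus(
                    mother_hom, father, HaplotypeGenotype(m_hap, p_hap), locus
                )
                assert call.category is Category.TYPE1
                assert call.informative_allele == "T"

    def test_haplotype_permutation_never_changes_the_call(self, panel):
        locus = panel["MH9"]
        mother, father, child = G("CA-CA"), G("CA-TG"), G("TG-CA")
        base = classify_locus(mother, father, child, locus)
        flipped = classify_locus(
            HaplotypeGenotype(mother.hap2, mother.hap1),
            HaplotypeGenotype(father.hap2, father.hap1),
            HaplotypeGenotype(child.hap2, child.hap1),
            locus,
        )
        assert base == flipped


def _uniform_trio(panel, mother, father, child):
    return TrioRecord(
        "fam",
        {loc.locus_id: mother for loc in panel},
        {loc.locus_id: father for loc in panel},
        {loc.locus_id: child for loc in panel},
    )


class TestTrioClassification:
    def test_one_call_per_locus_in_panel_order(self, panel):
        genotypes = {
            loc.locus_id: HaplotypeGenotype(loc.haplotypes[0], loc.haplotypes[0])
            for loc in panel
        }
        trio = TrioRecord("fam", dict(genotypes), dict(genotypes), dict(genotypes))
        calls = classify_trio(trio, panel)
        assert [c.locus_id for c in calls] == list(panel.locus_ids)
        assert all(c.category is Category.UNINFORMATIVE for c in calls)

    def test_self_trio_has_no_informative_marker(self, panel):
        sub = Panel((panel["MH9"], panel["MH11"]))
        for g in (G("CA-CA"), G("CA-TG")):
            trio = _uniform_trio(sub, g, g, g)
            assert expected_informative_count(classify_trio(trio, sub)) == 0

    def test_constructed_six_informative_loci_count_six(self, panel):
        # six C/T loci set up as TYPE2, the rest of the sub-panel TYPE3
        ct_loci = [loc for loc in panel if set(loc.snp1_alleles) == {"C", "T"}]
        assert len(ct_loci) >= 6
        sub = Panel(tuple(ct_loci))
        mother, father = {}, {}
        child = {}
        for i, loc in enumerate(sub):
            a2 = loc.snp2_alleles[0]
            hom = HaplotypeGenotype("C" + a2, "C" + a2)
            het = HaplotypeGenotype("C" + a2, "T" + a2)
            mother[loc.locus_id] = hom
            father[loc.locus_id] = het
            child[loc.locus_id] = het if i < 6 else hom
        trio = TrioRecord("fam", mother, father, child)
        calls = classify_trio(trio, sub)
        assert expected_informative_count(calls) == 6
        assert 0 <= expected_informative_count(calls) <= len(sub)

    def test_missing_locus_genotype_names_the_locus(self, panel):
        trio = _uniform_trio(panel, G("CA-CA"), G("CA-CA"), G("CA-CA"))
        del trio.mother["MH9"]
        with pytest.raises(KeyError, match="MH9"):
            classify_trio(trio, Panel((panel["MH9"],)))

    def test_trio_mendelian_validation(self, panel):
        trio = _uniform_trio(Panel((panel["MH9"],)), G("CA-CA"), G("CA-CA"), G("CA-CA"))
        trio.child["MH9"] = G("TG-TG")
        with pytest.raises(MendelianError):
            trio.validate_mendelian()
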