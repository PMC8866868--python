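"""ARMS/SBE peak model: mass accounting, calibration, specificity, mixtures."""

import numpy as np
import pytest

from snpsnp.amplification import (
    AmplificationParams,
    MixtureSpec,
    deepest_detected_ratio,
    expected_height,
    mixture_series,
    nontarget_mass,
    sensitivity_assay,
    simulate_peak,
    target_mass,
)

from conftest import FIG4_MAJOR, FIG4_MINOR, G

DET = AmplificationParams(noise_cv=0.0)
DET_SPECIFIC = AmplificationParams(noise_cv=0.0, nonspecific_rate=0.0)


class TestTargetMass:
    def test_minor_specific_allele_in_unbalanced_mixture(self, panel):
        # heterozygous minor at 0.05 ng against a 50 ng major lacking T:
        # only the minor's T haplotype feeds the T-specific primer
        mix = MixtureSpec.two_person(
            {"MH9": G("CA-TG")}, {"MH9": G("CA-CA")}, ratio=1000
        )
        primer = panel.primer("MH9-F2")
        assert target_mass(panel["MH9"], primer, mix) == pytest.approx(0.025)
        assert nontarget_mass(panel["MH9"], primer, mix) == pytest.approx(50.025)

    def test_absent_allele_has_zero_target_mass(self, panel):
        mix = MixtureSpec.two_person(
            {"MH9": G("CA-CA")}, {"MH9": G("CA-CA")}, ratio=10
        )
        assert target_mass(panel["MH9"], panel.primer("MH9-F2"), mix) == 0.0

    def test_heterozygote_contributes_half_its_mass(self, panel):
        mix = MixtureSpec.single_source({"MH9": G("CA-TG")}, 1.0)
        assert target_mass(panel["MH9"], panel.primer("MH9-F1"), mix) == 0.5

    def test_missing_genotype_raises(self, panel):
        mix = MixtureSpec.single_source({"MH1": G("CA-CA")}, 1.0)
        with pytest.raises(KeyError, match="MH9"):
            target_mass(panel["MH9"], panel.primer("MH9-F1"), mix)


class TestPeakModel:
    def test_no_template_no_peak(self, panel):
        mix = MixtureSpec.single_source({"MH9": G("CA-CA")}, 1.0)
        row = simulate_peak(panel["MH9"], panel.primer("MH9-F2"), mix, DET_SPECIFIC)
        assert row["height_rfu"] == 0.0
        assert not row["detected"]

    @pytest.mark.parametrize("primer_id", ["MH9-F1", "MH9-F2", "MH13-F1"])
    def test_calibration_anchor_heterozygous_lod_input_sits_on_threshold(
        self, panel, primer_id
    ):
        # a SNP1-heterozygous input of lod_ng lands exactly on 50 RFU
        primer = panel.primer(primer_id)
        locus = panel.locus_of_primer(primer_id)
        other = next(a for a in locus.snp1_alleles if a != primer.target_snp1_allele)
        genotype = G(
            f"{primer.target_snp1_allele}{locus.snp2_alleles[0]}"
            f"-{other}{locus.snp2_alleles[0]}"
        )
        mix = MixtureSpec.single_source({locus.locus_id: genotype}, primer.lod_ng)
        row = simulate_peak(locus, primer, mix, DET_SPECIFIC)
        assert row["height_rfu"] == pytest.approx(DET.threshold_rfu)
        assert row["detected"]

    def test_height_monotone_in_target_mass(self, panel):
        locus, primer = panel["MH9"], panel.primer("MH9-F1")
        heights = [
            expected_height(
                locus, primer, MixtureSpec.single_source({"MH9": G("CA-TG")}, m), DET
            )
            for m in (0.01, 0.05, 0.1, 1.0, 10.0)
        ]
        assert heights == sorted(heights)
        assert heights[0] < heights[-1]

    def test_height_constant_in_ratio_when_major_lacks_target(self, panel):
        # with zero nonspecific amplification the major adds nothing
        locus, primer = panel["MH9"], panel.primer("MH9-F2")
        heights = [
            expected_height(
                locus,
                primer,
                MixtureSpec.two_person({"MH9": G("CA-TG")}, {"MH9": G("CA-CA")}, r),
                DET_SPECIFIC,
            )
            for r in (1, 10, 100, 1000)
        ]
        assert heights == pytest.approx([heights[0]] * 4)

    def test_noise_is_mean_preserving_and_seeded(self, panel):
        locus, primer = panel["MH9"], panel.primer("MH9-F1")
        mix = MixtureSpec.single_source({"MH9": G("CA-TG")}, 1.0)
        params = AmplificationParams(noise_cv=0.3, nonspecific_rate=0.0)
        rng = np.random.default_rng(5)
        heights = np.array(
            [simulate_peak(locus, primer, mix, params, rng)["height_rfu"] for _ in range(4000)]
        )
        det = expected_height(locus, primer, mix, params)
        assert heights.mean() == pytest.approx(det, rel=0.02)
        rerun = simulate_peak(
            locus, primer, mix, params, np.random.default_rng(5)
        )["height_rfu"]
        assert rerun == heights[0]


class TestSensitivity:
    def test_deterministic_lod_equals_printed_sensitivity(self, panel):
        # the dilution series detects a heterozygous template down to the
        # primer's LOD input mass and no further
        for primer_id, lod in (("MH9-F1", 0.025), ("MH9-F2", 0.05)):
            locus = panel.locus_of_primer(primer_id)
            primer = panel.primer(primer_id)
            table = sensitivity_assay(
                locus, primer, [1, 0.5, 0.1, 0.05, 0.025, 0.0125], DET_SPECIFIC
            )
            detected = table[table["detection_rate"] == 1.0]["mass_ng"]
            assert detected.min() == pytest.approx(lod)

    def test_zero_mass_never_detected(self, panel):
        table = sensitivity_assay(
            panel["MH9"], panel.primer("MH9-F1"), [0.0], DET_SPECIFIC
        )
        assert table["detection_rate"].iloc[0] == 0.0

    def test_stochastic_rates_reproducible_and_monotone(self, panel):
        locus, primer = panel["MH9"], panel.primer("MH9-F1")
        params = AmplificationParams(noise_cv=0.3, nonspecific_rate=0.0)
        masses = [0.01, 0.025, 0.1, 1.0]
        t1 = sensitivity_assay(
            locus, primer, masses, params, np.random.default_rng(11), replicates=1000
        )
        t2 = sensitivity_assay(
            locus, primer, masses, params, np.random.default_rng(11), replicates=1000
        )
        assert t1["detection_rate"].tolist() == t2["detection_rate"].tolist()
        rates = t1["detection_rate"].to_numpy()
        assert (np.diff(rates) >= -0.05).all()  # monotone within MC error
        assert rates[-1] == 1.0


RATIOS = [1, 10, 20, 50, 100, 500, 1000]


class TestMixtureSeries:
    def test_seven_informative_loci_detected_to_extreme_dilution(self, panel):
        # seven-locus two-person mixture, minor fixed at 0.05 ng:
        # deterministic heights keep at least six loci above threshold at 1:1,000
        table = mixture_series(FIG4_MINOR, FIG4_MAJOR, RATIOS, panel, DET)
        assert table["locus_id"].nunique() == 7
        last = table[table["ratio"] == 1000]
        assert last["detected"].sum() >= 6
        deepest = deepest_detected_ratio(table)
        assert (deepest >= 1000).sum() >= 6

    def test_single_ratio_gives_one_row_per_informative_allele(self, panel):
        table = mixture_series(FIG4_MINOR, FIG4_MAJOR, [1], panel, DET)
        assert len(table) == 7
        assert set(table["ratio"]) == {1}

    def test_identical_contributors_yield_empty_table_with_warning(self, panel):
        table = mixture_series(FIG4_MINOR, FIG4_MINOR, RATIOS, panel, DET)
        assert table.empty
        assert "no informative locus" in table.attrs["warning"]

    def test_specificity_absent_allele_never_peaks(self, panel):
        # nonspecific_rate 0: a primer with no target template stays silent
        # regardless of major mass or noise
        params = AmplificationParams(noise_cv=0.3, nonspecific_rate=0.0)
        locus, primer = panel["MH9"], panel.primer("MH9-F2")
        mix = MixtureSpec.two_person(
            {"MH9": G("CA-CA")}, {"MH9": G("CA-CA")}, ratio=1000, minor_mass_ng=5.0
        )
        rng = np.random.default_rng(3)
        rows = [simulate_peak(locus, primer, mix, params, rng) for _ in range(2000)]
        assert not any(r["detected"] for r in rows)
        assert all(r["height_rfu"] == 0.0 for r in rows)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        AmplificationParams(threshold_rfu=-1)
    with pytest.raises(ValueError):
        AmplificationParams(nonspecific_rate=1.5)
    with pytest.raises(ValueError):
        MixtureSpec.two_person({}, {}, ratio=0.5)
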