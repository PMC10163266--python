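"""Risk arithmetic, classification bands and the per-site assessment modes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dustrisk import refdata
from dustrisk.dataio import CompositionTable, PMSeries
from dustrisk.exposure import DailyIntake, average_daily_intake
from dustrisk.refdata import Thresholds, ToxicityRecord
from dustrisk.risk import (ReferenceDose, assess_sites, cancer_risk,
                           classify_cancer_risk, classify_hazard_index,
                           hazard_index, hazard_quotient, reference_dose,
                           total_cancer_risk)

ADULT = refdata.default_profiles()["adult"]
CHILD = refdata.default_profiles()["child"]


def make_composition(conc_by_sample):
    rows = [{"sample": s, "city": "", "element": el, "concentration": c, "below_lod": False}
            for s, conc in conc_by_sample.items() for el, c in conc.items()]
    return CompositionTable(pd.DataFrame(rows))


def make_pm(values):
    return PMSeries(pd.DataFrame({
        "date": pd.date_range("2021-04-01", periods=len(values)),
        "pm25": [v / 2 for v in values], "pm10": values}))


class TestReferenceDose:
    def test_adult_hand_value(self):
        rfd = reference_dose(ToxicityRecord("Mn", rfc=0.1), ADULT)
        assert rfd.rfd == pytest.approx(0.1 * 15 / 80, rel=1e-12)  # 0.01875

    def test_child_hand_value(self):
        rfd = reference_dose(ToxicityRecord("Mn", rfc=0.1), CHILD)
        assert rfd.rfd == pytest.approx(0.1 * 12.5 / 15, rel=1e-12)  # 0.08333

    def test_fixed_mode_uses_reference_profile_for_child(self):
        rfd = reference_dose(ToxicityRecord("Mn", rfc=0.1), CHILD,
                             rfd_mode="fixed", fixed_profile=ADULT)
        assert rfd.rfd == pytest.approx(0.1 * 15 / 80, rel=1e-12)
        assert rfd.receptor == "child"

    def test_missing_rfc_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="no RfC"):
            reference_dose(ToxicityRecord("As", iur=4.3e-3), ADULT)


class TestHazardQuotient:
    def test_hand_value(self):
        adi = average_daily_intake(100, 100, ADULT, "non-carcinogenic", element="Mn")
        rfd = reference_dose(ToxicityRecord("Mn", rfc=0.1), ADULT)
        assert hazard_quotient(adi, rfd) == pytest.approx(9.589e-5, rel=1e-3)

    def test_zero_intake(self):
        adi = DailyIntake("Mn", "adult", "non-carcinogenic", 0.0)
        assert hazard_quotient(adi, ReferenceDose("Mn", "adult", 0.01)) == 0.0

    def test_element_mismatch_rejected(self):
        adi = DailyIntake("Mn", "adult", "non-carcinogenic", 1e-6)
        with pytest.raises(ValueError, match="mismatch"):
            hazard_quotient(adi, ReferenceDose("Ni", "adult", 0.01))

    def test_zero_rfd_rejected(self):
        adi = DailyIntake("Mn", "adult", "non-carcinogenic", 1e-6)
        with pytest.raises(ValueError, match="excluded"):
            hazard_quotient(adi, ReferenceDose("Mn", "adult", 0.0))

    def test_carcinogenic_intake_rejected(self):
        adi = DailyIntake("Mn", "adult", "carcinogenic", 1e-6)
        with pytest.raises(ValueError):
            hazard_quotient(adi, ReferenceDose("Mn", "adult", 0.01))


class TestSums:
    def test_hazard_index(self):
        assert hazard_index([0.5, 0.69]) == pytest.approx(1.19)
        assert hazard_index([0.71]) == 0.71
        assert hazard_index([]) == 0.0

    def test_total_cancer_risk(self):
        assert total_cancer_risk([1e-5, 2e-5]) == pytest.approx(3e-5)
        assert total_cancer_risk([]) == 0.0

    @given(st.lists(st.floats(0, 10), max_size=20), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, hqs, rnd):
        shuffled = list(hqs)
        rnd.shuffle(shuffled)
        assert hazard_index(shuffled) == pytest.approx(hazard_index(hqs), rel=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            hazard_index([0.5, -0.1])
        with pytest.raises(ValueError):
            total_cancer_risk([-1e-9])


class TestCancerRisk:
    def test_hand_value(self):
        adi = average_daily_intake(100, 100, ADULT, "carcinogenic", element="X")
        cr = cancer_risk(adi, ToxicityRecord("X", iur=0.01), ADULT)
        assert cr == pytest.approx(6.678e-7 * 0.01 * 1000 * 80 / 15, rel=1e-3)
        assert cr == pytest.approx(3.562e-5, rel=1e-3)

    @given(st.floats(1e-2, 1e4), st.floats(1, 500), st.floats(1e-6, 1e-1))
    def test_receptor_mode_matches_simplified_closed_form(self, c_i, c_pm10, iur):
        """BW and InhR cancel between the intake and risk formulas."""
        adi = average_daily_intake(c_i, c_pm10, ADULT, "carcinogenic", element="X")
        composed = cancer_risk(adi, ToxicityRecord("X", iur=iur), ADULT)
        simplified = c_i * c_pm10 * ADULT.ef * ADULT.ed * iur / (ADULT.at_ca * 1e6)
        assert composed == pytest.approx(simplified, rel=1e-12)

    def test_zero_iur_gives_zero(self):
        adi = average_daily_intake(100, 100, ADULT, "carcinogenic", element="X")
        assert cancer_risk(adi, ToxicityRecord("X", rfc=1e-5, iur=0.0), ADULT) == 0.0

    def test_missing_iur_is_an_error(self):
        adi = average_daily_intake(100, 100, ADULT, "carcinogenic", element="Mn")
        with pytest.raises(ValueError, match="no IUR"):
            cancer_risk(adi, ToxicityRecord("Mn", rfc=5e-5), ADULT)


class TestClassification:
    @pytest.mark.parametrize("hi,band", [
        (0.71, "no_risk"),   # lowest published adult site
        (5.28, "risk"),      # highest published child sites
        (1.0, "no_risk"),    # boundary is strict
        (1.0000001, "risk"),
    ])
    def test_hazard_index_bands(self, hi, band):
        assert classify_hazard_index(hi) == band

    @pytest.mark.parametrize("cr,band", [
        (5e-7, "acceptable"),
        (1e-6, "acceptable"),     # "at or lower than" 1e-6
        (1.0001e-6, "tolerable"),
        (1e-4, "tolerable"),
        (1.33e-4, "unacceptable"),
    ])
    def test_cancer_risk_bands(self, cr, band):
        assert classify_cancer_risk(cr) == band

    def test_custom_thresholds(self):
        t = Thresholds(hi_limit=2.0, cr_acceptable=1e-5, cr_tolerable_upper=1e-3)
        assert classify_hazard_index(1.5, t) == "no_risk"
        assert classify_cancer_risk(5e-6, t) == "acceptable"


conc_strategy = st.dictionaries(
    st.sampled_from(["Cr", "As", "Ni", "Mn", "Co", "Zn", "Cd"]),
    st.floats(0.1, 5000), min_size=2, max_size=7)


class TestAssessSites:
    def test_report_invariants(self, composition, pm_series):
        report = assess_sites(composition, pm_series, mode="strict")
        for s in report.sites:
            assert s.hi == pytest.approx(math.fsum(s.hq_by_element.values()), rel=1e-15)
            assert s.cr_total == pytest.approx(math.fsum(s.cr_by_element.values()), rel=1e-15)
            assert all(v >= 0 for v in s.hq_by_element.values())
            assert all(v >= 0 for v in s.cr_by_element.values())
        assert report.c_pm10.value >= np.mean(pm_series.pm10)

    @given(conc_strategy)
    def test_strict_mode_hi_is_receptor_independent(self, conc):
        comp = make_composition({"S1": conc})
        report = assess_sites(comp, make_pm([40, 80, 120]), mode="strict")
        adult = report.site("S1", "adult")
        child = report.site("S1", "child")
        assert child.hi == pytest.approx(adult.hi, rel=1e-12)

    @given(conc_strategy)
    def test_replicate_mode_reproduces_published_ratios(self, conc):
        comp = make_composition({"S1": conc})
        report = assess_sites(comp, make_pm([40, 80, 120]), mode="replicate")
        adult = report.site("S1", "adult")
        child = report.site("S1", "child")
        # HI ratio = (InhR_c/BW_c)/(InhR_a/BW_a) = 4.444…
        assert child.hi / adult.hi == pytest.approx(40 / 9, rel=1e-12)
        # CR ratio = (InhR_c·ED_c·BW_a·AT_ca,a)/(BW_c·AT_nc,c·InhR_a·ED_a) = 11.966
        if adult.cr_total > 0:
            expected = (12.5 * 6 * 80 * 25550) / (15 * 2190 * 15 * 26)
            assert child.cr_total / adult.cr_total == pytest.approx(expected, rel=1e-12)

    def test_strict_cr_independent_of_bw_and_inhr(self):
        comp = make_composition({"S1": {"As": 30.0, "Cr": 70.0}})
        pm = make_pm([50, 70, 90])
        base = assess_sites(comp, pm, mode="strict")
        perturbed_profiles = {
            "adult": ADULT.replace(bw=55, inhr=22),
            "child": CHILD.replace(bw=20, inhr=8),
        }
        pert = assess_sites(comp, pm, profiles=perturbed_profiles, mode="strict")
        for receptor in ("adult", "child"):
            assert pert.site("S1", receptor).cr_total == pytest.approx(
                base.site("S1", receptor).cr_total, rel=1e-12)

    def test_risks_scale_linearly_with_pm(self):
        comp = make_composition({"S1": {"As": 30.0, "Ni": 200.0}})
        base = assess_sites(comp, make_pm([50, 70, 90]), mode="strict")
        scaled = assess_sites(comp, make_pm([100, 140, 180]), mode="strict")
        for receptor in ("adult", "child"):
            assert scaled.site("S1", receptor).hi == pytest.approx(
                2 * base.site("S1", receptor).hi, rel=1e-12)
            assert scaled.site("S1", receptor).cr_total == pytest.approx(
                2 * base.site("S1", receptor).cr_total, rel=1e-12)

    def test_chromium_enters_speciated(self, pm_series):
        comp = make_composition({"S1": {"Cr": 70.0}})
        report = assess_sites(comp, pm_series, mode="strict")
        site = report.site("S1", "adult")
        assert set(site.cr_by_element) == {"Cr(VI)"}  # Cr(III) has no IUR
        assert {"Cr(VI)", "Cr(III)"} <= set(site.hq_by_element)

    def test_no_toxicity_overlap_is_an_error(self, pm_series):
        comp = make_composition({"S1": {"Unobtainium": 10.0}})
        with pytest.raises(ValueError, match="overlap"):
            assess_sites(comp, pm_series)

    def test_omitted_elements_are_counted_warnings(self, composition, pm_series):
        report = assess_sites(composition, pm_series)
        assert any("without IUR" in w for w in report.warnings)
        assert any("without any toxicity record" in w for w in report.warnings)

    def test_unknown_mode_rejected(self, composition, pm_series):
        with pytest.raises(ValueError, match="mode"):
            assess_sites(composition, pm_series, mode="lenient")
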