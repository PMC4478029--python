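"""Unit and property tests for the echo derivation rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ephstudy import echo
from ephstudy.config import Thresholds


class TestEstimateRap:
    @pytest.mark.parametrize("diameter,collapse,expected", [
        (18.0, 0.70, 3.0),    # small, collapsing IVC -> low RAP
        (25.0, 0.30, 15.0),   # large, non-collapsing -> high RAP
        (25.0, 0.70, 8.0),    # discordant -> intermediate
        (18.0, 0.30, 8.0),
        (21.0, 0.50, 8.0),    # both boundaries fail the strict tests
        (21.0, 0.51, 3.0),
        (21.01, 0.49, 15.0),
    ])
    def test_decision_rule(self, diameter, collapse, expected):
        assert echo.estimate_rap(diameter, collapse) == expected

    @pytest.mark.parametrize("diameter,collapse", [
        (float("nan"), 0.5), (20.0, float("nan")), (None, 0.5)])
    def test_missing_input_gives_missing_rap(self, diameter, collapse):
        assert math.isnan(echo.estimate_rap(diameter, collapse))

    def test_grid_partition_is_total_and_three_valued(self):
        """Brute-force enumeration: every (diameter, collapse) cell maps to
        exactly one of {3, 8, 15} and all three values are attained."""
        values = {
            echo.estimate_rap(d, c)
            for d in np.arange(5.0, 40.01, 0.5)
            for c in np.arange(0.0, 1.0001, 0.05)
        }
        assert values == {3.0, 8.0, 15.0}


class TestGradientAndEpasp:
    def test_fallback_thresholds(self):
        assert echo.tricuspid_gradient(3.0) == 36.0
        assert echo.tricuspid_gradient(3.4) == pytest.approx(46.24)
        assert round(echo.tricuspid_gradient(3.4)) == 46
        assert echo.tricuspid_gradient(0.0) == 0.0

    def test_missing_propagates(self):
        assert math.isnan(echo.tricuspid_gradient(float("nan")))
        assert math.isnan(echo.compute_epasp(36.0, float("nan")))
        assert math.isnan(echo.compute_epasp(float("nan"), 8.0))

    def test_epasp_is_sum(self):
        assert echo.compute_epasp(36.0, 3.0) == 39.0
        assert echo.compute_epasp(46.24, 8.0) == pytest.approx(54.24)

    @given(trv=st.floats(0.0, 6.0), rap=st.sampled_from([3.0, 8.0, 15.0]))
    @settings(derandomize=True, max_examples=200)
    def test_bernoulli_composition_exact(self, trv, rap):
        """compute_epasp(4t^2, r) == 4t^2 + r to machine precision, and the
        sum dominates both of its nonnegative terms."""
        g = echo.tricuspid_gradient(trv)
        p = echo.compute_epasp(g, rap)
        assert p == 4.0 * trv * trv + rap
        assert p >= g and p >= rap

    @given(lo=st.floats(0.01, 5.99), delta=st.floats(1e-6, 2.0))
    @settings(derandomize=True, max_examples=100)
    def test_gradient_strictly_monotone(self, lo, delta):
        assert echo.tricuspid_gradient(lo + delta) > echo.tricuspid_gradient(lo)


class TestFractionalShortening:
    @pytest.mark.parametrize("lvedd,lvesd,expected", [
        (50.0, 30.0, 40.0),
        (50.0, 50.0, 0.0),
        (40.0, 28.4, 29.0),
    ])
    def test_formula(self, lvedd, lvesd, expected):
        assert echo.fractional_shortening(lvedd, lvesd) == pytest.approx(expected)

    def test_inconsistent_diameters_raise(self):
        with pytest.raises(ValueError):
            echo.fractional_shortening(40.0, 41.0)
        with pytest.raises(ValueError):
            echo.fractional_shortening(0.0, 0.0)

    @pytest.mark.parametrize("fs,expected", [
        (28.9, True), (29.0, False), (41.1, False)])
    def test_systolic_dysfunction_cutoff_strict(self, fs, expected):
        assert echo.classify_lv_systolic(fs) is expected

    def test_missing_fs_unclassified(self):
        assert echo.classify_lv_systolic(float("nan")) is None


class TestRvDilated:
    @pytest.mark.parametrize("rvedd,expected", [
        (43.0, True), (42.0, False), (33.0, False)])
    def test_cutoff_strict(self, rvedd, expected):
        assert echo.classify_rv_dilated(rvedd) is expected

    def test_missing(self):
        assert echo.classify_rv_dilated(float("nan")) is None


class TestDiastolicStaging:
    def test_normal_pattern(self):
        # E/A 1.0, E/E' 7.5, E' 12 cm/s: normal under any sensible table
        assert echo.stage_diastolic(0.9, 0.9, 12.0, 250.0, af=False) == echo.STAGE_NORMAL

    def test_af_branch_ignores_a_peak(self):
        got = echo.stage_diastolic(0.8, float("nan"), 5.0, 120.0, af=True)
        assert got == echo.STAGE_3_4
        got = echo.stage_diastolic(0.8, float("nan"), 5.0, 200.0, af=True)
        assert got == echo.STAGE_2

    def test_missing_requirements(self):
        assert echo.stage_diastolic(0.9, float("nan"), 12.0, 250.0, af=False) is None
        assert echo.stage_diastolic(0.9, 0.9, 12.0, float("nan"), af=True) is None
        assert echo.stage_diastolic(float("nan"), 0.9, 12.0, 250.0, af=False) is None

    # Frozen default decision table, one representative point per branch.
    @pytest.mark.parametrize("ea,ee,eprime,expected", [
        (0.6, 7.0, 12.0, echo.STAGE_NORMAL),   # impaired relaxation counts as stage 1
        (0.6, 12.0, 6.0, echo.STAGE_NORMAL),   # low E/A stays normal/stage1 even if E/E' high
        (1.0, 12.0, 12.0, echo.STAGE_2),       # pseudonormal via E/E'
        (1.0, 8.0, 6.0, echo.STAGE_2),         # pseudonormal via low E'
        (1.0, 8.0, 12.0, echo.STAGE_NORMAL),   # normal window
        (2.0, 12.0, 12.0, echo.STAGE_3_4),     # restrictive
        (2.0, 8.0, 12.0, echo.STAGE_NORMAL),   # tall E/A but normal pressures
    ])
    def test_default_decision_table(self, ea, ee, eprime, expected):
        e_peak = ee * eprime / 100.0
        a_peak = e_peak / ea
        assert echo.stage_diastolic(e_peak, a_peak, eprime, 250.0, af=False) == expected

    def test_grid_enumeration_partitions_input_space(self):
        """Every complete sinus-rhythm input maps to exactly one stage and
        all three stages are reachable (no gaps, no overlaps)."""
        stages = set()
        for ea in np.arange(0.3, 3.01, 0.15):
            for ee in np.arange(4.0, 20.01, 1.0):
                for eprime in np.arange(3.0, 15.01, 1.0):
                    e_peak = ee * eprime / 100.0
                    got = echo.stage_diastolic(e_peak, e_peak / ea, eprime, 250.0, af=False)
                    assert got in echo.STAGES
                    stages.add(got)
        assert stages == set(echo.STAGES)


class TestVectorisedDerivation:
    def test_matches_scalar_rules(self, small_cohort):
        _, cohort, _, derived, _ = small_cohort
        sub = cohort.sample(300, random_state=0)
        for idx, row in sub.iterrows():
            rap = echo.estimate_rap(row["ivc_diameter"], row["ivc_collapse"])
            got = derived.loc[idx, "rap"]
            assert (math.isnan(rap) and math.isnan(got)) or rap == got
            g = echo.tricuspid_gradient(row["trv"])
            gotg = derived.loc[idx, "gradient"]
            assert (math.isnan(g) and math.isnan(gotg)) or g == pytest.approx(gotg)
            stage = echo.stage_diastolic(row["e_peak"], row["a_peak"], row["e_prime"],
                                         row["dec_time"], bool(row["af"]))
            assert stage == (None if pd.isna(derived.loc[idx, "diastolic_stage"])
                             else derived.loc[idx, "diastolic_stage"])

    def test_epasp_additivity_whenever_defined(self, small_cohort):
        _, _, _, derived, _ = small_cohort
        ok = derived["epasp"].notna()
        assert (derived.loc[ok, "epasp"] >= derived.loc[ok, "gradient"] - 1e-12).all()
        assert (derived.loc[ok, "epasp"] >= derived.loc[ok, "rap"] - 1e-12).all()
        np.testing.assert_allclose(
            derived.loc[ok, "epasp"],
            derived.loc[ok, "gradient"] + derived.loc[ok, "rap"], rtol=0, atol=1e-12)

    def test_inconsistent_lv_diameters_raise(self, small_cohort):
        _, cohort, *_ = small_cohort
        broken = cohort.head(10).copy()
        broken.loc[broken.index[0], "lvesd"] = broken.loc[broken.index[0], "lvedd"] + 1
        with pytest.raises(ValueError, match="LV diameters"):
            echo.derive_measures(broken)
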