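"""Geochemistry operations: I/O, chloride correction, Gran alkalinity,
SMT picking, steepest-gradient depth."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from smtdyn.geochem import (
    GranResult,
    PorewaterProfile,
    SmtNotCapturedError,
    TitrationSeries,
    chloride_correct_sulfate,
    estimate_smt_depth,
    gran_alkalinity,
    read_porewater_table,
    steepest_sulfate_gradient_depth,
    write_porewater_table,
)


class TestProfileIO:
    def test_round_trip_is_bit_exact(self, tmp_path):
        profile = PorewaterProfile(
            "GC1", depths=[10.0, 20.0, 30.0], sulfate=[28.0, 14.0, 0.2],
            methane=[np.nan, 0.1, 5.0], alkalinity=[2.4, 6.0, 11.0],
        )
        path = tmp_path / "pw.csv"
        write_porewater_table(profile, path)
        back = read_porewater_table(path)
        np.testing.assert_array_equal(back.depths, profile.depths)
        np.testing.assert_array_equal(back.sulfate, profile.sulfate)
        np.testing.assert_array_equal(back.methane, profile.methane)
        np.testing.assert_array_equal(back.alkalinity, profile.alkalinity)

    def test_minimal_three_row_table(self):
        buf = io.StringIO("core,depth_cmbsf,sulfate_mM\n"
                          "GC1,10,28\nGC1,20,14\nGC1,30,0.2\n")
        profile = read_porewater_table(buf)
        assert profile.n_samples == 3
        assert np.all(np.diff(profile.depths) > 0)

    def test_non_monotonic_depths_rejected(self):
        buf = io.StringIO("depth_cmbsf,sulfate_mM\n20,28\n10,14\n")
        with pytest.raises(ValueError, match="non-monotonic depths"):
            read_porewater_table(buf)

    def test_negative_concentration_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            PorewaterProfile("x", [0.0, 10.0], [28.0, -1.0])

    def test_case_insensitive_aliases(self):
        buf = io.StringIO("Core,Depth,SO4\nGC2,5,27\nGC2,15,20\n")
        profile = read_porewater_table(buf)
        assert profile.core_id == "GC2"
        assert profile.sulfate[1] == 20.0


class TestChlorideCorrection:
    @pytest.mark.parametrize("so4, cl, expected", [
        (10.0, 556.0, 10.0),       # reference chloride: factor 1
        (10.0, 278.0, 20.0),       # exact two-fold dilution
        (14.0, 500.0, 15.568),     # 14 * 556/500
    ])
    def test_worked_examples(self, so4, cl, expected):
        assert chloride_correct_sulfate(so4, cl) == pytest.approx(expected)

    def test_nonpositive_chloride_rejected(self):
        with pytest.raises(ValueError):
            chloride_correct_sulfate(10.0, 0.0)

    @given(so4=st.floats(0.01, 50), cl=st.floats(100, 800),
           scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_in_sulfate_and_joint_chloride_scale(self, so4, cl,
                                                             scale):
        base = chloride_correct_sulfate(so4, cl)
        assert chloride_correct_sulfate(scale * so4, cl) == \
            pytest.approx(scale * base)
        assert chloride_correct_sulfate(so4, scale * cl, 556.0 * scale) == \
            pytest.approx(base)


def simulate_bicarbonate_titration(ta_meq_l, v0_ml=0.5, c_acid=0.0012,
                                   n_points=9):
    """Independent forward model of an open-beaker HCO3- titration.

    Solves the full proton condition C_B + [H+] = [HCO3-] + 2[CO3--] +
    [OH-] + C_A at each acid addition by root-finding (first carbonate
    system: K1 = 10^-6.0, K2 = 10^-9.1, Kw = 10^-14; CO2 retained in
    solution). The oracle shares no code with the Gran fit under test.
    """
    k1, k2, kw = 10.0**-6.0, 10.0**-9.1, 10.0**-14
    dic = ta_meq_l / 1000.0  # mol/L; alkalinity carried entirely by HCO3-
    ve_true = ta_meq_l / 1000.0 * v0_ml / c_acid
    # sample well past equivalence (pH ~ 3-4) where the strong-acid excess
    # dominates residual carbonate buffering, the standard Gran region
    vols = np.linspace(ve_true * 1.5, ve_true * 4.0, n_points)

    def ph_at(v_ml):
        dil = v0_ml / (v0_ml + v_ml)
        ct = dic * dil
        ca = c_acid * v_ml / (v0_ml + v_ml)

        def proton_condition(ph):
            h = 10.0**-ph
            alpha1 = k1 * h / (h * h + k1 * h + k1 * k2)
            alpha2 = k1 * k2 / (h * h + k1 * h + k1 * k2)
            # charge balance with Na+ = DIC (NaHCO3) and Cl- = CA
            return (dic * dil + h) - (ct * alpha1 + 2 * ct * alpha2
                                      + kw / h + ca)

        return brentq(proton_condition, 2.0, 12.0, xtol=1e-10)

    ph = np.array([ph_at(v) for v in vols])
    return TitrationSeries(v0_ml, c_acid, vols, ph)


class TestGranAlkalinity:
    def test_zero_alkalinity_sample(self):
        # pH set by added strong acid alone: Ve extrapolates to ~0
        v0, c = 0.5, 0.0012
        vols = np.linspace(0.3, 1.0, 8)
        ph = -np.log10(c * vols / (v0 + vols))
        res = gran_alkalinity(TitrationSeries(v0, c, vols, ph))
        assert isinstance(res, GranResult)
        assert res.ta_meq_l == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("ta", [0.5, 2.5, 10.0, 40.0])
    def test_recovers_simulated_bicarbonate_ta_within_2pct(self, ta):
        titr = simulate_bicarbonate_titration(ta)
        res = gran_alkalinity(titr)
        assert res.ta_meq_l == pytest.approx(ta, rel=0.02)
        assert res.r_squared > 0.999

    def test_scale_invariance_of_titration(self):
        titr = simulate_bicarbonate_titration(2.5)
        ta1 = gran_alkalinity(titr).ta_meq_l
        # exact invariance: halving every volume (sample and titrant) at
        # fixed acid strength leaves all concentrations, hence the pH
        # series and the recovered TA, unchanged
        halved = TitrationSeries(titr.sample_volume / 2,
                                 titr.acid_concentration,
                                 titr.added_volumes / 2, titr.ph_readings)
        assert gran_alkalinity(halved).ta_meq_l == pytest.approx(ta1)
        # acid-strength invariance: titrating the same sample with
        # twice-strength acid (half the volumes to equivalence) recovers
        # the same TA
        stronger = simulate_bicarbonate_titration(2.5, c_acid=0.0024)
        assert gran_alkalinity(stronger).ta_meq_l == pytest.approx(ta1,
                                                                   rel=0.01)

    def test_warns_outside_reading_count_convention(self):
        with pytest.warns(UserWarning, match="7-10"):
            TitrationSeries(0.5, 0.0012, np.linspace(0.1, 1, 12),
                            np.linspace(8, 3, 12))

    def test_titration_short_of_equivalence_errors(self):
        with pytest.warns(UserWarning):
            titr = TitrationSeries(0.5, 0.0012, [0.01, 0.02, 0.03],
                                   [8.2, 8.1, 8.0])
        with pytest.raises(ValueError):
            gran_alkalinity(titr)


class TestSmtEstimate:
    def test_interpolated_threshold_crossing(self):
        profile = PorewaterProfile("x", [10.0, 50.0, 90.0],
                                   [28.0, 14.0, 0.2])
        est = estimate_smt_depth(profile, 0.5)
        assert est.depth == pytest.approx(89.13, abs=0.01)
        assert est.method == "sulfate-threshold"

    def test_not_captured_raises(self):
        profile = PorewaterProfile("PC-like", [10.0, 50.0, 90.0],
                                   [28.0, 26.0, 24.0])
        with pytest.raises(SmtNotCapturedError):
            estimate_smt_depth(profile)

    def test_exact_threshold_returns_sampled_depth(self):
        profile = PorewaterProfile("x", [10.0, 50.0, 90.0],
                                   [28.0, 0.5, 0.1])
        assert estimate_smt_depth(profile, 0.5).depth == 50.0

    def test_alkalinity_fallback_with_30cm_uncertainty(self):
        profile = PorewaterProfile(
            "x", [10.0, 40.0, 70.0, 100.0], [28.0, 25.0, 22.0, 20.0],
            alkalinity=[2.5, 3.0, 9.0, 10.0])
        est = estimate_smt_depth(profile)
        assert est.method == "alkalinity-inflection"
        assert est.depth == pytest.approx(55.0)
        assert est.uncertainty == 30.0

    def test_unit_rescale_invariance_and_threshold_monotonicity(self):
        depths = [10.0, 40.0, 70.0, 100.0]
        so4 = [28.0, 18.0, 6.0, 0.1]
        base = estimate_smt_depth(
            PorewaterProfile("x", depths, so4), 0.5).depth
        scaled = estimate_smt_depth(
            PorewaterProfile("x", depths, np.array(so4) * 3.7),
            0.5 * 3.7).depth
        assert scaled == pytest.approx(base)
        prev = np.inf
        for thr in (0.2, 0.5, 1.0, 3.0, 5.0):
            d = estimate_smt_depth(PorewaterProfile("x", depths, so4), thr).depth
            assert d <= prev + 1e-12  # raising threshold never deepens
            prev = d


class TestSteepestGradient:
    def test_worked_example(self):
        profile = PorewaterProfile("x", [0.0, 10.0, 15.0, 25.0],
                                   [28.0, 27.0, 15.0, 14.0])
        assert steepest_sulfate_gradient_depth(profile) == pytest.approx(12.5)

    def test_linear_profile_ties_to_shallowest(self):
        profile = PorewaterProfile("x", [0.0, 10.0, 20.0, 30.0],
                                   [28.0, 26.0, 24.0, 22.0])
        assert steepest_sulfate_gradient_depth(profile) == pytest.approx(5.0)

    def test_extra_sample_in_flat_interval_does_not_move_answer(self):
        base = PorewaterProfile("x", [0.0, 10.0, 15.0, 25.0],
                                [28.0, 27.0, 15.0, 14.0])
        refined = PorewaterProfile("x", [0.0, 5.0, 10.0, 15.0, 25.0],
                                   [28.0, 27.5, 27.0, 15.0, 14.0])
        assert steepest_sulfate_gradient_depth(refined) == \
            steepest_sulfate_gradient_depth(base)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            steepest_sulfate_gradient_depth(
                PorewaterProfile("x", [0.0, 10.0], [28.0, 20.0]))
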