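"""Methane-state classification and onset-time fitting."""

import numpy as np
import pytest

from smtdyn import defaults
from smtdyn.classify import (
    PorewaterStateModel,
    UnclassifiableError,
    classify_methane_state,
    fit_onset_time,
    linearity_metrics,
)
from smtdyn.geochem import PorewaterProfile
from smtdyn.synth import SynthSpec, synth_porewater

from conftest import STATE_DEPTHS, make_profile


class TestLinearityMetrics:
    def test_exactly_linear_profile(self):
        depths = np.arange(10.0, 120.0, 10.0)
        profile = PorewaterProfile("lin", depths, 28.0 - 0.25 * depths)
        m = linearity_metrics(profile)
        assert m.linearity_r2 == pytest.approx(1.0)
        assert abs(m.quadratic_coef) < 1e-12
        assert m.breakpoint_depth is None

    def test_two_slope_profile_breakpoint_location(self):
        depths = np.arange(0.0, 200.0, 10.0)
        so4 = np.where(depths <= 100.0, 28.0 - 0.02 * depths,
                       26.0 - 0.2 * (depths - 100.0))
        profile = PorewaterProfile("bp", depths, np.clip(so4, 0.01, None))
        m = linearity_metrics(profile, smt=None)
        assert m.breakpoint_depth is not None
        assert abs(m.breakpoint_depth - 100.0) <= 10.0  # one sample spacing
        assert m.upper_segment_r2 > 0.99

    def test_model_increasing_profile_flags_concave_up(self, increasing_run):
        st = increasing_run.states[-1]
        depths_cm = np.arange(10.0, 301.0, 10.0)
        so4 = np.interp(depths_cm / 100.0, st.z, st.sulfate)
        profile = PorewaterProfile("inc", depths_cm, so4)
        m = linearity_metrics(profile)
        assert m.curvature_sign > 0
        assert m.curvature_p < 0.05

    def test_too_few_points(self):
        with pytest.raises(UnclassifiableError):
            linearity_metrics(PorewaterProfile("x", [0, 10, 20],
                                               [28, 20, 12]))


class TestClassification:
    def test_seep_rule_fires_by_construction(self):
        profile = PorewaterProfile(
            "seep", [5.0, 20.0, 40.0, 60.0], [27.0, 26.5, 26.0, 25.5],
            methane=[2.0, 30.0, 28.0, 30.0])
        assert classify_methane_state(profile).label == "seep"

    def test_synthetic_steady_profile_classified_steady(self, state_runs):
        profile, _ = make_profile("steady", seed=3, state_runs=state_runs)
        c = classify_methane_state(profile)
        assert c.label == "steady"
        assert c.linearity_r2 > 0.9

    def test_synthetic_increasing_profile_classified(self, state_runs):
        profile, _ = make_profile("increasing", seed=3, state_runs=state_runs)
        assert classify_methane_state(profile).label == "increasing"

    def test_confusion_matrix_diagonal(self, state_runs):
        """>= 90 % of 40 synthetic profiles (10 per state, seeded) land
        on their generating state."""
        hits = total = 0
        for state in ("steady", "transitional", "increasing", "seep"):
            for seed in range(10):
                profile, truth = make_profile(state, seed, state_runs)
                label = classify_methane_state(profile).label
                total += 1
                hits += (label == truth["state"])
        assert total == 40
        assert hits / total >= 0.90

    def test_classification_invariant_under_regridding(self, steady_run):
        st = steady_run.states[-1]
        labels = []
        for depths_cm in (np.arange(5.0, 116.0, 10.0),
                          np.arange(2.0, 116.0, 6.0)):
            so4 = np.interp(depths_cm / 100.0, st.z, st.sulfate)
            labels.append(classify_methane_state(
                PorewaterProfile("re", depths_cm, so4)).label)
        assert labels[0] == labels[1] == "steady"


class TestOnsetFit:
    def test_noise_free_self_consistency(self, transitional_grid_run,
                                         onset_grid, column):
        spec = SynthSpec(state="transitional",
                         depths_cm=STATE_DEPTHS["transitional"],
                         onset_age=100.0, seed=0, sulfate_noise_mm=0.0,
                         alkalinity_noise_meql=0.0)
        profile, _ = synth_porewater(spec, run=_view(transitional_grid_run,
                                                     100.0))
        fit = fit_onset_time(profile, transitional_grid_run.scenario, column,
                             onset_grid, run=transitional_grid_run)
        assert fit.elapsed_time == pytest.approx(100.0, abs=5.0)
        assert fit.rmse < 0.05

    def test_noisy_recovery_within_10pct(self, transitional_grid_run,
                                         onset_grid, column):
        errors = []
        for seed in range(20):
            spec = SynthSpec(state="transitional",
                             depths_cm=STATE_DEPTHS["transitional"],
                             onset_age=100.0, seed=seed, sulfate_noise_mm=1.0)
            profile, _ = synth_porewater(
                spec, run=_view(transitional_grid_run, 100.0))
            fit = fit_onset_time(profile, transitional_grid_run.scenario,
                                 column, onset_grid,
                                 run=transitional_grid_run)
            errors.append(abs(fit.elapsed_time - 100.0) / 100.0)
        assert np.median(errors) <= 0.10

    def test_rmse_is_unimodal_near_optimum(self, transitional_grid_run,
                                           onset_grid, column):
        spec = SynthSpec(state="transitional",
                         depths_cm=STATE_DEPTHS["transitional"],
                         onset_age=100.0, seed=0, sulfate_noise_mm=0.0,
                         alkalinity_noise_meql=0.0)
        profile, _ = synth_porewater(spec, run=_view(transitional_grid_run,
                                                     100.0))
        fit = fit_onset_time(profile, transitional_grid_run.scenario, column,
                             onset_grid, run=transitional_grid_run)
        r = fit.grid_rmse
        i = int(np.argmin(r))
        assert np.all(np.diff(r[:i + 1]) <= 1e-9)
        assert np.all(np.diff(r[i:]) >= -1e-9)

    def test_empty_grid_rejected(self, transitional_grid_run, column):
        profile = PorewaterProfile("x", [0, 10, 20, 30], [28, 20, 12, 4])
        with pytest.raises(ValueError):
            fit_onset_time(profile, transitional_grid_run.scenario, column,
                           [])


class TestModelResultsInterface:
    def test_fit_returns_summary_and_dict(self, state_runs,
                                          transitional_grid_run, onset_grid):
        profile, _ = make_profile("transitional", seed=1,
                                  state_runs=state_runs)
        model = PorewaterStateModel(profile)
        res = model.fit(search_grid=onset_grid, run=transitional_grid_run)
        assert res.state == "transitional"
        d = res.as_dict()
        assert d["core"] == profile.core_id
        assert d["smt_depth_cmbsf"] is not None
        text = str(res.summary())
        assert "transitional" in text
        assert "SMT depth" in text

    def test_seep_profiles_are_never_dated(self, state_runs):
        profile, _ = make_profile("seep", seed=0, state_runs=state_runs)
        res = PorewaterStateModel(profile).fit()
        assert res.state == "seep"
        assert res.onset is None

    def test_from_dataframe_round_trip(self, state_runs):
        profile, _ = make_profile("steady", seed=0, state_runs=state_runs)
        model = PorewaterStateModel.from_dataframe(profile.to_frame())
        np.testing.assert_allclose(model.profile.sulfate, profile.sulfate)


def _view(run, onset_age):
    from conftest import _run_view_at

    return _run_view_at(run, run.scenario.t_step + onset_age)
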