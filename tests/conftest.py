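"""Shared fixtures: the calibrated scenario runs are expensive (seconds
each), so they are simulated once per session and reused across the
classifier, synthetic-data, and acceptance tests."""

import numpy as np
import pytest

from smtdyn import defaults
from smtdyn.rtm import build_column, simulate
from smtdyn.synth import SynthSpec, synth_porewater


@pytest.fixture(scope="session")
def column():
    return defaults.default_column()


@pytest.fixture(scope="session")
def steady_run(column):
    """Calibrated steady scenario to 40 kyr, late snapshots saved."""
    sc = defaults.steady_scenario()
    return simulate(sc, column, defaults.STEADY_T_END_YR,
                    save_times=[defaults.STEADY_LATE_WINDOW_YR[0],
                                defaults.STEADY_T_END_YR])


@pytest.fixture(scope="session")
def increasing_run(column):
    """Calibrated flux-increase scenario, 25 yr past the step."""
    sc = defaults.increasing_scenario()
    t_end = sc.t_step + defaults.INCREASING_POST_YR
    return simulate(sc, column, t_end, save_times=[sc.t_step + 15.0, t_end])


@pytest.fixture(scope="session")
def transitional_grid_run(column):
    """Transitional scenario with snapshots on the onset search grid."""
    sc = defaults.transitional_scenario()
    grid = np.arange(20.0, 151.0, 10.0)
    return simulate(sc, column, sc.t_step + defaults.TRANSITIONAL_POST_YR,
                    save_times=list(sc.t_step + grid), dt_transient=0.2)


@pytest.fixture(scope="session")
def onset_grid():
    return np.arange(20.0, 151.0, 10.0)


@pytest.fixture(scope="session")
def gene_run():
    """Flux-increase run on a low-k column whose AOM pulse is tens of
    cm wide -- the pulse geometry the observed gene profiles and the
    10-33.5 cm doubling-time intervals imply -- used as the emulation
    target for gene-profile dynamics."""
    col = defaults.default_column(k_aom=0.05)
    sc = defaults.increasing_scenario()
    t_end = sc.t_step + defaults.INCREASING_POST_YR
    return simulate(sc, col, t_end, save_times=[t_end])


@pytest.fixture(scope="session")
def gene_growth_depths(gene_run):
    """Ten sampling depths spanning the partially-exposed growth limb
    of the final AOM pulse (inside the half-peak band), plus the band
    width (cm)."""
    st = gene_run.states[-1]
    z_pk = st.z[int(np.argmax(st.aom_rate))] * 100.0
    above = st.aom_rate >= 0.5 * st.aom_rate.max()
    w = (st.z[above].max() - st.z[above].min()) * 100.0
    return tuple(np.linspace(z_pk - 0.4 * w, z_pk + 0.4 * w, 10)), w


# per-state sampling depths giving >= 4 usable above-SMT points
STATE_DEPTHS = {
    "steady": tuple(np.arange(5.0, 116.0, 10.0)),
    "transitional": tuple(np.arange(10.0, 401.0, 15.0)),
    "increasing": tuple(np.arange(10.0, 301.0, 10.0)),
    "seep": tuple(np.arange(5.0, 106.0, 10.0)),
}

STATE_ONSETS = {"steady": None, "transitional": 100.0, "increasing": 15.0,
                "seep": None}


@pytest.fixture(scope="session")
def state_runs(column, steady_run, transitional_grid_run, increasing_run):
    """Reference run per state at the onset used for profile synthesis."""
    return {"steady": steady_run, "transitional": transitional_grid_run,
            "increasing": increasing_run, "seep": None}


def make_profile(state, seed, state_runs, noise=0.5, onset=None):
    """Synthesize one porewater profile from the session reference runs."""
    onset = STATE_ONSETS[state] if onset is None else onset
    spec = SynthSpec(state=state, depths_cm=STATE_DEPTHS[state],
                     onset_age=onset, seed=seed, sulfate_noise_mm=noise)
    run = state_runs[state]
    if run is not None and onset is not None:
        # sample the snapshot closest to the requested onset age
        t_abs = run.scenario.t_step + onset
        run = _run_view_at(run, t_abs)
    return synth_porewater(spec, run=run)


def _run_view_at(run, t_abs):
    """A shallow view of a run whose final state is the snapshot
    closest to t_abs (the generators sample states[-1])."""
    from smtdyn.rtm import RunResult

    st = run.state_at(t_abs)
    return RunResult(states=[st], smt_times=run.smt_times,
                     smt_depths=run.smt_depths,
                     mass_balance_residual=run.mass_balance_residual,
                     scenario=run.scenario, budget=run.budget)
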