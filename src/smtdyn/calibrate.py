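"""Nested 1-D calibration of the model's supply-side parameters.

The reduced sulfate-methane network has four free parameters with no
direct observational constraint: the effective bottom-boundary methane
concentration of the steady scenario (C_steady), the bimolecular AOM
rate constant (k), the ascent rate of the stepped gas front in the
increasing scenario (w), and the intermediate front concentration of
the transitional scenario (C_mid). Each maps monotonically onto one
printed benchmark quantity, so the calibration is a cascade of
bracketed scalar root-finds:

    C_steady -> steady-state SMT depth (~1 m at 40 kyr)
    k        -> steady peak AOM rate (~10 nmol cm^-3 d^-1)
    w        -> SMT shoaling under a recent flux increase (~10 cm/yr)
    C_mid    -> transitional SMT shoaling (~0.4 cm/yr)

The report lists every target with the achieved value and relative
error -- including quantities that are *measured but not calibrated*
(fluxes, the increasing-scenario peak, late-time creep), so residual
disagreement is visible rather than hidden.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import defaults
from .rtm import (
    ScenarioSpec,
    build_column,
    depth_integrated_aom,
    simulate,
    smt_depth_model,
    smt_migration_rate,
)

__all__ = ["CalibrationReport", "calibrate_defaults", "PRINTED_TARGETS",
           "measure_steady", "measure_step_scenario"]

#: benchmark values the defaults are pinned against
PRINTED_TARGETS = {
    "steady_smt_m": 1.0,
    "steady_peak_nmol_cm3_d": 10.0,
    "steady_flux_mol_m2_yr": 1.3,
    "steady_late_shoal_cm_yr": 7e-3,
    "increasing_shoal_cm_yr": 10.0,
    "increasing_peak_nmol_cm3_d": 200.0,
    "transitional_shoal_cm_yr": 0.4,
}

DEFAULT_BOUNDS = {
    "c_steady": (600.0, 4000.0),
    "k_aom": (5.0, 300.0),
    # upper bound keeps the front below its ceiling through the whole
    # measurement window, where the shoaling response is monotone in w
    "front_rise": (0.05, 0.14),
    "c_mid": (5.0, 120.0),
}


@dataclass
class CalibrationReport:
    """Calibrated parameters plus per-target achieved values/errors."""

    params: dict
    rows: list = field(default_factory=list)  # dicts: target/value/achieved/err
    protocol: dict = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(abs(r["rel_error"]) <= 0.5 for r in self.rows
                   if r["calibrated"])

    def add(self, name, target, achieved, calibrated):
        self.rows.append({
            "target": name, "value": float(target),
            "achieved": float(achieved),
            "rel_error": float((achieved - target) / target),
            "calibrated": bool(calibrated),
        })

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"params": self.params, "targets": self.rows,
                       "protocol": self.protocol}, fh, indent=2)


def measure_steady(c_steady, k_aom, dz=defaults.GRID_DZ_M,
                   t_end=defaults.STEADY_T_END_YR,
                   window=defaults.STEADY_LATE_WINDOW_YR):
    """Run the steady scenario; return SMT (m), peak AOM (nmol cm^-3
    d^-1), flux (mol m^-2 yr^-1) and late-window shoaling (cm/yr)."""
    col = build_column(dz=dz, porosity=defaults.POROSITY, k_aom=k_aom)
    sc = ScenarioSpec("steady", base_methane=c_steady)
    res = simulate(sc, col, t_end, save_times=[t_end])
    st = res.states[-1]
    return {
        "smt_m": smt_depth_model(st),
        "peak_nmol_cm3_d": float(st.aom_rate_nmol_cm3_d().max()),
        "flux_mol_m2_yr": depth_integrated_aom(st, col),
        "late_shoal_cm_yr": smt_migration_rate(res, window[0], window[1]),
    }


def measure_step_scenario(label, step_methane, step_source_depth,
                          front_rise, k_aom, post_years, window,
                          dz=defaults.GRID_DZ_M,
                          base_methane=defaults.C_BOTTOM_WEAK_MM,
                          t_step=defaults.T_SPINUP_YR,
                          dt_transient=0.05):
    """Run a step scenario; return shoaling over the window (cm/yr),
    end-state peak AOM and flux."""
    col = build_column(dz=dz, porosity=defaults.POROSITY, k_aom=k_aom)
    sc = ScenarioSpec(label, base_methane=base_methane,
                      step_methane=step_methane,
                      step_source_depth=step_source_depth,
                      t_step=t_step, front_rise_rate=front_rise)
    res = simulate(sc, col, t_step + post_years,
                   save_times=[t_step + post_years],
                   dt_transient=dt_transient)
    st = res.states[-1]
    return {
        "shoal_cm_yr": smt_migration_rate(res, t_step + window[0],
                                          t_step + window[1]),
        "peak_nmol_cm3_d": float(st.aom_rate_nmol_cm3_d().max()),
        "flux_mol_m2_yr": depth_integrated_aom(st, col),
    }


def calibrate_defaults(targets=None, bounds=None, dz=defaults.GRID_DZ_M,
                       t_end=defaults.STEADY_T_END_YR,
                       steady_window=defaults.STEADY_LATE_WINDOW_YR,
                       increasing_post=defaults.INCREASING_POST_YR,
                       increasing_window=defaults.INCREASING_WINDOW_YR,
                       transitional_post=defaults.TRANSITIONAL_POST_YR,
                       transitional_window=defaults.TRANSITIONAL_WINDOW_YR,
                       rtol=0.01, verbose=False) -> CalibrationReport:
    """Run the calibration cascade against ``targets`` (defaults:
    :data:`PRINTED_TARGETS`; pass a subset to calibrate fewer knobs).

    Widening a bound can only improve the achieved objective (each
    search is a bracketed root-find on a monotone response). If a root
    is not bracketed, the nearest bound is taken and the residual is
    reported honestly in the report rather than silently accepted.
    """
    targets = dict(PRINTED_TARGETS if targets is None else targets)
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    report = CalibrationReport(params={}, protocol={
        "dz_m": dz, "t_end_yr": t_end, "steady_window_yr": list(steady_window),
        "increasing_post_yr": increasing_post,
        "increasing_window_yr": list(increasing_window),
        "transitional_post_yr": transitional_post,
        "transitional_window_yr": list(transitional_window),
    })

    def solve(fun, lo, hi, xtol):
        flo, fhi = fun(lo), fun(hi)
        if flo * fhi > 0:  # not bracketed: pick the closer endpoint
            return lo if abs(flo) < abs(fhi) else hi
        return brentq(fun, lo, hi, xtol=xtol)

    c_steady = defaults.C_BOTTOM_STEADY_MM
    k_aom = defaults.K_AOM

    if "steady_smt_m" in targets:
        tgt = targets["steady_smt_m"]

        def f_smt(logc):
            m = measure_steady(10.0**logc, k_aom, dz, t_end, steady_window)
            if verbose:
                print(f"  C_steady={10.0**logc:.0f} -> SMT {m['smt_m']:.3f} m")
            return m["smt_m"] - tgt

        lo, hi = bounds["c_steady"]
        c_steady = 10.0 ** solve(f_smt, np.log10(lo), np.log10(hi),
                                 xtol=rtol / 2)
    report.params["c_bottom_steady_mm"] = float(c_steady)

    if "steady_peak_nmol_cm3_d" in targets:
        tgt = targets["steady_peak_nmol_cm3_d"]

        def f_peak(logk):
            m = measure_steady(c_steady, 10.0**logk, dz, t_end, steady_window)
            if verbose:
                print(f"  k={10.0**logk:.1f} -> peak {m['peak_nmol_cm3_d']:.2f}")
            return m["peak_nmol_cm3_d"] - tgt

        lo, hi = bounds["k_aom"]
        k_aom = 10.0 ** solve(f_peak, np.log10(lo), np.log10(hi), xtol=rtol)
    report.params["k_aom_mm_yr"] = float(k_aom)

    steady = measure_steady(c_steady, k_aom, dz, t_end, steady_window)
    for name, key, calibrated in [
        ("steady_smt_m", "smt_m", True),
        ("steady_peak_nmol_cm3_d", "peak_nmol_cm3_d", True),
        ("steady_flux_mol_m2_yr", "flux_mol_m2_yr", False),
        ("steady_late_shoal_cm_yr", "late_shoal_cm_yr", False),
    ]:
        if name in targets:
            report.add(name, targets[name], steady[key], calibrated)

    front_rise = defaults.FRONT_RISE_M_YR
    if "increasing_shoal_cm_yr" in targets:
        tgt = targets["increasing_shoal_cm_yr"]

        def f_shoal(w):
            m = measure_step_scenario(
                "increasing", defaults.C_STEP_INCREASING_MM,
                defaults.Z_FRONT_INCREASING_M, w, k_aom,
                increasing_post, increasing_window, dz)
            if verbose:
                print(f"  w={w:.3f} -> shoal {m['shoal_cm_yr']:.2f} cm/yr")
            return m["shoal_cm_yr"] - tgt

        lo, hi = bounds["front_rise"]
        front_rise = solve(f_shoal, lo, hi, xtol=1e-3)
        incr = measure_step_scenario(
            "increasing", defaults.C_STEP_INCREASING_MM,
            defaults.Z_FRONT_INCREASING_M, front_rise, k_aom,
            increasing_post, increasing_window, dz)
        report.add("increasing_shoal_cm_yr", tgt, incr["shoal_cm_yr"], True)
        if "increasing_peak_nmol_cm3_d" in targets:
            report.add("increasing_peak_nmol_cm3_d",
                       targets["increasing_peak_nmol_cm3_d"],
                       incr["peak_nmol_cm3_d"], False)
    report.params["front_rise_m_yr"] = float(front_rise)

    c_mid = defaults.C_STEP_TRANSITIONAL_MM
    if "transitional_shoal_cm_yr" in targets:
        tgt = targets["transitional_shoal_cm_yr"]

        def f_trans(logc):
            m = measure_step_scenario(
                "transitional", 10.0**logc, defaults.Z_FRONT_TRANSITIONAL_M,
                0.0, k_aom, transitional_post, transitional_window, dz,
                dt_transient=0.2)
            if verbose:
                print(f"  C_mid={10.0**logc:.1f} -> {m['shoal_cm_yr']:.3f}")
            return m["shoal_cm_yr"] - tgt

        lo, hi = bounds["c_mid"]
        c_mid = 10.0 ** solve(f_trans, np.log10(lo), np.log10(hi), xtol=rtol)
        trans = measure_step_scenario(
            "transitional", c_mid, defaults.Z_FRONT_TRANSITIONAL_M, 0.0,
            k_aom, transitional_post, transitional_window, dz,
            dt_transient=0.2)
        report.add("transitional_shoal_cm_yr", tgt, trans["shoal_cm_yr"], True)
    report.params["c_step_transitional_mm"] = float(c_mid)
    return report
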