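"""Simple profile and diagnostic figures.

Matplotlib is imported lazily so headless library use never touches a
plotting backend.
"""

from __future__ import annotations

import numpy as np


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(4, 6))
    return ax


def plot_state(state, ax=None, max_depth_m=None):
    """Sulfate (black), methane (blue) and AOM rate (red, top axis) of
    one model snapshot, depth increasing downward."""
    ax = _get_axes(ax)
    z = state.z
    mask = slice(None) if max_depth_m is None else z <= max_depth_m
    ax.plot(state.sulfate[mask], z[mask], "k-", label="SO$_4^{2-}$ (mM)")
    ax.plot(state.methane[mask], z[mask], "b-", label="CH$_4$ (mM)")
    rax = ax.twiny()
    rax.plot(state.aom_rate_nmol_cm3_d()[mask], z[mask], "r-")
    rax.set_xlabel("AOM rate (nmol cm$^{-3}$ d$^{-1}$)", color="r")
    ax.invert_yaxis()
    ax.set_xlabel("concentration (mM)")
    ax.set_ylabel("depth (mbsf)")
    ax.legend(loc="lower right", fontsize=8)
    ax.set_title(f"t = {state.time:,.0f} yr")
    return ax


def plot_smt_trajectory(result, ax=None, relative_to_step=True):
    """SMT depth versus time for a run (years since the boundary step
    when one exists)."""
    ax = _get_axes(ax)
    t, z = result.smt_trajectory
    t = np.asarray(t, dtype=float)
    if (relative_to_step and result.scenario is not None
            and result.scenario.t_step is not None):
        t = t - result.scenario.t_step
        ax.set_xlabel("years since methane-flux step")
    else:
        ax.set_xlabel("model time (yr)")
    ok = np.isfinite(z)
    ax.plot(t[ok], np.asarray(z)[ok], "k-")
    ax.invert_yaxis()
    ax.set_ylabel("SMT depth (mbsf)")
    return ax


def plot_profile_fit(results, ax=None):
    """Observed sulfate and, when available, the onset-fit model curve
    for a classified core."""
    ax = _get_axes(ax)
    profile = results.model.profile
    depths, so4 = profile.sulfate_observed()
    ax.plot(so4, depths, "ko", ms=4, label="observed SO$_4^{2-}$")
    if results.onset is not None:
        ax.plot(results.onset.profile_at_fit, depths, "r-",
                label=f"model, onset {results.onset.elapsed_time:.0f} yr")
    smt = results.classification.smt
    if smt is not None:
        ax.axhline(smt.depth, ls="--", c="gray", lw=1)
    ax.invert_yaxis()
    ax.set_xlabel("sulfate (mM)")
    ax.set_ylabel("depth (cmbsf)")
    ax.set_title(f"{profile.core_id}: {results.state}")
    ax.legend(fontsize=8)
    return ax
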