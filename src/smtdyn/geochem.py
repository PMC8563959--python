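"""Porewater geochemistry: tabular I/O and the small shipboard computations.

Covers the observational side of the workflow: reading/writing porewater
profile tables (depth series of sulfate, methane, alkalinity, sulfide,
chloride for one core), the chloride-based correction of ion-chromatography
sulfate, Gran-function total alkalinity from open-beaker acidimetric
titrations, picking the sulfate-methane transition (SMT) from measured
profiles, and locating the steepest sulfate gradient (used as an AOM-peak
proxy where reactive-transport modelling is not applicable, e.g. seep
cores).

Depth convention: depths are positive downward in centimeters below
seafloor (cmbsf) in all I/O; model-facing code converts to meters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PorewaterProfile",
    "TitrationSeries",
    "SmtEstimate",
    "GranResult",
    "SmtNotCapturedError",
    "read_porewater_table",
    "write_porewater_table",
    "chloride_correct_sulfate",
    "gran_alkalinity",
    "estimate_smt_depth",
    "steepest_sulfate_gradient_depth",
]

#: reference seawater-like chloride used to normalize IC sulfate (mM)
CHLORIDE_REFERENCE_MM = 556.0

#: alkalinity-based SMT picks are only rough constraints (cm)
ALKALINITY_SMT_UNCERTAINTY_CM = 30.0

DEFAULT_SMT_THRESHOLD_MM = 0.5

_COLUMN_ALIASES = {
    "core": ("core", "core_id", "site"),
    "depth": ("depth_cmbsf", "depth", "depth_cm", "cmbsf"),
    "sulfate": ("sulfate_mm", "sulfate", "so4_mm", "so4"),
    "methane": ("methane_mm", "methane", "ch4_mm", "ch4"),
    "alkalinity": ("alkalinity_meql", "alkalinity", "ta_meql", "ta"),
    "sulfide": ("sulfide_um", "sulfide", "hs_um", "h2s"),
    "chloride": ("chloride_mm", "chloride", "cl_mm", "cl"),
}


class SmtNotCapturedError(ValueError):
    """The profile does not constrain an SMT (e.g. an active seep core
    where sulfate never draws down within the recovered interval)."""


def _clean_optional(values, n, name):
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have one value per depth")
    if np.any(arr[np.isfinite(arr)] < 0):
        bad = int(np.flatnonzero(np.isfinite(arr) & (arr < 0))[0])
        raise ValueError(f"negative {name} concentration at row {bad}")
    if not np.isfinite(arr).any():
        return None
    return arr


@dataclass
class PorewaterProfile:
    """Observed depth series of porewater solutes for one core.

    ``depths`` are cmbsf, strictly increasing; ``sulfate`` in mM;
    optional companions: ``methane`` (mM; may be missing at some depths
    because gas escapes during core recovery), ``alkalinity`` (meq/L),
    ``sulfide`` (uM), ``chloride`` (mM). Missing values are NaN.
    """

    core_id: str
    depths: np.ndarray
    sulfate: np.ndarray
    methane: np.ndarray | None = None
    alkalinity: np.ndarray | None = None
    sulfide: np.ndarray | None = None
    chloride: np.ndarray | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        n = self.depths.size
        if n == 0:
            raise ValueError("profile has no samples")
        if np.any(self.depths < 0):
            raise ValueError("depths must be nonnegative (cmbsf)")
        if np.any(np.diff(self.depths) <= 0):
            bad = int(np.flatnonzero(np.diff(self.depths) <= 0)[0]) + 1
            raise ValueError(f"non-monotonic depths at row {bad}")
        self.sulfate = np.asarray(self.sulfate, dtype=float)
        if self.sulfate.shape != (n,):
            raise ValueError("sulfate must have one value per depth")
        if np.any(self.sulfate[np.isfinite(self.sulfate)] < 0):
            bad = int(np.flatnonzero(np.isfinite(self.sulfate) & (self.sulfate < 0))[0])
            raise ValueError(f"negative sulfate concentration at row {bad}")
        for name in ("methane", "alkalinity", "sulfide", "chloride"):
            setattr(self, name, _clean_optional(getattr(self, name), n, name))

    @property
    def n_samples(self) -> int:
        return self.depths.size

    def sulfate_observed(self):
        """(depths, sulfate) restricted to rows with a sulfate value."""
        ok = np.isfinite(self.sulfate)
        return self.depths[ok], self.sulfate[ok]

    def to_frame(self) -> pd.DataFrame:
        data = {"core": self.core_id, "depth_cmbsf": self.depths,
                "sulfate_mM": self.sulfate}
        for name, col in (("methane", "methane_mM"),
                          ("alkalinity", "alkalinity_meqL"),
                          ("sulfide", "sulfide_uM"),
                          ("chloride", "chloride_mM")):
            arr = getattr(self, name)
            if arr is not None:
                data[col] = arr
        return pd.DataFrame(data)


@dataclass
class TitrationSeries:
    """One open-beaker acidimetric titration.

    ``sample_volume`` mL of porewater titrated with
    ``acid_concentration`` M HCl; ``added_volumes`` are cumulative
    titrant volumes (mL, strictly increasing) with a pH reading at each
    addition. Field practice is 7-10 readings per sample; a count
    outside that range triggers a warning, not an error.
    """

    sample_volume: float
    acid_concentration: float
    added_volumes: np.ndarray
    ph_readings: np.ndarray

    def __post_init__(self):
        if self.sample_volume <= 0:
            raise ValueError("sample_volume must be positive")
        if self.acid_concentration <= 0:
            raise ValueError("acid_concentration must be positive")
        self.added_volumes = np.asarray(self.added_volumes, dtype=float)
        self.ph_readings = np.asarray(self.ph_readings, dtype=float)
        if self.added_volumes.shape != self.ph_readings.shape:
            raise ValueError("added_volumes and ph_readings differ in length")
        if np.any(np.diff(self.added_volumes) <= 0):
            raise ValueError("added_volumes must be strictly increasing")
        n = self.added_volumes.size
        if not 7 <= n <= 10:
            warnings.warn(
                f"{n} titration readings; 7-10 expected per sample",
                stacklevel=2,
            )


@dataclass
class SmtEstimate:
    """An SMT depth pick with its method and uncertainty (cm)."""

    depth: float
    method: str  # sulfate-threshold | alkalinity-inflection | model-crossing
    uncertainty: float = 0.0

    def __post_init__(self):
        if self.depth < 0 or self.uncertainty < 0:
            raise ValueError("depth and uncertainty must be nonnegative")


@dataclass
class GranResult:
    """Total alkalinity from a Gran-function fit."""

    ta_meq_l: float
    equivalence_volume_ml: float
    r_squared: float
    n_points: int


# ------------------------------------------------------------------- I/O


def _resolve_columns(columns, dialect=None):
    dialect = dialect or {}
    lookup = {c.lower().strip(): c for c in columns}
    out = {}
    for field_name, aliases in _COLUMN_ALIASES.items():
        if field_name in dialect:
            if dialect[field_name] in columns:
                out[field_name] = dialect[field_name]
            continue
        for alias in aliases:
            if alias in lookup:
                out[field_name] = lookup[alias]
                break
    return out


def read_porewater_table(path, core=None, dialect=None) -> PorewaterProfile:
    """Read one core's porewater profile from a CSV table.

    Column names are resolved case-insensitively against standard
    aliases (depth_cmbsf, sulfate_mM, ...), or explicitly via
    ``dialect`` (mapping field name -> column name). If the table holds
    several cores, ``core`` selects one. Rows with missing sulfate are
    retained (as NaN); depths must be strictly increasing.
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(df.columns, dialect)
    if "depth" not in cols or "sulfate" not in cols:
        raise ValueError(
            f"could not resolve depth/sulfate columns among {list(df.columns)}")
    if "core" in cols:
        cores = df[cols["core"]].astype(str).unique()
        if core is None:
            if len(cores) > 1:
                raise ValueError(
                    f"table holds cores {sorted(cores)}; pass core=...")
            core = cores[0]
        df = df[df[cols["core"]].astype(str) == str(core)]
        if df.empty:
            raise ValueError(f"core {core!r} not present in table")
    core_id = str(core) if core is not None else "unknown"
    kwargs = {}
    for name in ("methane", "alkalinity", "sulfide", "chloride"):
        if name in cols:
            kwargs[name] = df[cols[name]].to_numpy(dtype=float)
    return PorewaterProfile(
        core_id=core_id,
        depths=df[cols["depth"]].to_numpy(dtype=float),
        sulfate=df[cols["sulfate"]].to_numpy(dtype=float),
        **kwargs,
    )


def write_porewater_table(profile: PorewaterProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


# ------------------------------------------------------- small computations


def chloride_correct_sulfate(sulfate_measured, chloride_measured,
                             chloride_reference=CHLORIDE_REFERENCE_MM):
    """Normalize IC sulfate to a constant chloride background.

    Instrument dilution is corrected multiplicatively by assuming
    porewater chloride is uniform at ``chloride_reference`` (556 mM for
    these Arctic shelf sites): returns
    ``sulfate_measured * chloride_reference / chloride_measured``.
    """
    chloride_measured = np.asarray(chloride_measured, dtype=float)
    if np.any(chloride_measured <= 0):
        raise ValueError("chloride_measured must be positive")
    out = np.asarray(sulfate_measured, dtype=float) * (
        chloride_reference / chloride_measured)
    return float(out) if out.ndim == 0 else out


def gran_alkalinity(titration: TitrationSeries, fit_window=None) -> GranResult:
    """Total alkalinity (meq/L) by Gran-function extrapolation.

    The Gran function F(V) = (V0 + V) * 10^(-pH) is linear in added
    acid volume V past the carbonate equivalence point; a line fitted
    to the acid-side readings extrapolated to F = 0 gives the
    equivalence volume Ve, and TA = Ve * C_acid / V0 (in eq/L, reported
    as meq/L).

    fit_window selects the acid-side readings: None applies the default
    rule (pH < 4.5 at/after the steepest single-addition pH drop), or
    pass a (lo, hi) pH interval, or a boolean mask per reading.
    """
    v = titration.added_volumes
    ph = titration.ph_readings
    v0 = titration.sample_volume
    if fit_window is None:
        drop = np.diff(ph)
        steepest = int(np.argmin(drop)) + 1 if drop.size else 0
        mask = np.zeros(ph.size, dtype=bool)
        mask[steepest:] = ph[steepest:] < 4.5
    elif isinstance(fit_window, tuple):
        lo, hi = fit_window
        mask = (ph >= lo) & (ph <= hi)
    else:
        mask = np.asarray(fit_window, dtype=bool)
    if mask.sum() < 3:
        raise ValueError(
            "fewer than 3 readings in the acid-side Gran window; titrate "
            "further past the equivalence point")
    f = (v0 + v) * 10.0 ** (-ph)
    slope, intercept = np.polyfit(v[mask], f[mask], 1)
    ve = -intercept / slope
    if ve < -1e-9 * v[-1]:
        raise ValueError("titration did not pass equivalence "
                         "(negative extrapolated Ve)")
    ve = max(ve, 0.0)
    resid = f[mask] - (slope * v[mask] + intercept)
    ss_tot = float(np.sum((f[mask] - f[mask].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    ta = ve * titration.acid_concentration / v0 * 1000.0
    return GranResult(ta_meq_l=float(ta), equivalence_volume_ml=float(ve),
                      r_squared=r2, n_points=int(mask.sum()))


def estimate_smt_depth(profile: PorewaterProfile,
                       sulfate_threshold=DEFAULT_SMT_THRESHOLD_MM) -> SmtEstimate:
    """Pick the SMT from observations.

    Primary: linear interpolation of the first downward crossing of the
    sulfate threshold (0.5 mM by default; an exact-equality sample
    returns that sampled depth). Fallback when sulfate never reaches the
    threshold: the depth of the steepest downcore alkalinity increase,
    which constrains the SMT only to within ~30 cm.
    """
    depths, so4 = profile.sulfate_observed()
    if so4.size >= 1:
        exact = np.flatnonzero(so4 == sulfate_threshold)
        if exact.size:
            return SmtEstimate(float(depths[exact[0]]), "sulfate-threshold")
        below = np.flatnonzero(so4 < sulfate_threshold)
        if below.size:
            i = int(below[0])
            if i == 0:
                return SmtEstimate(float(depths[0]), "sulfate-threshold")
            frac = (so4[i - 1] - sulfate_threshold) / (so4[i - 1] - so4[i])
            depth = depths[i - 1] + frac * (depths[i] - depths[i - 1])
            return SmtEstimate(float(depth), "sulfate-threshold")
    if profile.alkalinity is not None:
        ok = np.isfinite(profile.alkalinity)
        if ok.sum() >= 3:
            d = profile.depths[ok]
            ta = profile.alkalinity[ok]
            grad = np.diff(ta) / np.diff(d)
            i = int(np.argmax(grad))
            mid = 0.5 * (d[i] + d[i + 1])
            return SmtEstimate(float(mid), "alkalinity-inflection",
                               ALKALINITY_SMT_UNCERTAINTY_CM)
    raise SmtNotCapturedError(
        f"SMT not captured in core {profile.core_id}: sulfate never below "
        f"{sulfate_threshold} mM and no usable alkalinity")


def steepest_sulfate_gradient_depth(profile: PorewaterProfile) -> float:
    """Midpoint depth (cmbsf) of the sampling interval with the most
    negative sulfate gradient; ties go to the shallowest interval.

    Used as the AOM-peak depth proxy for cores that cannot be modelled
    (advective seep settings).
    """
    depths, so4 = profile.sulfate_observed()
    if so4.size < 3:
        raise ValueError("need at least 3 sulfate observations")
    grad = np.diff(so4) / np.diff(depths)
    i = int(np.argmin(grad))  # argmin returns the first (shallowest) tie
    return float(0.5 * (depths[i] + depths[i + 1]))
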