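"""Community diversity statistics tied to the AOM framework.

Shannon diversity of amplicon (ASV) count tables, the signed depth
offset of each sample from the present-day modeled AOM-rate maximum,
linear regressions of diversity against that offset (diversity
collapses toward the front in high-methane-flux settings), and the
assignment of samples to geochemical redox zones (linear sulfate
reduction, nonlinear SR recently impacted by methane, below-SMT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import StateClassification

__all__ = [
    "ASVTable",
    "OffsetRegression",
    "shannon_index",
    "signed_offset",
    "diversity_offset_regression",
    "assign_redox_zone",
]

#: samples with fewer reads than this are dropped before diversity
MIN_READS = 8931

#: default offset window (cm) for the diversity regressions
DEFAULT_WINDOW_CM = (-40.0, 40.0)

ZONE_LINEAR = "linear-SR"
ZONE_NONLINEAR = "nonlinear-SR"
ZONE_BELOW_SMT = "below-SMT"
ZONE_UNZONED = "unzoned"


@dataclass
class OffsetRegression:
    """OLS of Shannon H on signed offset from the AOM peak."""

    group: str
    slope: float            # nats per cm
    intercept: float
    r2: float
    slope_p: float
    n: int
    window: tuple
    offsets: np.ndarray
    shannon: np.ndarray


class ASVTable:
    """Sample-by-taxon count matrix with per-sample metadata.

    ``counts`` is a DataFrame (rows = samples, columns = taxa);
    ``sample_meta`` a DataFrame indexed like counts with at least
    ``core`` and ``depth_cmbsf`` columns (``state`` and ``zone`` labels
    optional). Samples under ``min_reads`` total reads (the blank/low-
    coverage filter) are dropped on construction.
    """

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame,
                 min_reads: int = MIN_READS):
        counts = counts.copy()
        if not counts.index.equals(sample_meta.index):
            missing = counts.index.difference(sample_meta.index)
            if len(missing):
                raise ValueError(f"samples without metadata: {list(missing)[:5]}")
            sample_meta = sample_meta.loc[counts.index]
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        for col in ("core", "depth_cmbsf"):
            if col not in sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")
        keep = counts.sum(axis=1) >= min_reads
        self.n_filtered = int((~keep).sum())
        self.counts = counts.loc[keep]
        self.sample_meta = sample_meta.loc[keep].copy()
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("included samples must have positive read totals")
        self.min_reads = min_reads

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def shannon(self) -> pd.Series:
        """Shannon H (nats) per sample."""
        return self.counts.apply(lambda row: shannon_index(row.to_numpy()),
                                 axis=1)

    @classmethod
    def from_csv(cls, counts_path, meta_path, min_reads: int = MIN_READS):
        counts = pd.read_csv(counts_path, index_col=0)
        meta = pd.read_csv(meta_path, index_col=0)
        return cls(counts, meta, min_reads=min_reads)


def shannon_index(counts) -> float:
    """Shannon-Wiener index H = -sum p_i ln p_i in nats (zero-count taxa
    drop out; single-taxon communities score 0)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("total count must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    return float(stats.entropy(counts))  # natural log, normalizes internally


def signed_offset(sample_depth_cm, peak_aom_depth_cm):
    """Signed distance (cm) of a sample from the AOM-peak depth:
    positive above the peak, negative below."""
    return np.asarray(peak_aom_depth_cm, dtype=float) - \
        np.asarray(sample_depth_cm, dtype=float)


def diversity_offset_regression(table: ASVTable, peak_depths: dict,
                                window=DEFAULT_WINDOW_CM,
                                group_by: str | None = None) -> dict:
    """Per-group OLS of Shannon H against signed offset from the AOM peak.

    ``peak_depths`` maps core id to its present-day AOM-peak depth
    (cmbsf) -- from the reactive-transport model, or from the steepest
    sulfate gradient for seep cores. Samples outside ``window`` (cm,
    relative offset) are excluded; each group (``group_by`` metadata
    column, or all samples pooled under "all") needs >= 3 samples.
    """
    h = table.shannon()
    meta = table.sample_meta
    offsets = signed_offset(
        meta["depth_cmbsf"].to_numpy(),
        meta["core"].map(peak_depths).to_numpy(dtype=float),
    )
    lo, hi = window
    in_win = (offsets >= lo) & (offsets <= hi) & np.isfinite(offsets)
    groups = meta[group_by] if group_by is not None else \
        pd.Series("all", index=meta.index)
    out = {}
    for name, idx in groups.groupby(groups).groups.items():
        mask = in_win & meta.index.isin(idx)
        if mask.sum() < 3:
            raise ValueError(
                f"group {name!r}: {int(mask.sum())} samples inside window "
                f"{window}; need >= 3")
        x = offsets[mask]
        y = h.to_numpy()[mask]
        res = stats.linregress(x, y)
        out[name] = OffsetRegression(
            group=str(name), slope=float(res.slope),
            intercept=float(res.intercept), r2=float(res.rvalue**2),
            slope_p=float(res.pvalue), n=int(mask.sum()),
            window=tuple(window), offsets=x, shannon=y,
        )
    return out


def assign_redox_zone(sample_depth_cm, classification: StateClassification) -> str:
    """Zone a sample by the shape of its core's sulfate profile.

    below-SMT beneath the SMT; nonlinear-SR between the gradient break
    and the SMT for cores with a recent methane impact (increasing or
    transitional states); linear-SR otherwise. Without an SMT the
    sample is "unzoned".
    """
    if classification.smt is None:
        return ZONE_UNZONED
    smt = classification.smt.depth
    if sample_depth_cm > smt:
        return ZONE_BELOW_SMT
    if (classification.label in ("increasing", "transitional")
            and classification.breakpoint_depth is not None
            and sample_depth_cm >= classification.breakpoint_depth):
        return ZONE_NONLINEAR
    return ZONE_LINEAR
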