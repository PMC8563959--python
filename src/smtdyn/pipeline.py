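"""Pipeline orchestration: configuration, staged execution, manifest.

Runs the full coupled analysis over a set of cores: classify each
porewater profile into a methane-dynamics state, date flux increases by
model runtime, report modeled AOM rates/fluxes/SMT depths, derive the
microbial-dynamics quantities from gene-count tables, and run the
diversity-versus-front statistics on ASV tables. All outputs are
CSV/JSON under the configured output directory, with a manifest
carrying the package version, seed and config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .calibrate import PRINTED_TARGETS
from .classify import PorewaterStateModel
from .community import ASVTable, diversity_offset_regression
from .geochem import (
    SmtNotCapturedError,
    read_porewater_table,
    steepest_sulfate_gradient_depth,
)
from .microbes import community_lag, doubling_times_auto, read_gene_table
from .rtm import depth_integrated_aom, smt_depth_model, smt_migration_rate
from .synth import reference_run

logger = logging.getLogger("smtdyn")

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and core names."""

    def __init__(self, stage, core, cause):
        super().__init__(f"stage {stage!r} failed on core {core!r}: {cause}")
        self.stage = stage
        self.core = core


@dataclass
class PipelineConfig:
    """Fully serializable pipeline configuration."""

    porewater_table: str | None = None
    gene_table: str | None = None
    asv_counts: str | None = None
    asv_metadata: str | None = None
    output_dir: str = "smtdyn_out"
    seed: int = 0
    dz_m: float = defaults.GRID_DZ_M
    k_aom: float = defaults.K_AOM
    shoaling_rate_cm_yr: float = 10.0   # front speed for microbial dynamics
    offset_window_cm: tuple = (-40.0, 40.0)
    verbosity: str = "INFO"

    def validate(self):
        for name in ("porewater_table", "gene_table", "asv_counts",
                     "asv_metadata"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if self.porewater_table is None:
            raise ValueError("a porewater table is required")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.offset_window_cm, list):
            cfg.offset_window_cm = tuple(cfg.offset_window_cm)
        return cfg

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _classify_stage(config, outdir):
    df = pd.read_csv(config.porewater_table)
    core_col = next((c for c in df.columns if c.lower() in ("core", "core_id")),
                    None)
    cores = df[core_col].astype(str).unique() if core_col else [None]
    column = defaults.default_column(dz=config.dz_m, k_aom=config.k_aom)
    results = {}
    for core in cores:
        try:
            profile = read_porewater_table(config.porewater_table, core=core)
            model = PorewaterStateModel(profile, column=column)
            results[profile.core_id] = model.fit()
            logger.info("classified core %s as %s", profile.core_id,
                        results[profile.core_id].state)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("classify", core, exc) from exc
    rows = [r.as_dict() for r in results.values()]
    pd.DataFrame(rows).drop(columns=["evidence"]).to_csv(
        outdir / "classification.csv", index=False)
    with open(outdir / "classification.json", "w") as fh:
        json.dump(rows, fh, indent=2, default=str)
    return results


def _model_report_stage(config, results, outdir):
    """Scenario-level AOM/flux/SMT summary for the states present."""
    report = {}
    column = defaults.default_column(dz=config.dz_m, k_aom=config.k_aom)
    states = {r.state for r in results.values()} & {
        "steady", "increasing", "transitional"}
    for state in sorted(states):
        try:
            run = reference_run(state, column=column)
            st = run.states[-1]
            entry = {
                "smt_depth_m": smt_depth_model(st),
                "peak_aom_nmol_cm3_d": float(st.aom_rate_nmol_cm3_d().max()),
                "depth_integrated_aom_mol_m2_yr": depth_integrated_aom(st, column),
            }
            if state == "steady":
                w = defaults.STEADY_LATE_WINDOW_YR
            elif state == "increasing":
                t0 = run.scenario.t_step
                w = (t0 + defaults.INCREASING_WINDOW_YR[0],
                     t0 + defaults.INCREASING_WINDOW_YR[1])
            else:
                t0 = run.scenario.t_step
                w = (t0 + defaults.TRANSITIONAL_WINDOW_YR[0],
                     t0 + defaults.TRANSITIONAL_WINDOW_YR[1])
            entry["smt_shoaling_cm_yr"] = smt_migration_rate(run, *w)
            report[state] = entry
        except Exception as exc:  # noqa: BLE001
            raise StageError("model-report", state, exc) from exc
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _dynamics_stage(config, results, outdir):
    report = {}
    gene_df = pd.read_csv(config.gene_table)
    core_col = next((c for c in gene_df.columns
                     if c.lower() in ("core", "core_id")), None)
    cores = gene_df[core_col].astype(str).unique() if core_col else [None]
    for core in cores:
        try:
            gp = read_gene_table(config.gene_table, core=core)
            res = results.get(gp.core_id)
            entry = {"n_depths": int(gp.depths.size),
                     "n_censored_mcra": int(gp.censored("mcra").sum())}
            v = config.shoaling_rate_cm_yr
            ests = doubling_times_auto(gp, v)
            entry["doubling_days"] = [e.doubling_days for e in ests]
            entry["doubling_intervals_cm"] = [list(e.depth_pair) for e in ests]
            if res is not None and res.smt_depth_cm is not None:
                entry["community_lag_yr"] = community_lag(
                    gp, res.smt_depth_cm, v)
            report[gp.core_id] = entry
            logger.info("microbial dynamics for core %s: %d doubling "
                        "estimates", gp.core_id, len(ests))
        except Exception as exc:  # noqa: BLE001
            raise StageError("dynamics", core, exc) from exc
    with open(outdir / "microbial_dynamics.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _diversity_stage(config, results, outdir):
    try:
        table = ASVTable.from_csv(config.asv_counts, config.asv_metadata)
        peaks = {}
        for core_id, res in results.items():
            if res.state == "seep":
                profile = read_porewater_table(config.porewater_table,
                                               core=core_id)
                peaks[core_id] = steepest_sulfate_gradient_depth(profile)
            elif res.smt_depth_cm is not None:
                peaks[core_id] = res.smt_depth_cm
        for core in table.sample_meta["core"].unique():
            peaks.setdefault(core, np.nan)
        group_col = "state" if "state" in table.sample_meta.columns else None
        regs = diversity_offset_regression(
            table, peaks, window=config.offset_window_cm, group_by=group_col)
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", "all", exc) from exc
    out = {g: {"slope_nats_cm": r.slope, "r2": r.r2, "slope_p": r.slope_p,
               "n": r.n, "window_cm": list(r.window)}
           for g, r in regs.items()}
    with open(outdir / "diversity.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; returns the output bundle paths.

    Stages: classification (always) -> scenario model report ->
    microbial dynamics (if a gene table is configured) -> diversity
    (if ASV tables are configured). A missing optional input skips its
    stage with a logged warning; any stage *failure* aborts with the
    stage and core named.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = {"output_dir": str(outdir)}
    results = _classify_stage(config, outdir)
    bundle["classification"] = str(outdir / "classification.json")
    _model_report_stage(config, results, outdir)
    bundle["model_report"] = str(outdir / "model_report.json")

    if config.gene_table:
        _dynamics_stage(config, results, outdir)
        bundle["microbial_dynamics"] = str(outdir / "microbial_dynamics.json")
    else:
        logger.warning("no gene-count table configured; skipping the "
                       "microbial-dynamics stage")
    if config.asv_counts and config.asv_metadata:
        _diversity_stage(config, results, outdir)
        bundle["diversity"] = str(outdir / "diversity.json")
    else:
        logger.warning("no ASV tables configured; skipping the diversity stage")

    from . import __version__

    manifest = {
        "package": "smtdyn",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("classify", "dynamics", "diversity")},
        "config_hash": config.content_hash(),
        "config": asdict(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": bundle,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = str(outdir / "manifest.json")
    return bundle
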