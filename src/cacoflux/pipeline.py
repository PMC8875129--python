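"""End-to-end orchestration: simulate datasets, analyze them, reproduce
the published tables.

These functions are the library-level equivalents of the CLI
subcommands: each takes a :class:`~cacoflux.config.RunConfig`, reads or
writes the tidy CSV dialects of :mod:`cacoflux.io`, and returns the
in-memory results so scripted use never has to shell out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as cio
from .calibration import fit_calibration, qc_stats
from .compare import build_report, effect_report
from .config import RunConfig
from .published import reproduce_percent_changes, reproduce_printed_ers
from .simdata import generate_standards, simulate_condition
from .transport import analyze_well, summarize_group

__all__ = ["run_simulate", "run_analyze", "run_reproduce_tables", "run_qc"]

log = logging.getLogger("cacoflux")


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: RunConfig, with_standards: bool = False) -> dict[str, Path]:
    """Simulate the configured condition and write the dataset files.

    Writes the wells CSV, a truth sidecar with the exact noiseless
    trajectories, a manifest recording the seed and parameters, and
    (optionally) a calibration-standards CSV generated from a default
    linear truth. Returns the written paths.
    """
    sim = config.simulation
    out = _outdir(config)
    ds = simulate_condition(sim.params, sim.schedule, sim.c0_list,
                            sim.n_wells, sim.seed, compound=sim.compound)
    paths = {"wells": out / "wells.csv", "truth": out / "truth.csv",
             "manifest": out / "manifest.json"}
    cio.write_wells_csv(ds.wells, paths["wells"])
    cio.write_frame(ds.truth_frame(), paths["truth"])
    manifest = {"seed": sim.seed, "n_wells": sim.n_wells,
                "c0_list": list(sim.c0_list), "compound": sim.compound,
                "params": asdict(sim.params),
                "schedule": {"times": list(sim.schedule.times),
                             "vs": sim.schedule.vs}}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True),
                                 encoding="utf-8")
    if with_standards:
        std = generate_standards(slope=1.8823, intercept=0.07998,
                                 noise_cv=sim.params.noise_cv, seed=sim.seed,
                                 analyte=sim.compound)
        paths["standards"] = out / "standards.csv"
        cio.write_frame(std, paths["standards"])
    log.info("simulated %d wells (seed=%s) -> %s", len(ds.wells), sim.seed, out)
    return paths


def run_analyze(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Analyze a wells CSV end to end and write the report files.

    Per well: dilution-corrected cumulative amounts, rate fit over the
    configured window, Papp. Per condition: mean +/- SD Papp by
    direction, ratio-of-means ER, mechanism label. Pairwise effects are
    computed against the first condition (in file order) as baseline
    when more than one condition is present. Optional inputs add a
    calibration report (standards CSV) and a TEER report (resistance
    CSV). Identical inputs produce byte-identical outputs.
    """
    if not config.wells_csv:
        raise ValueError("run_analyze: wells_csv is required")
    out = _outdir(config)
    wells = cio.read_wells_csv(config.wells_csv)
    log.info("analyzing %d wells; window=%s er_threshold=%g",
             len(wells), config.window or "all points", config.er_threshold)

    results = [analyze_well(w, config.window) for w in wells]
    per_well = pd.DataFrame([{
        "well_id": r.well.well_id, "condition": r.well.condition or "",
        "compound": r.well.compound, "direction": r.well.direction,
        "c0_ug_per_ml": r.well.c0, "rate_ug_per_s": r.rate,
        "rate_r2": r.rate_r2, "papp_e6_cm_per_s": r.papp_e6,
    } for r in results])

    order, by_cond = [], {}
    for r in results:
        key = r.well.condition or "all"
        if key not in by_cond:
            by_cond[key] = []
            order.append(key)
        by_cond[key].append(r)
    summaries = [summarize_group(by_cond[k], condition=k,
                                 er_threshold=config.er_threshold)
                 for k in order]
    effects = []
    if len(summaries) > 1:
        base = summaries[0]
        effects = [effect_report(base, s, config.alpha, config.test)
                   for s in summaries[1:]]
    groups_df, effects_df = build_report(summaries, effects)

    frames = {"per_well": per_well, "groups": groups_df, "effects": effects_df}
    if config.standards_csv:
        std = cio.read_standards_csv(config.standards_csv)
        curve = fit_calibration(std, split_at=config.calibration_split)
        frames["calibration"] = pd.DataFrame([{
            "analyte": curve.analyte, "segment": i, "lo": s.lo, "hi": s.hi,
            "slope": s.slope, "intercept": s.intercept, "r": s.r,
            "lloq": curve.lloq,
        } for i, s in enumerate(curve.segments)])
    if config.resistance_csv:
        records = cio.read_resistance_csv(config.resistance_csv)
        frames["teer"] = pd.DataFrame([{
            "well_id": t.well_id, "r1_ohm": t.r1, "r0_ohm": t.r0,
            "area_cm2": t.area, "teer_ohm_cm2": t.teer, "context": t.context,
            "flagged": t.teer < config.teer_threshold,
        } for t in records])

    for name, df in frames.items():
        cio.write_frame(df, out / f"{name}.csv")
    return frames


def run_reproduce_tables(out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Recompute the published ratio-of-means ERs and percent changes.

    Emits a pass/fail row per published group (with the one documented
    rounding exception) and per percent-change statement; optionally
    writes both tables as CSV.
    """
    frames = {"printed_ers": reproduce_printed_ers(),
              "percent_changes": reproduce_percent_changes()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            cio.write_frame(df, out / f"{name}.csv")
    return frames


def run_qc(standards_csv: str | Path, qc_csv: str | Path | None = None,
           split_at: float | None = None,
           out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Calibration fit and (optionally) QC precision/recovery statistics.

    ``qc_csv`` needs columns ``level``, ``measured`` and optionally
    ``day`` (measured = back-calculated concentration, ug/mL).
    """
    std = cio.read_standards_csv(standards_csv)
    curve = fit_calibration(std, split_at=split_at)
    frames = {"calibration": pd.DataFrame([{
        "analyte": curve.analyte, "segment": i, "lo": s.lo, "hi": s.hi,
        "slope": s.slope, "intercept": s.intercept, "r": s.r,
        "lloq": curve.lloq,
    } for i, s in enumerate(curve.segments)])}
    if qc_csv is not None:
        qc = pd.read_csv(qc_csv)
        frames["qc"] = qc_stats(qc).reset_index()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            cio.write_frame(df, out / f"{name}.csv")
    return frames
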