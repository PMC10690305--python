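"""End-to-end pipeline driver.

Stages: simulate (or read) -> flag/clean -> adjudicate -> cadence
summaries -> regularize -> competing-risk incidence -> backward
trajectory estimation -> figures. Every stage writes a machine-readable
CSV; a JSON-lines run log records the seed, row counts and every design
setting in force. Identical config + seed reproduces identical tables.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .backward import (
    align_backward,
    attach_weights,
    backward_estimate,
    backward_scatter,
    forward_scatter,
    ipcw_weights,
)
from .cleaning import apply_flag_policy, availability_matrix, flag_outliers, summarize_gaps
from .cohort import Cohort, adjudicate_outcomes, read_cohort, write_cohort
from .config import PGS4, PipelineConfig
from .incidence import aalen_johansen, censoring_km, cif_at
from .regularize import build_panel, panel_to_long
from .simulate import simulate_cohort


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


def _stage(log, name, fn, *args, **kwargs):
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    log(name)
    return out


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages; returns the output directory."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    fig_dir = os.path.join(outdir, "figures")
    if config.make_figures:
        os.makedirs(fig_dir, exist_ok=True)
    log_path = os.path.join(outdir, "run_log.jsonl")
    log_fh = open(log_path, "w")

    def log(stage: str, **extra) -> None:
        rec = {"stage": stage, **extra}
        log_fh.write(json.dumps(rec, default=str) + "\n")

    log(
        "config",
        version=__version__,
        seed=config.seed,
        flag_policy=config.flag_policy,
        min_n=config.min_n,
        death_as_censoring=config.death_as_censoring,
        horizon_h=config.horizon_h,
        window_h=config.window_h,
        outcomes=list(config.outcomes),
        variables=list(config.variables),
        sim=asdict(config.sim) if config.input_dir is None else None,
        input_dir=config.input_dir,
    )

    try:
        # --- acquire cohort ----------------------------------------------
        if config.input_dir is not None:
            cohort = _stage(lambda s: log(s), "read", read_cohort, config.input_dir)
            truth = None
        else:
            sim = config.sim
            sim.seed = config.seed
            cohort, truth = _stage(lambda s: None, "simulate", simulate_cohort, sim)
            write_cohort(cohort, os.path.join(outdir, "cohort"))
            truth.to_csv(os.path.join(outdir, "cohort", "truth.csv"), index=False)
            log("simulate", n_patients=len(cohort.patients), n_measurements=len(cohort.measurements))

        # --- cleaning ----------------------------------------------------
        flags = flag_outliers(cohort.measurements)
        cleaned, clean_report = apply_flag_policy(cohort.measurements, flags, config.flag_policy)
        flags.to_csv(os.path.join(outdir, "flags.csv"), index_label="row")
        cohort = Cohort(cohort.patients, cleaned.reset_index(drop=True), cohort.procedures)
        log("clean", **clean_report, n_flagged=int(flags["flagged"].sum()))

        # --- adjudication ------------------------------------------------
        records = {}
        for outcome in config.outcomes:
            rec = _stage(
                lambda s: None, f"adjudicate:{outcome}",
                adjudicate_outcomes, cohort, outcome, config.horizon_h,
            )
            records[outcome] = rec
            log(f"adjudicate:{outcome}",
                n_events=int((rec["status"] == 1).sum()),
                n_deaths=int((rec["status"] == 2).sum()),
                n_censored=int((rec["status"] == 0).sum()))
        pd.concat(records.values(), ignore_index=True).to_csv(
            os.path.join(outdir, "events.csv"), index=False
        )

        # --- cadence summary ---------------------------------------------
        gaps = summarize_gaps(cohort.measurements)
        gaps.to_csv(os.path.join(outdir, "gaps.csv"), index=False)
        log("gaps", n_variables=len(gaps))

        # --- incidence ---------------------------------------------------
        cif_frames, cif_eval = [], []
        for outcome in config.outcomes:
            est = _stage(lambda s: None, f"incidence:{outcome}", aalen_johansen, records[outcome])
            frame = est.to_frame()
            frame.insert(0, "outcome", outcome)
            cif_frames.append(frame)
            ev = cif_at(est, [24.0, 48.0, 72.0])
            ev.insert(0, "outcome", outcome)
            cif_eval.append(ev)
            log(f"incidence:{outcome}", n_jumps=len(est.times))
        pd.concat(cif_frames, ignore_index=True).to_csv(os.path.join(outdir, "cif.csv"), index=False)
        pd.concat(cif_eval, ignore_index=True).to_csv(
            os.path.join(outdir, "cif_at_times.csv"), index=False
        )

        # --- regularize + backward estimation ----------------------------
        ids = cohort.patients["patient_id"].to_numpy()
        backward_frames = []
        hourly_frames = []
        s_max = int(config.window_h)
        for outcome in config.outcomes:
            rec = records[outcome]
            G = censoring_km(rec, death_as_censoring=config.death_as_censoring)
            weights = ipcw_weights(rec, G)
            end_h = pd.Series(rec["X_h"].to_numpy(), index=rec["patient_id"].to_numpy())
            variables = list(config.variables)
            if outcome == PGS4 and "mls" in cohort.variables():
                variables = variables + ["mls"]  # MLS as exposure for the PGS outcome
            for var in variables:
                spec = config.sim.variable_specs[var]
                panel = build_panel(
                    cohort.measurements, spec, ids, config.horizon_h, end_h=end_h
                )
                if outcome == config.outcomes[0]:
                    hourly_frames.append(panel_to_long(panel))
                aligned = attach_weights(align_backward(panel, rec, s_max), weights)
                est = backward_estimate(aligned, min_n=config.min_n)
                est.insert(0, "variable", var)
                est.insert(0, "outcome", outcome)
                backward_frames.append(est)
            log(f"backward:{outcome}", n_cases=int((rec["status"] == 1).sum()))
        backward_tbl = pd.concat(backward_frames, ignore_index=True)
        backward_tbl.to_csv(os.path.join(outdir, "backward.csv"), index=False)
        pd.concat(hourly_frames, ignore_index=True).to_csv(
            os.path.join(outdir, "hourly.csv"), index=False
        )

        # --- scatter tables ----------------------------------------------
        first_outcome = config.outcomes[0]
        scatter_var = config.variables[0]
        fwd = forward_scatter(
            cohort.measurements, records[first_outcome], scatter_var, config.horizon_h
        )
        bwd = backward_scatter(
            cohort.measurements, records[first_outcome], scatter_var, config.window_h
        )
        fwd.to_csv(os.path.join(outdir, "forward_scatter.csv"), index=False)
        bwd.to_csv(os.path.join(outdir, "backward_scatter.csv"), index=False)
        log("scatter", forward_rows=len(fwd), backward_rows=len(bwd))

        # --- figures ------------------------------------------------------
        if config.make_figures:
            from . import viz

            for outcome in config.outcomes:
                sub = backward_tbl[backward_tbl["outcome"] == outcome]
                viz.plot_backward_bands(
                    sub, outcome, os.path.join(fig_dir, f"backward_{outcome}.png")
                )
            viz.plot_scatter(
                fwd, "time_h", scatter_var, backward=False,
                path=os.path.join(fig_dir, f"forward_scatter_{scatter_var}.png"),
            )
            viz.plot_scatter(
                bwd, "lag_h", scatter_var, backward=True,
                path=os.path.join(fig_dir, f"backward_scatter_{scatter_var}.png"),
            )
            avail = availability_matrix(
                cohort.measurements[cohort.measurements["variable"] == scatter_var],
                config.sim.variable_specs[scatter_var].grid_step_h,
                config.horizon_h,
                patient_ids=list(ids),
            )
            viz.plot_availability(
                avail, scatter_var, os.path.join(fig_dir, f"availability_{scatter_var}.png")
            )
            pid = str(ids[0])
            viz.plot_individual(
                cohort, pid, list(config.variables),
                pd.concat(records.values(), ignore_index=True),
                os.path.join(fig_dir, f"individual_{pid}.png"),
            )
            log("figures", fig_dir=fig_dir)
        log("done")
    finally:
        log_fh.close()
    return outdir
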