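"""Tidy cohort data model, CSV round-trip, baseline extraction and
outcome adjudication.

A cohort is three linked tables:

* ``patients``: one row per patient with ``patient_id``, nullable
  ``death_h`` / ``discharge_h`` (hours from admission) and baseline
  covariates;
* ``measurements``: long table ``(patient_id, variable, time_h, value,
  source)`` holding labs, vitals and radiographic scan series (variables
  ``mls`` and ``pgs``);
* ``procedures``: ``(patient_id, procedure, time_h)``, currently only
  decompressive hemicraniectomy (``dhc``).

Outcomes are adjudicated per patient against a 192 h horizon: first scan
with MLS >= 5 mm, first scan with PGS > 4 mm (strict), or DHC; death is a
competing event (status 2) and radiographic crossings occurring after DHC
are censored at the DHC time (censor_reason ``dhc_precedence``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DHC, HORIZON_H, MLS5, OUTCOMES, PGS4

PATIENT_COLUMNS = ["patient_id", "death_h", "discharge_h"]
MEASUREMENT_COLUMNS = ["patient_id", "variable", "time_h", "value", "source"]
PROCEDURE_COLUMNS = ["patient_id", "procedure", "time_h"]

STATUS_CENSORED = 0
STATUS_EVENT = 1
STATUS_DEATH = 2

#: which measurement variable and threshold define each radiographic outcome;
#: MLS uses an inclusive threshold, PGS a strict one.
_RADIOGRAPHIC_RULES = {MLS5: ("mls", 5.0, "ge"), PGS4: ("pgs", 4.0, "gt")}


class CohortValidationError(ValueError):
    """Schema or invariant violation, with row-level context."""


@dataclass
class Cohort:
    """Linked patients / measurements / procedures tables."""

    patients: pd.DataFrame
    measurements: pd.DataFrame
    procedures: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PROCEDURE_COLUMNS)
    )

    def validate(self) -> "Cohort":
        p, m, pr = self.patients, self.measurements, self.procedures
        for tbl, cols, name in (
            (p, PATIENT_COLUMNS, "patients"),
            (m, MEASUREMENT_COLUMNS, "measurements"),
            (pr, PROCEDURE_COLUMNS, "procedures"),
        ):
            missing = [c for c in cols if c not in tbl.columns]
            if missing:
                raise CohortValidationError(f"{name}: missing columns {missing}")
        if p["patient_id"].duplicated().any():
            dup = p.loc[p["patient_id"].duplicated(), "patient_id"].tolist()
            raise CohortValidationError(f"patients: duplicate patient_id {dup}")
        known = set(p["patient_id"])
        for tbl, name in ((m, "measurements"), (pr, "procedures")):
            if len(tbl):
                orphan = ~tbl["patient_id"].isin(known)
                if orphan.any():
                    raise CohortValidationError(
                        f"{name}: unknown patient_id at rows {list(tbl.index[orphan][:10])}"
                    )
        if len(m):
            t = pd.to_numeric(m["time_h"], errors="coerce")
            bad = ~np.isfinite(t) | (t < 0)
            if bad.any():
                raise CohortValidationError(
                    f"measurements: non-finite or negative time_h at rows "
                    f"{list(m.index[bad][:10])}"
                )
            end = p.set_index("patient_id")[["death_h", "discharge_h"]].min(axis=1)
            lim = m["patient_id"].map(end)
            late = lim.notna() & (t > lim + 1e-9)
            if late.any():
                raise CohortValidationError(
                    f"measurements: rows after death/discharge at rows "
                    f"{list(m.index[late][:10])}"
                )
        return self

    def variables(self) -> list[str]:
        return sorted(self.measurements["variable"].unique())


def _paths(directory: str) -> dict[str, str]:
    return {
        "patients": os.path.join(directory, "patients.csv"),
        "measurements": os.path.join(directory, "measurements.csv"),
        "procedures": os.path.join(directory, "procedures.csv"),
    }


def write_cohort(cohort: Cohort, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    paths = _paths(directory)
    cohort.patients.to_csv(paths["patients"], index=False)
    cohort.measurements.to_csv(paths["measurements"], index=False)
    cohort.procedures.to_csv(paths["procedures"], index=False)


def read_cohort(directory: str) -> Cohort:
    paths = _paths(directory)
    patients = pd.read_csv(paths["patients"])
    measurements = pd.read_csv(
        paths["measurements"],
        dtype={"patient_id": str, "variable": str, "source": str},
    )
    if os.path.exists(paths["procedures"]):
        procedures = pd.read_csv(paths["procedures"], dtype={"patient_id": str})
    else:
        procedures = pd.DataFrame(columns=PROCEDURE_COLUMNS)
    patients["patient_id"] = patients["patient_id"].astype(str)
    return Cohort(patients, measurements, procedures).validate()


def compute_mls(lateral_mm: float, medial_mm: float) -> float:
    """Midline shift as the average of the lateral and medial boundary
    displacements (mm)."""
    lateral = np.asarray(lateral_mm, dtype=float)
    medial = np.asarray(medial_mm, dtype=float)
    if np.any(lateral < 0) or np.any(medial < 0):
        raise ValueError("boundary displacements must be >= 0 mm")
    out = (lateral + medial) / 2.0
    return float(out) if out.ndim == 0 else out


def baseline_value(
    measurements: pd.DataFrame,
    variable: str,
    origin_h: float = 0.0,
    before_h: float = 8.0,
    after_h: float = 36.0,
) -> float:
    """Baseline = value closest in time to the origin within the window
    [origin - 8 h, origin + 36 h]; NaN when no measurement qualifies."""
    sub = measurements[measurements["variable"] == variable]
    if not len(sub):
        return float("nan")
    t = sub["time_h"].to_numpy(dtype=float)
    in_win = (t >= origin_h - before_h) & (t <= origin_h + after_h)
    if not in_win.any():
        return float("nan")
    tw = t[in_win]
    vw = sub["value"].to_numpy(dtype=float)[in_win]
    order = np.lexsort((tw, np.abs(tw - origin_h)))
    return float(vw[order[0]])


def baseline_table(cohort: Cohort, variables: list[str], origin_h: float = 0.0) -> pd.DataFrame:
    """Per-patient baseline values for the listed variables."""
    rows = []
    for pid, grp in cohort.measurements.groupby("patient_id", sort=True):
        row = {"patient_id": pid}
        for v in variables:
            row[v] = baseline_value(grp, v, origin_h)
        rows.append(row)
    out = pd.DataFrame(rows, columns=["patient_id", *variables])
    all_ids = cohort.patients[["patient_id"]]
    return all_ids.merge(out, on="patient_id", how="left")


def _first_crossing(scans: pd.DataFrame, threshold: float, mode: str) -> float:
    """Time of the first qualifying scan, NaN if never; NaN-valued scans
    are skipped."""
    if not len(scans):
        return float("nan")
    t = scans["time_h"].to_numpy(dtype=float)
    v = scans["value"].to_numpy(dtype=float)
    ok = np.isfinite(v)
    t, v = t[ok], v[ok]
    hit = v >= threshold if mode == "ge" else v > threshold
    if not hit.any():
        return float("nan")
    return float(t[hit].min())


def adjudicate_outcomes(
    cohort: Cohort, outcome: str, horizon_h: float = HORIZON_H
) -> pd.DataFrame:
    """One event record per patient for ``outcome``.

    Returns a DataFrame (patient_id, outcome, X_h, status, censor_reason)
    with status 1 = event, 2 = death before the event, 0 = censored
    (discharge, horizon, or DHC preceding a radiographic crossing).
    Ties at equal timestamps resolve event > death > DHC > discharge.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    meas = cohort.measurements
    dhc_times = (
        cohort.procedures[cohort.procedures["procedure"] == "dhc"]
        .groupby("patient_id")["time_h"]
        .min()
    )
    pat = cohort.patients.set_index("patient_id")
    bad = dhc_times.index[
        dhc_times > pat.reindex(dhc_times.index)["death_h"].fillna(np.inf)
    ]
    if len(bad):
        raise CohortValidationError(f"DHC after death for patients {list(bad)}")

    if outcome in _RADIOGRAPHIC_RULES:
        var, thr, mode = _RADIOGRAPHIC_RULES[outcome]
        scans = meas[meas["variable"] == var]
        cross = scans.groupby("patient_id").apply(
            lambda g: _first_crossing(g, thr, mode), include_groups=False
        )
    else:
        cross = dhc_times

    records = []
    for pid in cohort.patients["patient_id"]:
        e_t = float(cross.get(pid, np.nan))
        death = float(pat.at[pid, "death_h"]) if pd.notna(pat.at[pid, "death_h"]) else np.nan
        disch = (
            float(pat.at[pid, "discharge_h"]) if pd.notna(pat.at[pid, "discharge_h"]) else np.nan
        )
        dhc_t = float(dhc_times.get(pid, np.nan))

        # candidate (time, status, reason) triples, in tie-break priority order
        cands: list[tuple[float, int, str]] = []
        if np.isfinite(e_t):
            cands.append((e_t, STATUS_EVENT, "none"))
        if np.isfinite(death):
            cands.append((death, STATUS_DEATH, "none"))
        if outcome != DHC and np.isfinite(dhc_t):
            cands.append((dhc_t, STATUS_CENSORED, "dhc_precedence"))
        if np.isfinite(disch):
            cands.append((disch, STATUS_CENSORED, "discharge"))
        cands.append((np.inf, STATUS_CENSORED, "horizon"))

        best = min(enumerate(cands), key=lambda ic: (ic[1][0], ic[0]))[1]
        x, status, reason = best
        if x > horizon_h:
            x, status, reason = horizon_h, STATUS_CENSORED, "horizon"
        records.append(
            {
                "patient_id": pid,
                "outcome": outcome,
                "X_h": float(x),
                "status": int(status),
                "censor_reason": reason,
            }
        )
    out = pd.DataFrame(records, columns=["patient_id", "outcome", "X_h", "status", "censor_reason"])
    return out


def adjudicate_all(cohort: Cohort, horizon_h: float = HORIZON_H) -> pd.DataFrame:
    """Event records for every outcome, concatenated."""
    return pd.concat(
        [adjudicate_outcomes(cohort, o, horizon_h) for o in OUTCOMES], ignore_index=True
    )
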