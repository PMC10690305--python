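"""Erroneous-measurement flagging, rater agreement and cadence summaries.

Flagging rule: a measurement is flagged when its absolute Z-score against
the pooled full-cohort distribution of its variable is >= 3 (inclusive),
or when it changes by >= 25% from the immediately preceding same-variable
value within the same patient. The 25%-change rule is not applied to
radiographic series, whose between-scan change is legitimately large.
Removal is a separate, opt-in policy; the default annotates only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import RADIOGRAPHIC_VARIABLES

Z_THRESHOLD = 3.0
REL_CHANGE_THRESHOLD = 0.25


def flag_outliers(
    measurements: pd.DataFrame,
    rel_change_exempt: frozenset[str] | set[str] = RADIOGRAPHIC_VARIABLES,
    z_threshold: float = Z_THRESHOLD,
    rel_threshold: float = REL_CHANGE_THRESHOLD,
) -> pd.DataFrame:
    """Flag table aligned to ``measurements`` (same index).

    Columns: ``z_score`` (pooled per-variable standardization; NaN when the
    variable's cohort SD is zero or undefined), ``rel_change`` (absolute
    relative change vs the preceding same-variable value within patient;
    NaN for first values and zero predecessors), ``flagged``, ``removed``
    (always False here; set by :func:`apply_flag_policy`).
    """
    m = measurements
    z = pd.Series(np.nan, index=m.index, dtype=float)
    rel = pd.Series(np.nan, index=m.index, dtype=float)

    values = pd.to_numeric(m["value"], errors="coerce")
    for var, idx in m.groupby("variable").groups.items():
        v = values.loc[idx]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            if len(idx) > 1:
                warnings.warn(f"variable {var!r}: zero/undefined cohort SD; Z rule skipped")
            continue
        z.loc[idx] = (v - v.mean()) / sd

    order = m.sort_values(["patient_id", "variable", "time_h"], kind="mergesort").index
    vo = values.loc[order]
    key = m.loc[order, "patient_id"].astype(str) + "\x00" + m.loc[order, "variable"].astype(str)
    prev = vo.shift(1)
    prev[key != key.shift(1)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vo - prev).abs() / prev.abs()
    r[prev == 0] = np.nan
    rel.loc[order] = r

    flagged = (z.abs() >= z_threshold).fillna(False)
    rel_ok = ~m["variable"].isin(rel_change_exempt)
    flagged |= (rel >= rel_threshold).fillna(False) & rel_ok
    return pd.DataFrame(
        {"z_score": z, "rel_change": rel, "flagged": flagged, "removed": False},
        index=m.index,
    )


def apply_flag_policy(
    measurements: pd.DataFrame, flags: pd.DataFrame, policy: str = "flag_only"
) -> tuple[pd.DataFrame, dict]:
    """Apply ``flag_only`` (annotate, keep everything) or ``drop_flagged``.

    Returns (measurements, report) where report gives the number and
    fraction of rows removed. ``drop_flagged`` removes exactly the flagged
    rows and marks them ``removed`` in ``flags`` (in place).
    """
    if not flags.index.equals(measurements.index):
        raise ValueError("flags are not aligned to measurements")
    n = len(measurements)
    if policy == "flag_only":
        report = {"policy": policy, "n_rows": n, "n_removed": 0, "fraction_removed": 0.0}
        return measurements, report
    if policy != "drop_flagged":
        raise ValueError(f"unknown policy {policy!r}")
    keep = ~flags["flagged"]
    flags.loc[~keep, "removed"] = True
    removed = int((~keep).sum())
    report = {
        "policy": policy,
        "n_rows": n,
        "n_removed": removed,
        "fraction_removed": removed / n if n else 0.0,
    }
    return measurements.loc[keep].copy(), report


def percent_agreement(ratings_a, ratings_b) -> float:
    """Percentage of exact categorical matches between two raters."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty rating vectors")
    return float(np.mean(a == b) * 100.0)


def mean_abs_error(values_a, values_b) -> float:
    """Mean absolute difference between paired continuous readings."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty value vectors")
    return float(np.mean(np.abs(a - b)))


def summarize_gaps(
    measurements: pd.DataFrame, restrict_before: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Median [q25, q75] inter-measurement gap in hours, per variable.

    Gaps are between consecutive same-variable measurements within a
    patient; patients with fewer than two measurements contribute nothing.
    With ``restrict_before`` (an event-record table with one row per
    patient), only gaps whose later endpoint falls at or before the
    patient's observed time X_h are pooled.
    """
    m = measurements.sort_values(["patient_id", "variable", "time_h"], kind="mergesort")
    key = m["patient_id"].astype(str) + "\x00" + m["variable"].astype(str)
    gap = m["time_h"].diff()
    gap[key != key.shift(1)] = np.nan
    keep = gap.notna()
    if restrict_before is not None:
        x = restrict_before.set_index("patient_id")["X_h"]
        keep &= m["time_h"] <= m["patient_id"].map(x)
    g = m.loc[keep]
    gaps = gap.loc[keep]
    rows = []
    for var, idx in g.groupby("variable").groups.items():
        arr = gaps.loc[idx].to_numpy(dtype=float)
        rows.append(
            {
                "variable": var,
                "n_gaps": len(arr),
                "median_h": float(np.median(arr)),
                "q25_h": float(np.quantile(arr, 0.25)),
                "q75_h": float(np.quantile(arr, 0.75)),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "n_gaps", "median_h", "q25_h", "q75_h"])


def availability_matrix(
    measurements: pd.DataFrame,
    grid_step_h: int,
    horizon_h: float = 192.0,
    patient_ids: list | None = None,
) -> pd.DataFrame:
    """Patient x time-bin boolean presence matrix; bin k covers
    [k*step, (k+1)*step) hours."""
    n_bins = int(np.ceil(horizon_h / grid_step_h))
    edges = np.arange(n_bins) * grid_step_h
    if patient_ids is None:
        patient_ids = sorted(measurements["patient_id"].unique())
    mat = pd.DataFrame(False, index=pd.Index(patient_ids, name="patient_id"), columns=edges)
    sub = measurements[measurements["time_h"] < horizon_h]
    if len(sub):
        bins = (sub["time_h"].to_numpy(dtype=float) // grid_step_h).astype(int)
        ridx = mat.index.get_indexer(sub["patient_id"])
        ok = ridx >= 0
        mat.values[ridx[ok], bins[ok]] = True
    return mat
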