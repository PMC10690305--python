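"""Event-aligned backward-looking trajectory estimation.

Cases are aligned at their outcome time and the distribution of each
hourly-interpolated marker is summarized at backward lags s = 0..72 h
before the event. Right-censoring (discharge, horizon, and — under the
default convention — death before the outcome) selects cases with early
events; inverse-probability-of-censoring weights w_i = 1 / Ĝ(X_i-),
with Ĝ the Kaplan-Meier censoring survival, undo that selection so that
the weighted mean and quantile trajectories estimate the marker
distribution at each lag among patients whose outcome occurs within the
horizon. With no censoring, every estimate reduces exactly to the plain
case-only statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import STATUS_EVENT
from .incidence import CensoringSurvival
from .regularize import HourlyPanel

DEFAULT_S_MAX = 72
DEFAULT_MIN_N = 5


class PositivityError(ValueError):
    """Ĝ(X-) = 0 for an event case: the censoring weight is undefined."""


@dataclass
class AlignedMatrix:
    """Cases x backward-lags value matrix.

    ``values[i, s]`` is case i's hourly value at hour round(X_i) - s
    (NaN when that hour is negative or outside the patient's observed
    series span); column s = 0 aligns to the outcome time.
    """

    variable: str
    case_ids: np.ndarray
    event_times: np.ndarray     # X_i, hours
    values: np.ndarray          # (n_cases, s_max + 1)
    weights: np.ndarray | None = None

    @property
    def s_max(self) -> int:
        return self.values.shape[1] - 1

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def align_backward(
    panel: HourlyPanel, records: pd.DataFrame, s_max: int = DEFAULT_S_MAX
) -> AlignedMatrix:
    """Align hourly series of event cases at the outcome time.

    ``records`` is an event-record table; only status 1 rows become rows
    of the matrix (one per case, even when the patient has no series for
    this variable — such rows stay all-missing and count in diagnostics).
    """
    cases = records[records["status"] == STATUS_EVENT]
    case_ids = cases["patient_id"].to_numpy()
    x = cases["X_h"].to_numpy(dtype=float)
    n = len(case_ids)
    values = np.full((n, s_max + 1), np.nan)
    ridx = pd.Index(panel.patient_ids).get_indexer(case_ids)
    have = ridx >= 0
    if have.any():
        xh = _round_half_up(x[have])
        lags = np.arange(s_max + 1)
        hours = xh[:, None] - lags[None, :]          # (n_have, s_max+1)
        valid = (hours >= 0) & (hours < panel.n_hours)
        rows = np.broadcast_to(ridx[have][:, None], hours.shape)
        vals = np.full(hours.shape, np.nan)
        vals[valid] = panel.values[rows[valid], hours[valid]]
        values[have] = vals
    return AlignedMatrix(panel.variable, case_ids, x, values)


def ipcw_weights(records: pd.DataFrame, G: CensoringSurvival) -> pd.Series:
    """Normalized inverse-probability-of-censoring weights.

    Event cases get w_i proportional to 1 / Ĝ(X_i-); all other patients
    get weight 0 (they contribute through Ĝ). Weights sum to 1 over
    cases. Raises :class:`PositivityError` when Ĝ(X_i-) = 0 for a case.
    """
    status = records["status"].to_numpy(dtype=int)
    x = records["X_h"].to_numpy(dtype=float)
    w = np.zeros(len(records))
    is_case = status == STATUS_EVENT
    if is_case.any():
        g = G.at_minus(x[is_case])
        if np.any(g <= 0):
            bad = records["patient_id"].to_numpy()[is_case][g <= 0]
            raise PositivityError(
                f"censoring survival is zero at the event time of patients {list(bad[:5])}"
            )
        w[is_case] = 1.0 / g
        w /= w.sum()
    return pd.Series(w, index=records["patient_id"].to_numpy(), name="weight")


def attach_weights(aligned: AlignedMatrix, weights: pd.Series) -> AlignedMatrix:
    """Attach per-case weights (indexed by patient_id) to an aligned matrix."""
    aligned.weights = weights.reindex(aligned.case_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(aligned.weights)):
        raise ValueError("weights missing for some cases")
    return aligned


def weighted_quantile(values, weights, q: float) -> float:
    """Left-continuous inverse of the weighted empirical CDF: the smallest
    value whose cumulative normalized weight reaches q."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = np.isfinite(v) & (w > 0)
    v, w = v[keep], w[keep]
    if v.size == 0:
        return float("nan")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(v[min(idx, len(v) - 1)])


def _column_stats(col: np.ndarray, w: np.ndarray, quantiles=(0.25, 0.5, 0.75)):
    avail = np.isfinite(col)
    n_eff = int(avail.sum())
    if n_eff == 0:
        return n_eff, np.nan, [np.nan] * len(quantiles)
    ws = w[avail]
    tot = ws.sum()
    if tot <= 0:
        return n_eff, np.nan, [np.nan] * len(quantiles)
    ws = ws / tot
    vals = col[avail]
    mean = float(np.sum(ws * vals))
    qs = [weighted_quantile(vals, ws, q) for q in quantiles]
    return n_eff, mean, qs


def backward_mean(aligned: AlignedMatrix, min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Weighted mean trajectory μ̂(s); weights renormalized per lag over
    the cases whose cell is defined. Lags with fewer than ``min_n``
    contributing cases are masked (mean reported as NaN)."""
    return backward_estimate(aligned, min_n)[["lag_h", "n_eff", "mean", "masked"]]


def backward_quantiles(aligned: AlignedMatrix, min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    return backward_estimate(aligned, min_n)[["lag_h", "n_eff", "q25", "q50", "q75", "masked"]]


def backward_estimate(aligned: AlignedMatrix, min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Mean and quartile trajectories per backward lag.

    Returns columns (lag_h, n_eff, mean, q25, q50, q75, masked); masked
    lags (n_eff < min_n) keep their statistics as NaN, never as zero.
    """
    n, k = aligned.values.shape
    w = aligned.weights if aligned.weights is not None else np.ones(n)
    rows = []
    for s in range(k):
        n_eff, mean, (q25, q50, q75) = _column_stats(aligned.values[:, s], w)
        masked = n_eff < min_n
        rows.append(
            {
                "lag_h": s,
                "n_eff": n_eff,
                "mean": np.nan if masked else mean,
                "q25": np.nan if masked else q25,
                "q50": np.nan if masked else q50,
                "q75": np.nan if masked else q75,
                "masked": masked,
            }
        )
    return pd.DataFrame(rows)


def backward_scatter(
    measurements: pd.DataFrame, records: pd.DataFrame, variable: str, window_h: float = 72.0
) -> pd.DataFrame:
    """Raw (uninterpolated) measurements of cases in the window before
    their event: rows (patient_id, lag_h, value) with 0 <= lag <= window."""
    cases = records[records["status"] == STATUS_EVENT].set_index("patient_id")["X_h"]
    sub = measurements[
        (measurements["variable"] == variable)
        & measurements["patient_id"].isin(cases.index)
    ].copy()
    x = sub["patient_id"].map(cases)
    lag = x - sub["time_h"]
    keep = (lag >= 0) & (lag <= window_h)
    out = sub.loc[keep, ["patient_id", "value"]].copy()
    out.insert(1, "lag_h", lag[keep].to_numpy(dtype=float))
    return out.reset_index(drop=True)


def forward_scatter(
    measurements: pd.DataFrame,
    records: pd.DataFrame | None = None,
    variable: str | None = None,
    horizon_h: float = 192.0,
) -> pd.DataFrame:
    """All patients' raw measurements from admission, truncated at each
    patient's observed time (event or censoring) and at the horizon."""
    sub = measurements
    if variable is not None:
        sub = sub[sub["variable"] == variable]
    keep = sub["time_h"] <= horizon_h
    if records is not None:
        x = records.set_index("patient_id")["X_h"]
        keep &= sub["time_h"] <= sub["patient_id"].map(x).fillna(np.inf)
    return sub.loc[keep, ["patient_id", "time_h", "value"]].reset_index(drop=True)
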