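"""Regularization of irregular clinical time series to hourly grids.

Two-step scheme: measurements are first binned to a variable-specific
grid (half-open bins of 1/2/6/12/24 h, one node per non-empty bin at the
bin's left edge; in-bin mean for continuous variables, last value for
dichotomous ones), then hourly values are inferred between nodes by
piecewise-linear interpolation (continuous) or midpoint switching
(dichotomous). No extrapolation: hours before the first or after the
last node are missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import VariableSpec


@dataclass
class HourlySeries:
    """Hourly values for one patient-variable on [t0_h, t0_h + len - 1]."""

    patient_id: str
    variable: str
    t0_h: int
    values: np.ndarray
    observed_mask: np.ndarray  # True at grid nodes backed by data

    @property
    def hours(self) -> np.ndarray:
        return self.t0_h + np.arange(len(self.values))


@dataclass
class HourlyPanel:
    """Hourly series for all patients of one variable, as a dense matrix.

    ``values[i, h]`` is patient i's interpolated value at integer hour h
    (NaN outside the patient's observed node span); ``observed[i, h]`` is
    True at hours that are grid nodes backed by raw data.
    """

    variable: str
    patient_ids: np.ndarray
    values: np.ndarray    # (n_patients, n_hours)
    observed: np.ndarray  # bool, same shape

    @property
    def n_hours(self) -> int:
        return self.values.shape[1]

    def row(self, patient_id: str) -> np.ndarray:
        i = int(np.flatnonzero(self.patient_ids == patient_id)[0])
        return self.values[i]


def bin_to_grid(measurements: pd.DataFrame, spec: VariableSpec) -> pd.DataFrame:
    """Collapse one patient's measurements of one variable onto the grid.

    Returns a node table (time_h, value) with one node per non-empty
    half-open bin [k*step, (k+1)*step), placed at the bin's left edge.
    """
    sub = measurements
    if "variable" in sub.columns:
        sub = sub[sub["variable"] == spec.name]
    if not len(sub):
        return pd.DataFrame(columns=["time_h", "value"])
    sub = sub.sort_values("time_h", kind="mergesort")
    t = sub["time_h"].to_numpy(dtype=float)
    v = sub["value"].to_numpy(dtype=float)
    bins = np.floor(t / spec.grid_step_h).astype(int)
    if spec.kind == "continuous":
        agg = pd.Series(v).groupby(bins).mean()
    else:
        agg = pd.Series(v).groupby(bins).last()
    return pd.DataFrame(
        {"time_h": agg.index.to_numpy() * spec.grid_step_h, "value": agg.to_numpy()}
    )


def interpolate_hourly(
    nodes: pd.DataFrame, kind: str = "continuous", patient_id: str = "", variable: str = ""
) -> HourlySeries:
    """Hourly series between the first and last node (inclusive).

    Continuous: piecewise-linear between consecutive nodes, evaluated at
    integer hours; node hours reproduce node values exactly. Dichotomous:
    the value switches at the midpoint between consecutive differing
    nodes — an hour takes the later node's value iff hour >= midpoint.
    """
    if not len(nodes):
        raise ValueError("interpolate_hourly requires at least one node")
    t = nodes["time_h"].to_numpy(dtype=float)
    v = nodes["value"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("node times must be strictly increasing")
    t0, t_end = int(t[0]), int(t[-1])
    hours = np.arange(t0, t_end + 1)
    if kind == "continuous":
        values = np.interp(hours, t, v)
    else:
        right = np.searchsorted(t, hours, side="right")
        left = np.clip(right - 1, 0, len(t) - 1)
        right = np.clip(right, 0, len(t) - 1)
        mid = (t[left] + t[right]) / 2.0
        take_right = hours >= mid
        values = np.where(take_right, v[right], v[left])
        values[hours <= t[0]] = v[0]
    observed = np.isin(hours, t.astype(int))
    return HourlySeries(patient_id, variable, t0, values, observed)


def build_panel(
    measurements: pd.DataFrame,
    spec: VariableSpec,
    patient_ids: np.ndarray | list,
    horizon_h: float = 192.0,
    end_h: pd.Series | dict | None = None,
) -> HourlyPanel:
    """Regularize one variable for a whole cohort into an HourlyPanel.

    ``end_h`` (per patient, hours) optionally truncates the raw series
    before regularization: measurements strictly after a patient's end
    time are discarded. Used to exclude post-outcome data when building
    backward-looking inputs.
    """
    patient_ids = np.asarray(patient_ids)
    n = len(patient_ids)
    n_hours = int(np.floor(horizon_h)) + 1
    values = np.full((n, n_hours), np.nan)
    observed = np.zeros((n, n_hours), dtype=bool)

    sub = measurements[measurements["variable"] == spec.name]
    if end_h is not None:
        lim = sub["patient_id"].map(pd.Series(end_h))
        sub = sub[sub["time_h"] <= lim.fillna(np.inf)]
    sub = sub[(sub["time_h"] >= 0) & (sub["time_h"] <= horizon_h)]
    if not len(sub):
        return HourlyPanel(spec.name, patient_ids, values, observed)

    ridx = pd.Index(patient_ids).get_indexer(sub["patient_id"])
    ok = ridx >= 0
    t = sub["time_h"].to_numpy(dtype=float)[ok]
    v = sub["value"].to_numpy(dtype=float)[ok]
    ridx = ridx[ok]
    node_h = (np.floor(t / spec.grid_step_h) * spec.grid_step_h).astype(int)

    flat = ridx * n_hours + node_h
    if spec.kind == "continuous":
        sums = np.zeros(n * n_hours)
        counts = np.zeros(n * n_hours)
        np.add.at(sums, flat, v)
        np.add.at(counts, flat, 1.0)
        have = counts > 0
        node_vals = np.full(n * n_hours, np.nan)
        node_vals[have] = sums[have] / counts[have]
        values = node_vals.reshape(n, n_hours)
        observed = have.reshape(n, n_hours)
        # piecewise-linear fill strictly inside each patient's node span;
        # integer-hour columns are equally spaced, so index-linear = time-linear
        values = (
            pd.DataFrame(values)
            .interpolate(axis=1, method="linear", limit_area="inside")
            .to_numpy()
        )
    else:
        order = np.argsort(t, kind="stable")
        values[ridx[order], node_h[order]] = v[order]  # last-in-bin wins
        observed[ridx, node_h] = True
        for i in range(n):
            obs = np.flatnonzero(observed[i])
            if len(obs) < 2:
                continue
            nodes = pd.DataFrame({"time_h": obs, "value": values[i, obs]})
            series = interpolate_hourly(nodes, kind="dichotomous")
            values[i, series.t0_h : series.t0_h + len(series.values)] = series.values
    return HourlyPanel(spec.name, patient_ids, values, observed)


def panel_to_long(panel: HourlyPanel) -> pd.DataFrame:
    """Long-format hourly table (patient_id, variable, hour, value,
    observed), dropping undefined hours."""
    n, h = panel.values.shape
    mask = np.isfinite(panel.values)
    ridx, hidx = np.nonzero(mask)
    return pd.DataFrame(
        {
            "patient_id": panel.patient_ids[ridx],
            "variable": panel.variable,
            "hour": hidx,
            "value": panel.values[ridx, hidx],
            "observed": panel.observed[ridx, hidx],
        }
    )
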