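"""Static figures: individual forward trajectories, cohort scatter
plots, backward trajectory bands, and availability heatmaps.

Every figure is a derived view of a machine-readable table produced by
the pipeline; plotting never computes statistics of its own.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort import Cohort, STATUS_DEATH, STATUS_EVENT


def plot_individual(
    cohort: Cohort,
    patient_id: str,
    variables: list[str],
    records: pd.DataFrame | None = None,
    path: str | None = None,
):
    """Forward-looking panel per variable for one patient, with vertical
    markers at adjudicated outcome, DHC and death times."""
    if patient_id not in set(cohort.patients["patient_id"]):
        raise KeyError(f"unknown patient {patient_id!r}")
    m = cohort.measurements
    sub = m[m["patient_id"] == patient_id]
    nv = len(variables)
    fig, axes = plt.subplots(nv, 1, figsize=(8, 2.2 * nv), sharex=True, squeeze=False)
    marks = []
    if records is not None:
        for _, r in records[records["patient_id"] == patient_id].iterrows():
            if r["status"] == STATUS_EVENT:
                marks.append((r["X_h"], f"{r['outcome']} event", "tab:red"))
            elif r["status"] == STATUS_DEATH:
                marks.append((r["X_h"], "death", "black"))
    dhc = cohort.procedures[
        (cohort.procedures["patient_id"] == patient_id)
        & (cohort.procedures["procedure"] == "dhc")
    ]
    for _, r in dhc.iterrows():
        marks.append((r["time_h"], "dhc", "tab:purple"))
    for ax, var in zip(axes.ravel(), variables):
        s = sub[sub["variable"] == var].sort_values("time_h")
        if len(s):
            ax.plot(s["time_h"], s["value"], "o-", ms=3, lw=0.8)
        else:
            ax.text(0.5, 0.5, "no data", transform=ax.transAxes, ha="center", color="grey")
        for t, label, color in marks:
            ax.axvline(t, color=color, lw=0.8, ls="--")
        ax.set_ylabel(var)
    axes.ravel()[-1].set_xlabel("hours from admission")
    fig.suptitle(f"patient {patient_id}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_backward_bands(
    estimates: pd.DataFrame, outcome: str, path: str | None = None
):
    """Backward trajectory bands: one panel per variable, x-axis is hours
    before the outcome decreasing to 0 (event at the right), median line
    with interquartile band and mean overlay. Masked lags appear as gaps."""
    variables = sorted(estimates["variable"].unique())
    nv = len(variables)
    fig, axes = plt.subplots(nv, 1, figsize=(7, 2.2 * nv), sharex=True, squeeze=False)
    for ax, var in zip(axes.ravel(), variables):
        e = estimates[estimates["variable"] == var].sort_values("lag_h")
        lag = e["lag_h"].to_numpy(dtype=float)
        med = e["q50"].where(~e["masked"]).to_numpy(dtype=float)
        ax.fill_between(
            lag,
            e["q25"].where(~e["masked"]).to_numpy(dtype=float),
            e["q75"].where(~e["masked"]).to_numpy(dtype=float),
            alpha=0.25,
            label="IQR",
        )
        ax.plot(lag, med, lw=1.4, label="median")
        ax.plot(lag, e["mean"].where(~e["masked"]).to_numpy(dtype=float), lw=1.0, ls="--", label="mean")
        ax.set_ylabel(var)
        ax.invert_xaxis()
    axes.ravel()[0].legend(loc="upper left", fontsize=8)
    axes.ravel()[-1].set_xlabel("hours before outcome")
    fig.suptitle(f"backward trajectories before {outcome}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_scatter(
    table: pd.DataFrame, xcol: str, variable: str, backward: bool = False,
    path: str | None = None,
):
    """Cohort-level scatter of raw measurements (forward from admission,
    or backward in hours before the outcome)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(table[xcol], table["value"], s=4, alpha=0.25, edgecolors="none")
    ax.set_ylabel(variable)
    if backward:
        ax.set_xlabel("hours before outcome")
        ax.invert_xaxis()
    else:
        ax.set_xlabel("hours from admission")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_availability(matrix: pd.DataFrame, variable: str, path: str | None = None):
    """Heatmap of measurement availability: patients x time bins."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.imshow(
        matrix.to_numpy(dtype=float),
        aspect="auto",
        interpolation="nearest",
        cmap="Greys",
        extent=(0, float(matrix.columns[-1]) + 1, len(matrix), 0),
    )
    ax.set_xlabel("hours from admission")
    ax.set_ylabel("patients")
    ax.set_title(f"availability: {variable}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
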