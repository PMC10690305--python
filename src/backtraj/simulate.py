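"""Seeded synthetic cohort generator with joint longitudinal-survival
structure and exported ground truth.

Per patient the generator draws independent latent times: T* (latent
midline-shift crossing, the event anchor), death D and discharge C; the
observed state is the earliest of the three truncated at the horizon.
Lab/vital measurements arrive on an irregular schedule (i.i.d. log-normal
gaps per variable, parameterized by the gap median and quartiles, plus a
measurement at admission and at the end of follow-up) and follow a
patient-level baseline plus an event-anchored linear ramp: the marker
drifts by ``net_change`` over the ``onset_lag_h`` hours preceding T*.
Radiographic series are monotone-plus-noise latent processes whose
threshold crossings define the radiographic outcomes: MLS reaches 5 mm
exactly at T* and PGS reaches 4 mm at ``pgs_delay_factor`` * T*. DHC is
assigned to a configurable fraction of patients with in-horizon latent
crossings, at a lag after T*.

Ground truth (latent times and realized baselines) is exported for
estimator validation; identical (config, seed) reproduces the cohort
bit-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy.stats import norm

from .cohort import (
    Cohort,
    PROCEDURE_COLUMNS,
    STATUS_CENSORED,
    STATUS_DEATH,
    STATUS_EVENT,
)
from .config import ConfigError, GapSpec, SimConfig

_Z75 = norm.ppf(0.75)


def lognormal_from_quartiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and quartiles
    (sigma from the quartile ratio; exact when q25*q75 = median^2)."""
    mu = np.log(median)
    sigma = np.log(q75 / q25) / (2 * _Z75) if q75 > q25 else 0.0
    return mu, sigma


def draw_times(dist: dict, rng: np.random.Generator, n: int, field: str = "dist") -> np.ndarray:
    fam = dist.get("family")
    if fam == "weibull":
        return dist["scale"] * rng.weibull(dist["shape"], size=n)
    if fam == "exponential":
        return rng.exponential(dist["scale"], size=n)
    if fam == "lognormal":
        if "median" in dist:
            mu, sigma = lognormal_from_quartiles(dist["median"], dist["q25"], dist["q75"])
        else:
            mu, sigma = dist["mu"], dist["sigma"]
        return rng.lognormal(mu, sigma, size=n)
    if fam == "degenerate":
        return np.full(n, float(dist["value"]))
    if fam == "uniform":
        return rng.uniform(dist["low"], dist["high"], size=n)
    raise ConfigError(f"{field}: unknown family {fam!r}")


def simulate_event_times(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Independent latent event/death/discharge times per patient.

    Returns (patient_id, T_star_h, death_h, discharge_h). The observed
    state is the argmin of the three truncated at the horizon (see
    :func:`records_from_truth`).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    t_star = draw_times(config.event_time_dist, rng, n, "event_time_dist")
    death = draw_times(config.death_time_dist, rng, n, "death_time_dist")
    discharge = draw_times(config.discharge_time_dist, rng, n, "discharge_time_dist")
    ids = np.array([f"p{i:04d}" for i in range(n)])
    return pd.DataFrame(
        {"patient_id": ids, "T_star_h": t_star, "death_h": death, "discharge_h": discharge}
    )


def records_from_truth(truth: pd.DataFrame, horizon_h: float = 192.0) -> pd.DataFrame:
    """Exact event records for the latent event anchor T* (used for
    estimator validation, bypassing imaging-based adjudication)."""
    t = truth["T_star_h"].to_numpy(dtype=float)
    d = truth["death_h"].to_numpy(dtype=float)
    c = truth["discharge_h"].to_numpy(dtype=float)
    x = np.minimum.reduce([t, d, c, np.full_like(t, horizon_h)])
    status = np.full(len(t), STATUS_CENSORED)
    status[np.isclose(x, d) & (d <= horizon_h)] = STATUS_DEATH
    status[np.isclose(x, t) & (t <= horizon_h)] = STATUS_EVENT  # ties: event first
    reason = np.where(
        status == STATUS_EVENT, "none",
        np.where(status == STATUS_DEATH, "none", np.where(x < horizon_h, "discharge", "horizon")),
    )
    return pd.DataFrame(
        {
            "patient_id": truth["patient_id"].to_numpy(),
            "outcome": "latent",
            "X_h": x,
            "status": status,
            "censor_reason": reason,
        }
    )


def _sample_schedule(
    gap: GapSpec, end: np.ndarray, rng: np.random.Generator,
    extra: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Irregular measurement times per patient: t=0, log-normal gaps, and
    a final measurement at the end of follow-up; ``extra`` optionally adds
    one further time per patient (NaN to skip), used to record an
    assessment at clinical deterioration. Returns flat arrays
    (patient_index, time_h)."""
    n = len(end)
    mu, sigma = lognormal_from_quartiles(gap.median_h, gap.q25_h, gap.q75_h)
    max_k = int(np.ceil(end.max() / max(gap.q25_h, 1e-6) * 2)) + 20
    gaps = rng.lognormal(mu, sigma, size=(n, max_k))
    times = np.cumsum(gaps, axis=1)
    keep = times < end[:, None]
    ridx, cidx = np.nonzero(keep)
    t = times[ridx, cidx]
    # admission and end-of-follow-up measurements are always recorded
    ridx = np.concatenate([np.arange(n), ridx, np.arange(n)])
    t = np.concatenate([np.zeros(n), t, end])
    if extra is not None:
        keep_x = np.isfinite(extra) & (extra > 0) & (extra < end)
        ridx = np.concatenate([ridx, np.flatnonzero(keep_x)])
        t = np.concatenate([t, extra[keep_x]])
    order = np.lexsort((t, ridx))
    return ridx[order], t[order]


def _signature_values(
    t: np.ndarray,
    baseline: np.ndarray,
    t_star: np.ndarray,
    net_change: float,
    onset_lag_h: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """baseline + linear ramp reaching ``net_change`` at T* + noise."""
    frac = np.clip((t - (t_star - onset_lag_h)) / onset_lag_h, 0.0, 1.0)
    values = baseline + net_change * frac
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(t))
    return values


def simulate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground truth.

    Returns (cohort, truth) where ``truth`` holds the latent times
    (T_star_h, death_h, discharge_h, dhc_h) and the realized per-variable
    baselines. Identical (config, seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    horizon = config.horizon_h
    truth = simulate_event_times(config, rng)
    ids = truth["patient_id"].to_numpy()
    t_star = truth["T_star_h"].to_numpy()
    death = truth["death_h"].to_numpy()
    discharge = truth["discharge_h"].to_numpy()
    end = np.minimum.reduce([death, discharge, np.full(n, horizon)])

    # baseline covariates (decorative, cohort-realistic)
    age = np.clip(rng.normal(69, 15, n), 18, 100).round(0)
    female = rng.random(n) < 0.49
    nihss = np.clip(rng.normal(17.3, 5.9, n), 0, 42).round(0)

    meas_parts: list[pd.DataFrame] = []

    # lab / vital variables with event-anchored signatures
    for name in sorted(config.signatures):
        sig = config.signatures[name]
        spec = config.variable_specs[name]
        gap = config.sampling_gap_dist[name]
        baseline = rng.normal(sig.baseline_mean, sig.baseline_sd_between_patients, n)
        truth[f"baseline_{name}"] = baseline
        # labs/vitals are also recorded at the deterioration time itself
        ridx, t = _sample_schedule(gap, end, rng, extra=t_star)
        v = _signature_values(
            t, baseline[ridx], t_star[ridx], sig.net_change, sig.onset_lag_h, sig.noise_sd, rng
        )
        v = np.clip(v, *spec.plausible_range)
        meas_parts.append(
            pd.DataFrame(
                {
                    "patient_id": ids[ridx],
                    "variable": name,
                    "time_h": t,
                    "value": v,
                    "source": "lab" if spec.grid_step_h >= 6 else "vital",
                }
            )
        )

    # radiographic series: latent monotone shift, MLS crosses 5mm at T*,
    # PGS crosses 4mm at pgs_delay_factor * T*; scans at imaging cadence
    if "mls" in config.variable_specs and "imaging" in config.sampling_gap_dist:
        ridx, t = _sample_schedule(config.sampling_gap_dist["imaging"], end, rng)
        mls_latent = 5.0 * t / t_star[ridx]
        pgs_latent = 4.0 * t / (config.pgs_delay_factor * t_star[ridx])
        for name, latent in (("mls", mls_latent), ("pgs", pgs_latent)):
            spec = config.variable_specs[name]
            v = latent + rng.normal(0.0, config.scan_noise_sd_mm, size=len(t))
            v = np.clip(v, *spec.plausible_range)
            meas_parts.append(
                pd.DataFrame(
                    {
                        "patient_id": ids[ridx],
                        "variable": name,
                        "time_h": t,
                        "value": v,
                        "source": "imaging",
                    }
                )
            )

    measurements = (
        pd.concat(meas_parts, ignore_index=True)
        .sort_values(["patient_id", "variable", "time_h"], kind="mergesort")
        .reset_index(drop=True)
    )
    measurements["value"] = measurements["value"].round(6)
    measurements["time_h"] = measurements["time_h"].round(4)

    # DHC for a fraction of patients with in-horizon latent crossings,
    # at a lag after T*, only while the patient is still in hospital
    eligible = t_star <= horizon
    chosen = eligible & (rng.random(n) < config.dhc_fraction)
    lag = draw_times(config.dhc_lag_dist, rng, n, "dhc_lag_dist")
    dhc_h = np.where(chosen, t_star + lag, np.nan)
    dhc_h[dhc_h >= np.minimum(death, discharge)] = np.nan
    truth["dhc_h"] = dhc_h
    has_dhc = np.isfinite(dhc_h)
    procedures = pd.DataFrame(
        {
            "patient_id": ids[has_dhc],
            "procedure": "dhc",
            "time_h": np.round(dhc_h[has_dhc], 4),
        },
        columns=PROCEDURE_COLUMNS,
    )

    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "death_h": np.where(death <= discharge, np.round(death, 4), np.nan),
            "discharge_h": np.where(discharge < death, np.round(discharge, 4), np.nan),
            "age": age,
            "female": female.astype(int),
            "nihss": nihss,
        }
    )

    if config.artifact_rate > 0:
        measurements = inject_artifacts(
            measurements, config.artifact_rate, seed=int(rng.integers(0, 2**31 - 1))
        )

    cohort = Cohort(patients, measurements, procedures).validate()
    return cohort, truth


def inject_artifacts(measurements: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Corrupt a random fraction of measurements so that the outlier rules
    are guaranteed to fire on them.

    Rows with a same-variable predecessor within the patient are set to
    1.3x the (running) predecessor value, guaranteeing a >=25% jump even
    when consecutive rows are injected; first-in-series rows are pushed to
    cohort mean + 6 SD of their variable so the pooled |Z| >= 3 rule fires
    despite the SD inflation injection itself causes. Adds a boolean
    ``injected`` truth column.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = measurements.copy()
    out["injected"] = False
    if rate == 0.0 or not len(out):
        return out
    rng = np.random.default_rng(seed)
    hit = rng.random(len(out)) < rate
    stats = out.groupby("variable")["value"].agg(["mean", "std"])
    order = out.sort_values(["patient_id", "variable", "time_h"], kind="mergesort").index
    values = out["value"].to_numpy(dtype=float).copy()
    pos = {idx: k for k, idx in enumerate(out.index)}
    last_key = None
    prev_val = np.nan
    for idx in order:
        k = pos[idx]
        key = (out.at[idx, "patient_id"], out.at[idx, "variable"])
        if key != last_key:
            prev_val = np.nan
            last_key = key
        if hit[k]:
            if np.isfinite(prev_val) and prev_val != 0:
                values[k] = 1.3 * prev_val
            else:
                mu, sd = stats.loc[out.at[idx, "variable"]]
                values[k] = mu + 6.0 * (sd if np.isfinite(sd) and sd > 0 else max(abs(mu), 1.0))
        prev_val = values[k]
    out["value"] = values
    out["injected"] = hit
    return out
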