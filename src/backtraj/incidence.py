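"""Competing-risk cumulative incidence and the censoring survival curve.

The Aalen-Johansen estimator gives, for each cause k (1 = outcome,
2 = death), the cumulative incidence

    F_k(t) = sum_{t_j <= t} S(t_j-) * d_kj / n_j,

where S is the all-cause Kaplan-Meier survival, n_j the number at risk
and d_kj the cause-k events at t_j. Ties at equal timestamps are
processed simultaneously on the shared risk set (censored observations
at t remain in the risk set at t). Pointwise variance uses the Aalen-type
estimator and confidence intervals the log(-log) transform, which keeps
them inside [0, 1].

The censoring distribution Ĝ needed by inverse-probability-of-censoring
weighting is the Kaplan-Meier curve with the roles of event and censoring
reversed; a left-limit accessor Ĝ(t-) is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy.stats import norm

from .cohort import STATUS_CENSORED, STATUS_DEATH, STATUS_EVENT


@dataclass
class CIFEstimate:
    """Aalen-Johansen estimate at the ordered distinct event times."""

    times: np.ndarray                     # distinct times with >=1 event of any cause
    cif: dict[int, np.ndarray]            # cause -> F_k at each time (right-continuous)
    variance: dict[int, np.ndarray]
    ci_lower: dict[int, np.ndarray]
    ci_upper: dict[int, np.ndarray]
    n_at_risk: np.ndarray
    km_allcause: np.ndarray               # S(t_j), all-cause KM after each time
    causes: tuple[int, ...] = (STATUS_EVENT, STATUS_DEATH)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for k in self.causes:
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "cause": k,
                        "cif": self.cif[k],
                        "var": self.variance[k],
                        "ci_lo": self.ci_lower[k],
                        "ci_hi": self.ci_upper[k],
                        "n_risk": self.n_at_risk,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _loglog_ci(f: np.ndarray, var: np.ndarray, level: float) -> tuple[np.ndarray, np.ndarray]:
    z = norm.ppf(0.5 + level / 2.0)
    lo = np.zeros_like(f)
    hi = np.zeros_like(f)
    # exp(z*se) may overflow for tiny f with huge variance; f**inf -> 0 is
    # the correct degenerate lower bound, so the overflow is benign
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        interior = (f > 0) & (f < 1) & (var > 0)
        se_theta = np.sqrt(var[interior]) / (f[interior] * np.abs(np.log(f[interior])))
        lo[interior] = f[interior] ** np.exp(z * se_theta)
        hi[interior] = f[interior] ** np.exp(-z * se_theta)
    lo[~np.isfinite(lo)] = 0.0
    hi[~np.isfinite(hi)] = 1.0
    edge = (f >= 1) | ((f > 0) & (var == 0))
    lo[edge] = f[edge]
    hi[edge] = f[edge]
    return np.clip(lo, 0, 1), np.clip(hi, 0, 1)


def aalen_johansen(
    records: pd.DataFrame, causes: tuple[int, ...] = (STATUS_EVENT, STATUS_DEATH),
    ci_level: float = 0.95,
) -> CIFEstimate:
    """Aalen-Johansen cumulative incidence from an event-record table.

    ``records`` needs columns X_h (observed time > 0) and status
    (0 = censored, otherwise a cause code listed in ``causes``).
    """
    x = records["X_h"].to_numpy(dtype=float)
    status = records["status"].to_numpy(dtype=int)
    if np.any(x <= 0):
        raise ValueError("observed times must be > 0")
    if not set(np.unique(status)) <= ({STATUS_CENSORED} | set(causes)):
        raise ValueError("status codes outside {0} + causes")
    if not np.any(status != STATUS_CENSORED):
        warnings.warn("all observations censored; CIF is identically zero")
        t = np.array([np.max(x)]) if len(x) else np.array([0.0])
        zeros = np.zeros_like(t)
        return CIFEstimate(
            t,
            {k: zeros.copy() for k in causes},
            {k: zeros.copy() for k in causes},
            {k: zeros.copy() for k in causes},
            {k: zeros.copy() for k in causes},
            np.array([len(x)], dtype=float),
            np.ones_like(t),
            causes,
        )

    event_any = status != STATUS_CENSORED
    times = np.unique(x[event_any])
    J = len(times)
    # risk set: X >= t_j (censored at t stay in the risk set at t)
    x_sorted = np.sort(x)
    n_risk = len(x) - np.searchsorted(x_sorted, times, side="left")
    d = {}
    for k in causes:
        xk = np.sort(x[status == k])
        d[k] = (
            np.searchsorted(xk, times, side="right") - np.searchsorted(xk, times, side="left")
        ).astype(float)
    d_all = np.sum([d[k] for k in causes], axis=0)

    frac = np.where(n_risk > 0, d_all / n_risk, 0.0)
    S = np.cumprod(1.0 - frac)                    # S(t_j)
    S_minus = np.concatenate([[1.0], S[:-1]])     # S(t_j-)

    cif, variance, ci_lo, ci_hi = {}, {}, {}, {}
    for k in causes:
        dF = S_minus * d[k] / n_risk
        F = np.cumsum(dF)
        # Aalen-type variance via cumulative sums:
        # a_j = d_j / (n_j (n_j - d_j)), b_j = S(t_j-) d_kj / n_j^2
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(n_risk > d_all, d_all / (n_risk * (n_risk - d_all)), 0.0)
        b = S_minus * d[k] / n_risk**2
        c2 = S_minus**2 * ((n_risk - d[k]) / n_risk) * (d[k] / n_risk**2)
        A, FA, F2A = np.cumsum(a), np.cumsum(F * a), np.cumsum(F**2 * a)
        B, FB = np.cumsum(b), np.cumsum(F * b)
        C2 = np.cumsum(c2)
        var = (F**2 * A - 2 * F * FA + F2A) + C2 - 2 * (F * B - FB)
        var = np.maximum(var, 0.0)
        lo, hi = _loglog_ci(F, var, ci_level)
        cif[k], variance[k], ci_lo[k], ci_hi[k] = F, var, lo, hi

    return CIFEstimate(times, cif, variance, ci_lo, ci_hi, n_risk.astype(float), S, causes)


def cif_at(
    estimate: CIFEstimate, times, cause: int = STATUS_EVENT
) -> pd.DataFrame:
    """Right-continuous step evaluation of one cause's CIF with its CI.

    Times beyond the last observed jump return the last value and are
    flagged ``beyond_data``.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("evaluation times must be >= 0")
    idx = np.searchsorted(estimate.times, t, side="right") - 1
    out = pd.DataFrame({"time_h": t})
    for col, arr in (
        ("cif", estimate.cif[cause]),
        ("ci_lo", estimate.ci_lower[cause]),
        ("ci_hi", estimate.ci_upper[cause]),
    ):
        vals = np.where(idx >= 0, arr[np.clip(idx, 0, None)], 0.0)
        out[col] = vals
    out["beyond_data"] = t > estimate.times[-1]
    return out


@dataclass
class CensoringSurvival:
    """Kaplan-Meier estimate Ĝ of the censoring-time survival."""

    times: np.ndarray      # distinct censoring times (jumps)
    survival: np.ndarray   # Ĝ(t_j), right-continuous
    n_at_risk: np.ndarray = field(default_factory=lambda: np.array([]))

    def at(self, t) -> np.ndarray:
        """Ĝ(t), right-continuous."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)

    def at_minus(self, t) -> np.ndarray:
        """Left limit Ĝ(t-): jumps at exactly t are excluded."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left") - 1
        return np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)


def censoring_km(records: pd.DataFrame, death_as_censoring: bool = True) -> CensoringSurvival:
    """KM of the censoring distribution, reversing event/censoring roles.

    With ``death_as_censoring`` (default), death is pooled with discharge
    and horizon censoring as the terminating "censoring event" — the
    convention under which longitudinal follow-up ends at death or
    discharge and the backward estimand conditions on the outcome being
    observed. Otherwise only status 0 counts as censoring.
    """
    x = records["X_h"].to_numpy(dtype=float)
    status = records["status"].to_numpy(dtype=int)
    is_cens = (status == STATUS_CENSORED) | (
        death_as_censoring & (status == STATUS_DEATH)
    )
    if not is_cens.any():
        return CensoringSurvival(np.array([np.inf]), np.array([1.0]), np.array([float(len(x))]))
    times = np.unique(x[is_cens])
    x_sorted = np.sort(x)
    n_risk = len(x) - np.searchsorted(x_sorted, times, side="left")
    xc = np.sort(x[is_cens])
    d = (
        np.searchsorted(xc, times, side="right") - np.searchsorted(xc, times, side="left")
    ).astype(float)
    surv = np.cumprod(1.0 - d / n_risk)
    return CensoringSurvival(times, surv, n_risk.astype(float))
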