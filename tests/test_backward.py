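import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from backtraj.backward import (
    AlignedMatrix,
    PositivityError,
    align_backward,
    attach_weights,
    backward_estimate,
    backward_scatter,
    forward_scatter,
    ipcw_weights,
    weighted_quantile,
)
from backtraj.incidence import CensoringSurvival, censoring_km
from backtraj.regularize import HourlyPanel


def _panel(values, ids=None, variable="hr"):
    values = np.asarray(values, dtype=float)
    ids = np.array([f"p{i}" for i in range(values.shape[0])]) if ids is None else np.asarray(ids)
    return HourlyPanel(variable, ids, values, np.isfinite(values))


def _records(ids, times, statuses):
    return pd.DataFrame({"patient_id": ids, "X_h": times, "status": statuses})


class TestAlign:
    def test_constant_series_single_case(self):
        panel = _panel(np.full((1, 20), 7.0))
        rec = _records(["p0"], [10.0], [1])
        aligned = align_backward(panel, rec, s_max=15)
        assert np.all(aligned.values[0, :11] == 7.0)
        assert np.isnan(aligned.values[0, 11:]).all()  # X - s < 0

    def test_linear_series_shifts_by_lag(self):
        hours = np.arange(60.0)
        panel = _panel(hours[None, :])
        rec = _records(["p0"], [50.0], [1])
        aligned = align_backward(panel, rec, s_max=40)
        assert np.allclose(aligned.values[0], 50.0 - np.arange(41))

    def test_zero_cases_empty_matrix(self):
        panel = _panel(np.full((2, 10), 1.0))
        rec = _records(["p0", "p1"], [5.0, 6.0], [0, 2])
        aligned = align_backward(panel, rec, s_max=10)
        assert aligned.n_cases == 0
        est = backward_estimate(aligned)
        assert est["masked"].all() and est["mean"].isna().all()

    def test_case_without_series_stays_all_missing(self):
        panel = _panel(np.full((1, 10), 3.0), ids=["p0"])
        rec = _records(["p0", "ghost"], [5.0, 5.0], [1, 1])
        aligned = align_backward(panel, rec, s_max=5)
        assert aligned.n_cases == 2
        assert np.isnan(aligned.values[1]).all()

    def test_event_time_rounding_half_up(self):
        panel = _panel(np.arange(10.0)[None, :])
        rec = _records(["p0"], [4.5], [1])
        aligned = align_backward(panel, rec, s_max=2)
        assert aligned.values[0, 0] == 5.0


class TestIpcw:
    def test_no_censoring_equal_weights(self):
        rec = _records(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 1])
        G = censoring_km(rec)
        w = ipcw_weights(rec, G)
        assert np.allclose(w.to_numpy(), 1 / 3)

    def test_hand_weights_one_third_two_thirds(self):
        rec = _records(["a", "b"], [1.0, 2.0], [1, 1])
        G = CensoringSurvival(np.array([1.5]), np.array([0.5]))
        w = ipcw_weights(rec, G)
        assert np.allclose(w.to_numpy(), [1 / 3, 2 / 3])

    def test_single_case_weight_one(self):
        rec = _records(["a"], [5.0], [1])
        G = CensoringSurvival(np.array([1.0]), np.array([0.25]))
        assert ipcw_weights(rec, G).iloc[0] == 1.0

    def test_non_cases_weight_zero(self):
        rec = _records(["a", "b"], [1.0, 2.0], [1, 0])
        w = ipcw_weights(rec, censoring_km(rec))
        assert w["b"] == 0.0 and w["a"] == 1.0

    def test_positivity_violation_names_patient(self):
        rec = _records(["a", "late"], [1.0, 9.0], [1, 1])
        G = CensoringSurvival(np.array([5.0]), np.array([0.0]))
        with pytest.raises(PositivityError, match="late"):
            ipcw_weights(rec, G)


class TestWeightedQuantile:
    def test_equal_weights_median(self):
        assert weighted_quantile([1, 2, 3], [1, 1, 1], 0.5) == 2

    def test_cumulative_weight_hits_q_at_first_value(self):
        assert weighted_quantile([1, 3], [0.5, 0.5], 0.5) == 1

    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=20),
        seed=st.integers(0, 10_000),
    )
    def test_quartiles_ordered(self, values, seed):
        w = np.random.default_rng(seed).uniform(0.1, 1.0, len(values))
        qs = [weighted_quantile(values, w, q) for q in (0.25, 0.5, 0.75)]
        assert qs[0] <= qs[1] <= qs[2]

    def test_empty_returns_missing(self):
        assert np.isnan(weighted_quantile([], [], 0.5))


class TestBackwardEstimate:
    def test_constant_cases_give_constant_mean(self):
        panel = _panel(np.full((6, 30), 4.2))
        rec = _records([f"p{i}" for i in range(6)], [20.0] * 6, [1] * 6)
        aligned = attach_weights(align_backward(panel, rec, 10), ipcw_weights(rec, censoring_km(rec)))
        est = backward_estimate(aligned)
        assert np.allclose(est["mean"], 4.2) and np.allclose(est["q50"], 4.2)

    def test_two_case_mean(self):
        values = np.vstack([np.full(40, 10.0), np.full(40, 12.0)])
        panel = _panel(values)
        rec = _records(["p0", "p1"], [30.0] * 2, [1, 1])
        aligned = align_backward(panel, rec, 24)
        est = backward_estimate(aligned, min_n=1)
        assert est.loc[est["lag_h"] == 24, "mean"].iloc[0] == 11.0

    def test_min_n_masks_sparse_lags(self):
        values = np.full((3, 10), 1.0)
        panel = _panel(values)
        rec = _records(["p0", "p1", "p2"], [9.0, 3.0, 3.0], [1, 1, 1])
        aligned = align_backward(panel, rec, 8)
        est = backward_estimate(aligned, min_n=3)
        # lags 4..8 are observable only for the X=9 case -> masked, never zero
        masked = est.loc[est["lag_h"] >= 4]
        assert masked["masked"].all() and masked["mean"].isna().all()
        assert not est.loc[est["lag_h"] <= 3, "masked"].any()

    def test_uncensored_equals_bruteforce_case_statistics(self, rng):
        n, h = 50, 120
        values = rng.normal(10, 3, (n, h))
        x = rng.uniform(20, 110, n)
        start = rng.integers(0, 10, n)
        for i in range(n):
            values[i, : start[i]] = np.nan
            values[i, int(x[i]) + 1:] = np.nan
        panel = _panel(values)
        ids = panel.patient_ids
        rec = _records(ids, x, [1] * n)
        aligned = attach_weights(
            align_backward(panel, rec, 72), ipcw_weights(rec, censoring_km(rec))
        )
        est = backward_estimate(aligned, min_n=1)
        xr = np.floor(x + 0.5).astype(int)
        for s in range(73):
            col = np.array(
                [values[i, xr[i] - s] if 0 <= xr[i] - s < h else np.nan for i in range(n)]
            )
            avail = np.isfinite(col)
            row = est.loc[est["lag_h"] == s].iloc[0]
            if not avail.any():
                assert np.isnan(row["mean"])
                continue
            assert row["n_eff"] == avail.sum()
            assert row["mean"] == pytest.approx(col[avail].mean(), abs=1e-12)
            v = np.sort(col[avail])
            cum = np.arange(1, len(v) + 1) / len(v)
            for q, name in ((0.25, "q25"), (0.5, "q50"), (0.75, "q75")):
                # when q lands exactly on a cumulative-weight boundary,
                # floating-point rounding may resolve to either neighbouring
                # order statistic; accept any valid left-continuous quantile
                lo = np.searchsorted(cum, q - 1e-9, side="left")
                hi = np.searchsorted(cum, q + 1e-9, side="left")
                assert row[name] in v[lo : hi + 1]


class TestScatterTables:
    def _meas(self):
        return pd.DataFrame(
            {
                "patient_id": ["a", "a", "a", "b"],
                "variable": "wbc",
                "time_h": [5.0, 60.0, 70.0, 5.0],
                "value": [9.0, 10.0, 11.0, 8.0],
            }
        )

    def test_backward_lags(self):
        rec = _records(["a", "b"], [65.0, 100.0], [1, 0])
        tbl = backward_scatter(self._meas(), rec, "wbc", window_h=72)
        assert tbl["lag_h"].tolist() == [60.0, 5.0]  # 70h is after the event

    def test_measurement_at_event_time_has_lag_zero(self):
        rec = _records(["a"], [60.0], [1])
        tbl = backward_scatter(self._meas(), rec, "wbc", window_h=72)
        assert 0.0 in tbl["lag_h"].tolist()

    def test_window_excludes_old_measurements(self):
        rec = _records(["a"], [80.0], [1])
        tbl = backward_scatter(self._meas(), rec, "wbc", window_h=72)
        assert 75.0 not in tbl["lag_h"].tolist()  # 5h point is 75h before event

    def test_forward_excludes_post_event_rows(self):
        rec = _records(["a", "b"], [65.0, 100.0], [1, 0])
        tbl = forward_scatter(self._meas(), rec, "wbc")
        assert len(tbl) == 3  # a@70h dropped
        unrestricted = forward_scatter(self._meas(), None, "wbc")
        assert len(unrestricted) == 4
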