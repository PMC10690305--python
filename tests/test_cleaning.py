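import numpy as np
import pandas as pd
import pytest

from backtraj.cleaning import (
    apply_flag_policy,
    availability_matrix,
    flag_outliers,
    mean_abs_error,
    percent_agreement,
    summarize_gaps,
)
from backtraj.simulate import inject_artifacts, simulate_cohort
from backtraj.config import SimConfig


def _meas(values, times=None, pid="p", var="glucose"):
    times = list(range(len(values))) if times is None else times
    return pd.DataFrame(
        {"patient_id": pid, "variable": var, "time_h": times, "value": values}
    )


class TestFlagRules:
    def test_forty_percent_jump_flagged(self):
        # cohort SD large so the Z rule stays quiet; 10 -> 14 is a 40% jump
        m = pd.concat(
            [_meas([10.0, 10.0, 14.0]), _meas([200.0, 400.0], pid="q", var="other")],
            ignore_index=True,
        )
        flags = flag_outliers(m)
        assert flags.loc[2, "flagged"]
        assert flags.loc[2, "rel_change"] == pytest.approx(0.4)
        assert not flags.loc[[0, 1], "flagged"].any()

    def test_twenty_percent_change_not_flagged(self):
        m = _meas([10.0, 12.0, 11.0, 10.5, 9.8, 10.2, 11.0, 10.4])
        assert not flag_outliers(m)["flagged"].any()

    @pytest.mark.parametrize("target_z, expect", [(3.0001, True), (2.9999, False)])
    def test_z_rule_threshold_location(self, target_z, expect):
        # the Z threshold sits at 3 pooled SDs; margins far exceed float noise
        base = np.array([-1.0, 1.0] * 10)
        m = _meas(list(base) + [0.0])
        v = m["value"].to_numpy()
        # solve for x so that (x - mean')/sd' == target after including x itself
        x = 0.0
        for _ in range(200):
            vals = np.append(v[:-1], x)
            x_new = vals.mean() + target_z * vals.std(ddof=1)
            if abs(x_new - x) < 1e-12:
                break
            x = x_new
        m.loc[len(m) - 1, "value"] = x
        # distinct patients disable the relative-change path for a pure Z check
        m["patient_id"] = [f"p{i}" for i in range(len(m))]
        flags = flag_outliers(m)
        assert flags["z_score"].iloc[-1] == pytest.approx(target_z, abs=1e-8)
        assert bool(flags["flagged"].iloc[-1]) is expect

    def test_rel_change_boundary_inclusive(self):
        # 10 -> 12.5 is exactly 25% in binary floating point: flagged
        m = pd.concat(
            [_meas([10.0, 12.5]), _meas([200.0, 400.0], pid="q", var="other")],
            ignore_index=True,
        )
        flags = flag_outliers(m)
        assert flags.loc[1, "rel_change"] == 0.25
        assert flags.loc[1, "flagged"]

    def test_constant_cohort_no_flags(self):
        with pytest.warns(UserWarning, match="zero/undefined cohort SD"):
            flags = flag_outliers(_meas([5.0] * 6))
        assert not flags["flagged"].any()

    def test_radiographic_series_exempt_from_change_rule(self):
        m = _meas([1.0, 2.0, 4.0], var="mls")
        assert not flag_outliers(m)["flagged"].any()

    def test_first_value_has_undefined_rel_change(self):
        flags = flag_outliers(_meas([10.0, 11.0]))
        assert np.isnan(flags.loc[0, "rel_change"])

    def test_zero_predecessor_rel_change_undefined(self):
        flags = flag_outliers(_meas([0.0, 5.0, 5.0]))
        assert np.isnan(flags.loc[1, "rel_change"])

    def test_row_order_and_relabeling_invariance(self):
        m = pd.concat(
            [_meas([10.0, 14.0, 13.0]), _meas([8.0, 9.0], pid="q")], ignore_index=True
        )
        f1 = flag_outliers(m)["flagged"]
        perm = [3, 1, 4, 0, 2]
        f2 = flag_outliers(m.iloc[perm])["flagged"].sort_index()
        assert (f1 == f2).all()
        relabeled = m.assign(patient_id=m["patient_id"].map({"p": "zz", "q": "aa"}))
        f3 = flag_outliers(relabeled)["flagged"]
        assert (f1 == f3).all()


class TestFlagPolicy:
    def test_drop_removes_exactly_flagged(self):
        m = pd.concat(
            [_meas([10.0, 10.0, 14.0]), _meas([200.0, 400.0], pid="q", var="other")],
            ignore_index=True,
        )
        flags = flag_outliers(m)
        out, report = apply_flag_policy(m, flags, "drop_flagged")
        assert report["n_removed"] == int(flags["flagged"].sum())
        assert len(out) == len(m) - report["n_removed"]
        assert not flags.loc[out.index, "flagged"].any()
        assert flags.loc[flags["flagged"], "removed"].all()

    def test_flag_only_is_identity(self):
        m = _meas([10.0, 14.0])
        out, report = apply_flag_policy(m, flag_outliers(m), "flag_only")
        pd.testing.assert_frame_equal(out, m)
        assert report["n_removed"] == 0

    def test_drop_with_zero_flags_is_identity(self):
        m = _meas([10.0, 10.5, 10.2])
        out, report = apply_flag_policy(m, flag_outliers(m), "drop_flagged")
        pd.testing.assert_frame_equal(out, m)
        assert report["n_removed"] == 0

    def test_misaligned_flags_rejected(self):
        m = _meas([10.0, 11.0])
        with pytest.raises(ValueError, match="aligned"):
            apply_flag_policy(m, flag_outliers(m).iloc[:1], "drop_flagged")


class TestAgreement:
    def test_identical(self):
        assert percent_agreement(["A", "B"], ["A", "B"]) == 100.0
        assert mean_abs_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_examples(self):
        assert percent_agreement(list("AABC"), list("ABBC")) == 75.0
        assert mean_abs_error([1.0, 2.0], [1.2, 1.6]) == pytest.approx(0.3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_agreement(["A"], ["A", "B"])
        with pytest.raises(ValueError):
            mean_abs_error([1.0], [1.0, 2.0])


class TestGaps:
    def test_simple_median(self):
        g = summarize_gaps(_meas([1, 2, 3], times=[0.0, 6.0, 12.0]))
        assert g.loc[0, "median_h"] == 6.0 and g.loc[0, "n_gaps"] == 2

    def test_single_measurement_contributes_nothing(self):
        assert len(summarize_gaps(_meas([1.0], times=[3.0]))) == 0

    def test_pooled_across_patients(self):
        m = pd.concat(
            [_meas([1, 2, 3], times=[0.0, 2.0, 10.0]),
             _meas([1, 2], times=[0.0, 4.0], pid="q")],
            ignore_index=True,
        )
        g = summarize_gaps(m)
        assert g.loc[0, "n_gaps"] == 3
        assert g.loc[0, "median_h"] == 4.0

    def test_restriction_to_pre_event_gaps(self):
        m = _meas([1, 2, 3, 4], times=[0.0, 10.0, 20.0, 30.0])
        rec = pd.DataFrame({"patient_id": ["p"], "X_h": [20.0]})
        g = summarize_gaps(m, restrict_before=rec)
        assert g.loc[0, "n_gaps"] == 2  # gaps ending at 10h and 20h


class TestAvailability:
    def test_single_measurement_bin(self):
        mat = availability_matrix(_meas([1.0], times=[3.0]), 2, horizon_h=8)
        assert mat.loc["p", 2] and mat.drop(columns=[2]).loc["p"].sum() == 0

    def test_empty_input_all_false(self):
        mat = availability_matrix(_meas([], times=[]), 6, horizon_h=24, patient_ids=["a"])
        assert not mat.to_numpy().any()

    def test_half_open_binning(self):
        mat = availability_matrix(_meas([1.0, 2.0], times=[0.0, 23.9]), 24, horizon_h=48)
        assert mat.loc["p", 0] and not mat.loc["p", 24]


class TestInjectedSensitivity:
    def test_flag_rules_catch_injected_artifacts(self):
        cfg = SimConfig(n_patients=80, seed=11)
        cohort, _ = simulate_cohort(cfg)
        labs = cohort.measurements[
            cohort.measurements["variable"].isin(["glucose", "sodium", "wbc"])
        ].reset_index(drop=True)
        corrupted = inject_artifacts(labs, rate=0.05, seed=3)
        flags = flag_outliers(corrupted)
        injected = corrupted["injected"]
        sensitivity = flags.loc[injected, "flagged"].mean()
        assert sensitivity >= 0.95
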