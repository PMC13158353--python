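"""KDIGO phenotyping: eGFR equation, baseline definitions, daily-max rule,
adjudication examples and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akival import (
    BaselineEstimate,
    BaselineMethod,
    CreatinineMeasurement,
    Setting,
    Trigger,
    adjudicate_aki,
    compute_baseline,
    daily_max,
    egfr_japanese,
    egfr_stratum,
    egfr_to_scr,
)
from akival.kdigo import BaselineUnavailableError

from conftest import oracle_adjudicate, random_fixture


def _m(day, value, setting=Setting.INPATIENT, hid="H1"):
    return CreatinineMeasurement(hid, day, value, setting)


def _baseline(value, n=1):
    egfr = egfr_japanese(value, 60, "male")
    return BaselineEstimate(
        value, BaselineMethod.MEAN_OUTPATIENT_7_365, n, egfr, egfr_stratum(egfr)
    )


class TestEgfr:
    @pytest.mark.parametrize(
        "scr, age, sex, expected",
        [(0.80, 62, "male", 75.8), (0.80, 62, "female", 56.0)],
    )
    def test_printed_formula(self, scr, age, sex, expected):
        assert egfr_japanese(scr, age, sex) == pytest.approx(expected, abs=0.05)

    @given(
        scr=st.floats(0.2, 8.0),
        age=st.floats(18.0, 100.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_female_male_ratio_is_0739(self, scr, age):
        ratio = egfr_japanese(scr, age, "female") / egfr_japanese(scr, age, "male")
        assert ratio == pytest.approx(0.739, rel=1e-12)

    @given(egfr=st.floats(5.0, 150.0), age=st.floats(18.0, 100.0))
    @settings(max_examples=50, derandomize=True)
    def test_inverse_round_trips(self, egfr, age):
        scr = egfr_to_scr(egfr, age, "female")
        assert egfr_japanese(scr, age, "female") == pytest.approx(egfr, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            egfr_japanese(0.0, 60, "male")
        with pytest.raises(ValueError):
            egfr_japanese(1.0, 60, "unknown")

    def test_strata_boundaries(self):
        assert egfr_stratum(60.0).value == "ge60"
        assert egfr_stratum(59.999).value == "30to59.9"
        assert egfr_stratum(30.0).value == "30to59.9"
        assert egfr_stratum(15.0).value == "15to29.9"
        assert egfr_stratum(14.999).value == "lt15"


class TestBaseline:
    OUT = [
        _m(-30, 0.9, Setting.OUTPATIENT),
        _m(-10, 1.1, Setting.OUTPATIENT),
    ]

    def test_mean_of_outpatient_window(self):
        est = compute_baseline(self.OUT, 0, "mean_outpatient_7_365", age=60, sex="male")
        assert est.value == pytest.approx(1.0)
        assert est.n_contributing == 2

    def test_latest_outpatient(self):
        est = compute_baseline(self.OUT, 0, "latest_outpatient_7_365", age=60, sex="male")
        assert est.value == pytest.approx(1.1)
        assert est.n_contributing == 1

    def test_window_boundaries(self):
        # enumerate eligibility of each lag: only 7..365 days before surgery
        for lag, ok in [(6, False), (7, True), (365, True), (366, False)]:
            ms = [_m(-lag, 1.0, Setting.OUTPATIENT)]
            if ok:
                assert compute_baseline(ms, 0).value == 1.0
            else:
                with pytest.raises(BaselineUnavailableError):
                    compute_baseline(ms, 0)

    def test_latest_inpatient_presurgery(self):
        ms = [_m(1, 0.8, Setting.INPATIENT), _m(2, 0.9, Setting.INPATIENT)]
        est = compute_baseline(ms, 3, "latest_inpatient_presurgery", age=60, sex="male")
        assert est.value == pytest.approx(0.9)
        with pytest.raises(BaselineUnavailableError):
            compute_baseline(ms, 1, "latest_inpatient_presurgery")

    def test_egfr_attached(self):
        est = compute_baseline(self.OUT, 0, age=62, sex="male")
        assert est.egfr == pytest.approx(egfr_japanese(1.0, 62, "male"))


class TestDailyMax:
    def test_highest_same_day_value_kept(self):
        ms = [_m(1, 1.2), _m(1, 1.5), _m(1, 1.3)]
        out = daily_max(ms)
        assert len(out) == 1 and out[0].value == 1.5

    def test_identity_when_one_per_day(self):
        ms = [_m(1, 1.2), _m(2, 1.4)]
        assert daily_max(ms) == ms

    def test_empty(self):
        assert daily_max([]) == []

    def test_settings_kept_separate(self):
        ms = [_m(1, 1.2, Setting.OUTPATIENT), _m(1, 1.0, Setting.INPATIENT)]
        assert len(daily_max(ms)) == 2


class TestAdjudication:
    def test_absolute_rise_within_two_days(self):
        adj = adjudicate_aki([_m(0, 1.1), _m(2, 1.31)], _baseline(1.0), [], 0)
        assert adj.positive and adj.stage == 1
        assert adj.trigger is Trigger.ABSOLUTE_RISE and adj.trigger_day == 2

    def test_relative_rise_stage_2(self):
        adj = adjudicate_aki([_m(1, 2.0)], _baseline(0.9), [], 0)
        assert adj.positive and adj.stage == 2
        assert adj.trigger is Trigger.RELATIVE_RISE
        assert adj.peak_ratio == pytest.approx(2.0 / 0.9)

    def test_below_both_thresholds_negative(self):
        adj = adjudicate_aki([_m(1, 1.2)], _baseline(1.0), [], 0)
        assert not adj.positive and adj.stage == 0 and adj.trigger is Trigger.NONE

    def test_rrt_alone_is_stage_3(self):
        adj = adjudicate_aki([_m(0, 1.05)], _baseline(1.0), [3], 0)
        assert adj.positive and adj.stage == 3 and adj.trigger is Trigger.RRT

    def test_negative_by_absence(self):
        adj = adjudicate_aki([], _baseline(1.0), [], 0)
        assert not adj.positive and not adj.evaluable

    def test_scr4_gate(self):
        # a lone high value without a qualifying rise: promoted only when
        # the gate is released
        high = [_m(1, 4.1)]
        gated = adjudicate_aki(high, _baseline(3.9), [], 0, scr4_requires_aki=True)
        assert not gated.positive
        open_ = adjudicate_aki(high, _baseline(3.9), [], 0, scr4_requires_aki=False)
        assert open_.positive and open_.stage == 3 and open_.trigger is Trigger.SCR_GE4

    def test_baseline_comparator_mode(self):
        # rise >=0.3 mg/dL more than 2 days after surgery, rolling minimum
        # anchored by an intermediate value: fires under rolling, not under
        # the baseline-only comparator
        ms = [_m(0, 1.0), _m(3, 1.05), _m(4, 1.40)]
        rolling = adjudicate_aki(ms, _baseline(1.0), [], 0, absolute_comparator="rolling")
        vs_base = adjudicate_aki(ms, _baseline(1.0), [], 0, absolute_comparator="baseline")
        assert rolling.positive and not vs_base.positive

    def test_same_day_tie_prefers_relative(self):
        # both rules fire on day 1 at stage 1
        adj = adjudicate_aki([_m(1, 1.6)], _baseline(1.0), [], 0)
        assert adj.trigger is Trigger.RELATIVE_RISE and adj.stage == 1

    def test_preop_measurement_rejected(self):
        with pytest.raises(ValueError):
            adjudicate_aki([_m(-1, 1.0)], _baseline(1.0), [], 0)


class TestAdjudicationProperties:
    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            days, values, b, rrt, wend, gate = random_fixture(rng)
            ms = [_m(d, v) for d, v in zip(days, values)]
            adj = adjudicate_aki(
                ms,
                _baseline(b),
                rrt,
                0,
                window="days_0_to_7" if wend == 7 else "through_discharge",
                scr4_requires_aki=gate,
            )
            exp_pos, exp_stage = oracle_adjudicate(
                days, values, b, rrt, 0, window_end=wend, scr4_requires_aki=gate
            )
            assert (adj.positive, adj.stage) == (exp_pos, exp_stage), (
                days, values, b, rrt, wend, gate,
            )

    @given(
        values=st.lists(st.floats(0.3, 3.0), min_size=1, max_size=6),
        lam=st.floats(1.0, 3.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_uniform_scaleup_never_lowers_stage(self, values, lam):
        days = list(range(len(values)))
        base = _baseline(1.0)
        before = adjudicate_aki([_m(d, v) for d, v in zip(days, values)], base, [], 0)
        after = adjudicate_aki(
            [_m(d, v * lam) for d, v in zip(days, values)], base, [], 0
        )
        assert after.stage >= before.stage
        assert after.positive or not before.positive

    @given(
        values=st.lists(st.floats(0.3, 3.0), min_size=1, max_size=6),
        which=st.integers(0, 5),
        bump=st.floats(0.0, 2.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_single_value_monotone_under_baseline_comparator(self, values, which, bump):
        days = list(range(len(values)))
        base = _baseline(1.0)
        kw = dict(absolute_comparator="baseline")
        before = adjudicate_aki([_m(d, v) for d, v in zip(days, values)], base, [], 0, **kw)
        bumped = [
            v + (bump if i == which % len(values) else 0.0) for i, v in enumerate(values)
        ]
        after = adjudicate_aki([_m(d, v) for d, v in zip(days, bumped)], base, [], 0, **kw)
        assert after.stage >= before.stage

    def test_window_nesting(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            days, values, b, rrt, _, gate = random_fixture(rng)
            ms = [_m(d, v) for d, v in zip(days, values)]
            narrow = adjudicate_aki(ms, _baseline(b), rrt, 0, window="days_0_to_7",
                                    scr4_requires_aki=gate)
            wide = adjudicate_aki(ms, _baseline(b), rrt, 0, window="through_discharge",
                                  scr4_requires_aki=gate)
            if narrow.positive:
                assert wide.positive and wide.stage >= narrow.stage

    @given(ratio=st.floats(1.5, 6.0))
    @settings(max_examples=60, derandomize=True)
    def test_stage_bands_partition(self, ratio):
        adj = adjudicate_aki([_m(1, ratio)], _baseline(1.0), [], 0)
        assert adj.positive
        in_band = [
            1.5 <= adj.peak_ratio < 2.0,
            2.0 <= adj.peak_ratio < 3.0,
            adj.peak_ratio >= 3.0,
        ]
        assert sum(in_band) == 1
        # SCr >= 4 promotes to stage 3 once a rise rule fires
        expected = 3 if (adj.peak_value >= 4.0 or in_band[2]) else (2 if in_band[1] else 1)
        assert adj.stage == expected
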