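"""KDIGO creatinine-based AKI adjudication.

Implements the laboratory reference standard used to validate administrative
AKI coding: acute kidney injury is present when serum creatinine (SCr) rises
to >=1.5x the pre-surgery baseline, or by >=0.3 mg/dL within a 48-hour
window, or when renal replacement therapy (RRT) is initiated after surgery.
Severity staging follows the KDIGO bands: stage 1 for a 1.5-1.9x rise or an
absolute >=0.3 mg/dL rise, stage 2 for 2.0-2.9x, stage 3 for >=3.0x, an SCr
>=4.0 mg/dL, or RRT initiation.

All dates are integer day offsets from hospital admission (day 0); the data
source records laboratory values at daily resolution, so "within 48 hours"
is calendar-day arithmetic (day difference <= 2).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Setting",
    "BaselineMethod",
    "DetectionWindow",
    "Trigger",
    "CreatinineMeasurement",
    "BaselineEstimate",
    "AkiAdjudication",
    "egfr_japanese",
    "egfr_to_scr",
    "egfr_stratum",
    "daily_max",
    "compute_baseline",
    "adjudicate_aki",
    "adjudicate_cohort",
]

ABSOLUTE_RISE_MG_DL = 0.3
RELATIVE_RISE_FACTOR = 1.5
STAGE2_FACTOR = 2.0
STAGE3_FACTOR = 3.0
SCR_STAGE3_MG_DL = 4.0
ROLLING_WINDOW_DAYS = 2


class Setting(str, enum.Enum):
    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"


class BaselineMethod(str, enum.Enum):
    """Baseline SCr definitions: the main analysis uses the mean of
    outpatient values drawn 7-365 days before surgery; the two variants are
    the most recent outpatient value from the same window and the most
    recent inpatient value before surgery."""

    MEAN_OUTPATIENT_7_365 = "mean_outpatient_7_365"
    LATEST_OUTPATIENT_7_365 = "latest_outpatient_7_365"
    LATEST_INPATIENT_PRESURGERY = "latest_inpatient_presurgery"


class DetectionWindow(str, enum.Enum):
    THROUGH_DISCHARGE = "through_discharge"
    DAYS_0_TO_7 = "days_0_to_7"


class Trigger(str, enum.Enum):
    ABSOLUTE_RISE = "absolute_rise"
    RELATIVE_RISE = "relative_rise"
    SCR_GE4 = "scr_ge4"
    RRT = "rrt"
    NONE = "none"


class Stratum(str, enum.Enum):
    """Baseline eGFR strata (mL/min/1.73 m^2) used for subgrouping."""

    GE60 = "ge60"
    S30_TO_59 = "30to59.9"
    S15_TO_29 = "15to29.9"
    LT15 = "lt15"


@dataclass(frozen=True)
class CreatinineMeasurement:
    """One dated serum creatinine value (mg/dL) with its care setting."""

    hospitalization_id: str
    day: int
    value: float
    setting: Setting

    def __post_init__(self) -> None:
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError(f"creatinine must be positive and finite, got {self.value}")


@dataclass(frozen=True)
class BaselineEstimate:
    value: float
    method: BaselineMethod
    n_contributing: int
    egfr: float
    egfr_stratum: Stratum


@dataclass(frozen=True)
class AkiAdjudication:
    positive: bool
    stage: int  # 0 = none
    trigger: Trigger
    trigger_day: int | None
    peak_ratio: float
    peak_value: float
    #: False when no post-operative creatinine and no RRT were available:
    #: a negative-by-absence that eligibility should drop, not a firm negative.
    evaluable: bool = True


def egfr_japanese(scr: float, age: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73 m^2) by the Japanese equation.

    eGFR = 194 * SCr^-1.094 * age^-0.287, multiplied by 0.739 for women.
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    if age < 18:
        raise ValueError("equation is validated for adults (age >= 18)")
    egfr = 194.0 * scr**-1.094 * age**-0.287
    if sex == "female":
        egfr *= 0.739
    elif sex != "male":
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return egfr


def egfr_to_scr(egfr: float, age: float, sex: str) -> float:
    """Invert the Japanese eGFR equation for SCr (closed form: the equation
    is a monotone power law in creatinine)."""
    if egfr <= 0:
        raise ValueError("eGFR must be positive")
    k = 194.0 * age**-0.287 * (0.739 if sex == "female" else 1.0)
    return (egfr / k) ** (-1.0 / 1.094)


def egfr_stratum(egfr: float) -> Stratum:
    if egfr >= 60.0:
        return Stratum.GE60
    if egfr >= 30.0:
        return Stratum.S30_TO_59
    if egfr >= 15.0:
        return Stratum.S15_TO_29
    return Stratum.LT15


def daily_max(measurements: Iterable[CreatinineMeasurement]) -> list[CreatinineMeasurement]:
    """Collapse repeat same-day tests to the highest value.

    One value is kept per (hospitalization, day, setting); output is sorted
    by day. The highest same-day value governs AKI assessment.
    """
    best: dict[tuple[str, int, Setting], CreatinineMeasurement] = {}
    for m in measurements:
        key = (m.hospitalization_id, m.day, m.setting)
        if key not in best or m.value > best[key].value:
            best[key] = m
    return sorted(best.values(), key=lambda m: (m.hospitalization_id, m.day, m.setting.value))


class BaselineUnavailableError(ValueError):
    """No qualifying creatinine for the requested baseline definition.

    Eligibility treats this as an exclusion, not a failure.
    """


def compute_baseline(
    measurements: Sequence[CreatinineMeasurement],
    surgery_day: int,
    method: BaselineMethod | str = BaselineMethod.MEAN_OUTPATIENT_7_365,
    *,
    age: float = 60.0,
    sex: str = "male",
) -> BaselineEstimate:
    """Baseline SCr for one hospitalization under the chosen definition.

    ``age`` and ``sex`` feed the eGFR attached to the estimate (used for the
    low-eGFR exclusion and for subgrouping).
    """
    method = BaselineMethod(method)
    if method is BaselineMethod.LATEST_INPATIENT_PRESURGERY:
        pool = [m for m in measurements if m.setting is Setting.INPATIENT and m.day < surgery_day]
    else:
        pool = [
            m
            for m in measurements
            if m.setting is Setting.OUTPATIENT and 7 <= surgery_day - m.day <= 365
        ]
    if not pool:
        raise BaselineUnavailableError(
            f"no qualifying creatinine for baseline method {method.value}"
        )
    if method is BaselineMethod.MEAN_OUTPATIENT_7_365:
        value = float(np.mean([m.value for m in pool]))
        n = len(pool)
    else:
        latest = max(pool, key=lambda m: m.day)
        value, n = latest.value, 1
    egfr = egfr_japanese(value, age, sex)
    return BaselineEstimate(value, method, n, egfr, egfr_stratum(egfr))


def _window_days(window: DetectionWindow, surgery_day: int) -> float:
    return surgery_day + 7 if window is DetectionWindow.DAYS_0_TO_7 else math.inf


def adjudicate_aki(
    postop: Sequence[CreatinineMeasurement],
    baseline: BaselineEstimate,
    rrt_days: Sequence[int],
    surgery_day: int,
    window: DetectionWindow | str = DetectionWindow.THROUGH_DISCHARGE,
    scr4_requires_aki: bool = True,
    absolute_comparator: str = "rolling",
) -> AkiAdjudication:
    """Adjudicate AKI presence, stage and trigger for one hospitalization.

    ``postop`` must already be daily-max reduced, with all days >=
    ``surgery_day``. Rules applied inside the detection window:

    * relative rise: any value >= 1.5x baseline; stage from the peak ratio
      band ([1.5, 2.0) -> 1, [2.0, 3.0) -> 2, [3.0, inf) -> 3);
    * absolute rise: a value exceeding by >= 0.3 mg/dL the minimum of all
      values in the preceding 2 calendar days (inclusive), where the
      baseline estimate is treated as observed on the surgery day
      (``absolute_comparator="rolling"``, the KDIGO-faithful reading), or a
      value within 2 days of surgery exceeding the baseline by >= 0.3
      (``absolute_comparator="baseline"``); stage >= 1;
    * SCr >= 4.0 mg/dL promotes to stage 3, by default only when a rise
      rule also fires (``scr4_requires_aki``);
    * RRT initiation on any day in the window is stage 3.

    The trigger is the rule firing on the earliest day; same-day ties go to
    the higher-stage rule, then to the relative rule.
    """
    window = DetectionWindow(window)
    if absolute_comparator not in ("rolling", "baseline"):
        raise ValueError("absolute_comparator must be 'rolling' or 'baseline'")
    last_day = _window_days(window, surgery_day)

    obs = sorted((m for m in postop if m.day <= last_day), key=lambda m: m.day)
    if any(m.day < surgery_day for m in postop):
        raise ValueError("post-operative measurements must not precede surgery")
    rrt_in = sorted(d for d in rrt_days if surgery_day <= d <= last_day)

    if not obs and not rrt_in:
        return AkiAdjudication(False, 0, Trigger.NONE, None, 0.0, 0.0, evaluable=False)

    b = baseline.value
    # (day, stage, trigger) events; the pseudo-baseline is anchored at surgery_day
    events: list[tuple[int, int, Trigger]] = []
    rise_fired = False
    for j, m in enumerate(obs):
        ratio = m.value / b
        if ratio >= RELATIVE_RISE_FACTOR:
            stage = 3 if ratio >= STAGE3_FACTOR else 2 if ratio >= STAGE2_FACTOR else 1
            events.append((m.day, stage, Trigger.RELATIVE_RISE))
            rise_fired = True
        if absolute_comparator == "rolling":
            cands = [
                p.value for p in obs[:j] if m.day - p.day <= ROLLING_WINDOW_DAYS
            ]
            if m.day - surgery_day <= ROLLING_WINDOW_DAYS:
                cands.append(b)
            comparator = min(cands) if cands else None
        else:
            comparator = b if m.day - surgery_day <= ROLLING_WINDOW_DAYS else None
        if comparator is not None and m.value - comparator >= ABSOLUTE_RISE_MG_DL:
            events.append((m.day, 1, Trigger.ABSOLUTE_RISE))
            rise_fired = True

    scr4_events = [
        (m.day, 3, Trigger.SCR_GE4) for m in obs if m.value >= SCR_STAGE3_MG_DL
    ]
    if scr4_events and (rise_fired or not scr4_requires_aki):
        events.extend(scr4_events)
    events.extend((d, 3, Trigger.RRT) for d in rrt_in)

    peak_value = max((m.value for m in obs), default=0.0)
    peak_ratio = peak_value / b if obs else 0.0
    if not events:
        return AkiAdjudication(False, 0, Trigger.NONE, None, peak_ratio, peak_value)

    stage = max(s for _, s, _ in events)
    first_day = min(d for d, _, _ in events)
    rank = {
        Trigger.RELATIVE_RISE: 0,
        Trigger.RRT: 1,
        Trigger.SCR_GE4: 2,
        Trigger.ABSOLUTE_RISE: 3,
    }
    day_events = [e for e in events if e[0] == first_day]
    day_events.sort(key=lambda e: (-e[1], rank[e[2]]))
    trigger = day_events[0][2]
    return AkiAdjudication(True, stage, trigger, first_day, peak_ratio, peak_value)


def adjudicate_cohort(
    hospitalizations: pd.DataFrame,
    measurements: pd.DataFrame,
    procedures: pd.DataFrame,
    *,
    baseline_method: BaselineMethod | str = BaselineMethod.MEAN_OUTPATIENT_7_365,
    window: DetectionWindow | str = DetectionWindow.THROUGH_DISCHARGE,
    scr4_requires_aki: bool = True,
    absolute_comparator: str = "rolling",
    rrt_codes: tuple[str, ...] = ("J038", "J042"),
) -> pd.DataFrame:
    """Run baseline estimation and AKI adjudication for every hospitalization.

    Expects the CSV-dialect tables produced by :mod:`akival.synthetic` (or
    equivalently structured real extracts). Returns one row per
    hospitalization with the adjudication, the baseline value/method and the
    baseline eGFR stratum; hospitalizations without a computable baseline or
    without any post-operative data are flagged rather than dropped.
    """
    meas_by_h = {k: g for k, g in measurements.groupby("hospitalization_id")}
    proc_by_h = {k: g for k, g in procedures.groupby("hospitalization_id")}
    rows = []
    for rec in hospitalizations.itertuples(index=False):
        hid = rec.hospitalization_id
        surgery_day = min(int(d) for d in str(rec.surgery_days).split(";"))
        g = meas_by_h.get(hid)
        ms = (
            [
                CreatinineMeasurement(hid, int(r.day), float(r.value), Setting(r.setting))
                for r in g.itertuples(index=False)
            ]
            if g is not None
            else []
        )
        ms = daily_max(ms)
        try:
            base = compute_baseline(
                ms, surgery_day, baseline_method, age=rec.age, sex=rec.sex
            )
        except BaselineUnavailableError:
            rows.append(
                {
                    "hospitalization_id": hid,
                    "evaluable": False,
                    "positive": False,
                    "stage": 0,
                    "trigger": Trigger.NONE.value,
                    "trigger_day": np.nan,
                    "peak_ratio": np.nan,
                    "peak_value": np.nan,
                    "baseline_value": np.nan,
                    "baseline_method": BaselineMethod(baseline_method).value,
                    "baseline_n": 0,
                    "baseline_egfr": np.nan,
                    "egfr_stratum": "",
                }
            )
            continue
        postop = [m for m in ms if m.setting is Setting.INPATIENT and m.day >= surgery_day]
        pg = proc_by_h.get(hid)
        rrt_days = (
            [int(r.day) for r in pg.itertuples(index=False) if r.code in rrt_codes]
            if pg is not None
            else []
        )
        adj = adjudicate_aki(
            postop,
            base,
            rrt_days,
            surgery_day,
            window=window,
            scr4_requires_aki=scr4_requires_aki,
            absolute_comparator=absolute_comparator,
        )
        rows.append(
            {
                "hospitalization_id": hid,
                "evaluable": adj.evaluable,
                "positive": adj.positive,
                "stage": adj.stage,
                "trigger": adj.trigger.value,
                "trigger_day": adj.trigger_day if adj.trigger_day is not None else np.nan,
                "peak_ratio": adj.peak_ratio,
                "peak_value": adj.peak_value,
                "baseline_value": base.value,
                "baseline_method": base.method.value,
                "baseline_n": base.n_contributing,
                "baseline_egfr": base.egfr,
                "egfr_stratum": base.egfr_stratum.value,
            }
        )
    return pd.DataFrame(rows)
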