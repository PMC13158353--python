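"""Inclusion/exclusion cascade for the surgical validation cohort.

A hospitalization enters the analysis when the patient is an adult who
underwent surgery under general anesthesia within 7 days of admission, has
at least one outpatient serum creatinine 7-365 days before surgery (the
baseline pool) and at least one inpatient value within 2 days after
surgery, carries no renal-transplant marker, is not on maintenance dialysis
(dialysis procedure under an ESRD comorbidity at admission, or any dialysis
on or before the surgery day), and has baseline SCr < 4 mg/dL with baseline
eGFR >= 15 mL/min/1.73 m^2. Each criterion is record-intrinsic, so the
final cohort is invariant to ordering; the ordering only attributes counts
in the attrition table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kdigo import (
    BaselineMethod,
    BaselineUnavailableError,
    CreatinineMeasurement,
    Setting,
    compute_baseline,
    daily_max,
)

__all__ = [
    "EXCLUSION_ORDER",
    "AttritionReport",
    "select_index_surgery",
    "apply_eligibility",
]

TRANSPLANT_ICD_PREFIX = "Z940"
TRANSPLANT_PROCEDURES = frozenset({"K780", "K780-2"})
DIALYSIS_PROCEDURES = frozenset({"J038", "J042"})
ESRD_ICD_PREFIX = "N185"  # end-stage renal disease comorbidity at admission

EXCLUSION_ORDER = (
    "under_18",
    "late_surgery",
    "missing_baseline",
    "missing_followup",
    "transplant",
    "dialysis",
    "high_baseline",
)

_LABELS = {
    "under_18": "Age < 18 years",
    "late_surgery": "Surgery > 7 days after admission",
    "missing_baseline": "No outpatient creatinine 7-365 days before surgery",
    "missing_followup": "No creatinine within 2 days after surgery",
    "missing_creatinine": "No qualifying baseline or follow-up creatinine",
    "transplant": "Renal transplant (Z94.0 / K780 / K780-2)",
    "dialysis": "Maintenance or pre-surgery dialysis (J038 / J042)",
    "high_baseline": "Baseline SCr >= 4 mg/dL or eGFR < 15",
}


@dataclass
class AttritionReport:
    """Ordered per-criterion exclusion counts, flowchart-style."""

    initial_n: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (reason, excluded, remaining)

    @property
    def final_n(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "criterion": reason,
                    "label": _LABELS.get(reason, reason),
                    "n_excluded": excl,
                    "n_remaining": rem,
                }
                for reason, excl, rem in self.steps
            ]
        )

    def check_conservation(self) -> bool:
        return self.initial_n == self.final_n + sum(e for _, e, _ in self.steps)


def select_index_surgery(surgery_days) -> int:
    """Index surgery = the first surgery of the hospitalization."""
    days = list(surgery_days)
    if not days:
        raise ValueError("not a surgical hospitalization: no surgery days")
    return int(min(days))


def _normalize(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def _exclusion_reason(
    rec,
    surgery_day: int,
    meas: pd.DataFrame | None,
    diag: pd.DataFrame | None,
    proc: pd.DataFrame | None,
    baseline_method: BaselineMethod,
) -> str | None:
    if rec.age < 18:
        return "under_18"
    if surgery_day - rec.admission_day > 7:
        return "late_surgery"

    if meas is not None and len(meas):
        days = meas["day"].to_numpy()
        outpatient = meas["setting"].to_numpy() == Setting.OUTPATIENT.value
        has_baseline_pool = bool(
            np.any(outpatient & (surgery_day - days >= 7) & (surgery_day - days <= 365))
        )
        has_followup = bool(
            np.any(~outpatient & (days >= surgery_day) & (days <= surgery_day + 2))
        )
    else:
        has_baseline_pool = has_followup = False
    if not has_baseline_pool:
        return "missing_baseline"
    if not has_followup:
        return "missing_followup"

    if diag is not None and len(diag):
        codes = diag["icd10"].map(_normalize)
        if codes.str.startswith(TRANSPLANT_ICD_PREFIX).any():
            return "transplant"
        esrd = bool(
            codes.str.startswith(ESRD_ICD_PREFIX)[
                diag["role"].to_numpy() == "comorbidity_at_admission"
            ].any()
        )
    else:
        esrd = False
    if proc is not None and len(proc):
        pcodes = proc["code"].astype(str)
        if pcodes.isin(TRANSPLANT_PROCEDURES).any():
            return "transplant"
        dialysis = pcodes.isin(DIALYSIS_PROCEDURES)
        if dialysis.any():
            if esrd or bool((proc.loc[dialysis, "day"] <= surgery_day).any()):
                return "dialysis"

    ms = daily_max(
        CreatinineMeasurement(rec.hospitalization_id, int(r.day), float(r.value), Setting(r.setting))
        for r in meas.itertuples(index=False)
    )
    try:
        base = compute_baseline(ms, surgery_day, baseline_method, age=rec.age, sex=rec.sex)
    except BaselineUnavailableError:
        # possible under the latest-inpatient baseline variant even when the
        # outpatient pool exists
        return "missing_baseline"
    if base.value >= 4.0 or base.egfr < 15.0:
        return "high_baseline"
    return None


def apply_eligibility(
    hospitalizations: pd.DataFrame,
    measurements: pd.DataFrame,
    diagnoses: pd.DataFrame,
    procedures: pd.DataFrame,
    *,
    baseline_method: BaselineMethod | str = BaselineMethod.MEAN_OUTPATIENT_7_365,
    group_missing: bool = False,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Apply the cascade; return the eligible hospitalizations and the
    attrition report.

    ``group_missing`` merges the two missing-creatinine rows into one, the
    way selection flowcharts often group them; the cohort is unaffected.
    """
    baseline_method = BaselineMethod(baseline_method)
    meas_by_h = {k: g for k, g in measurements.groupby("hospitalization_id")}
    diag_by_h = {k: g for k, g in diagnoses.groupby("hospitalization_id")}
    proc_by_h = {k: g for k, g in procedures.groupby("hospitalization_id")}

    reasons: dict[str, str] = {}
    for rec in hospitalizations.itertuples(index=False):
        hid = rec.hospitalization_id
        surgery_day = select_index_surgery(
            int(d) for d in str(rec.surgery_days).split(";")
        )
        reason = _exclusion_reason(
            rec,
            surgery_day,
            meas_by_h.get(hid),
            diag_by_h.get(hid),
            proc_by_h.get(hid),
            baseline_method,
        )
        if reason is not None:
            reasons[hid] = reason

    order = list(EXCLUSION_ORDER)
    counts = {r: 0 for r in order}
    for r in reasons.values():
        counts[r] += 1
    if group_missing:
        merged = counts.pop("missing_baseline") + counts.pop("missing_followup")
        i = order.index("missing_baseline")
        order = [r for r in order if not r.startswith("missing_")]
        order.insert(i, "missing_creatinine")
        counts["missing_creatinine"] = merged

    report = AttritionReport(initial_n=len(hospitalizations))
    remaining = report.initial_n
    for r in order:
        remaining -= counts[r]
        report.steps.append((r, counts[r], remaining))

    eligible = hospitalizations[
        ~hospitalizations["hospitalization_id"].isin(reasons)
    ].reset_index(drop=True)
    return eligible, report
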