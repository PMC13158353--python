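"""Adjudicate AKI from a single patient's creatinine series.

Baseline = mean outpatient SCr 7-365 days before surgery; AKI when a
post-operative value reaches 1.5x baseline, rises >= 0.3 mg/dL within 48 h,
or renal replacement therapy starts. Stage from the peak ratio band.
"""

from akival import CreatinineMeasurement, Setting, adjudicate_aki, compute_baseline, daily_max

series = [
    CreatinineMeasurement("H1", -120, 0.92, Setting.OUTPATIENT),
    CreatinineMeasurement("H1", -30, 0.88, Setting.OUTPATIENT),
    CreatinineMeasurement("H1", 0, 0.95, Setting.INPATIENT),   # surgery day
    CreatinineMeasurement("H1", 1, 1.31, Setting.INPATIENT),
    CreatinineMeasurement("H1", 1, 1.26, Setting.INPATIENT),   # same-day repeat
    CreatinineMeasurement("H1", 3, 1.10, Setting.INPATIENT),
]
reduced = daily_max(series)  # highest value per day governs
baseline = compute_baseline(reduced, surgery_day=0, age=64, sex="male")
postop = [m for m in reduced if m.setting is Setting.INPATIENT and m.day >= 0]
adj = adjudicate_aki(postop, baseline, rrt_days=[], surgery_day=0)

print(f"baseline: {baseline.value:.2f} mg/dL from {baseline.n_contributing} outpatient tests"
      f" (eGFR {baseline.egfr:.1f}, stratum {baseline.egfr_stratum.value})")
print(f"AKI: {adj.positive}, stage {adj.stage}, trigger {adj.trigger.value} on day {adj.trigger_day}")
print(f"peak {adj.peak_value:.2f} mg/dL = {adj.peak_ratio:.2f}x baseline")
# Day 1 rises 0.41 mg/dL above the 0.90 baseline within 48 h -> stage 1 via
# the absolute rule (the 1.46x peak ratio stays below the 1.5x relative cut).
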