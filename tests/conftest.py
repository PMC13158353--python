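"""Shared fixtures and the independent brute-force KDIGO oracle.

The oracle enumerates every single value (relative rule) and every ordered
pair of values at most two days apart (absolute rule), deliberately sharing
no code with the package's rolling-minimum implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from akival import CohortConfig, analyze_tables, generate_cohort

# 2x2 cells reconstructed from the published margins (N, reference-positive
# count, index-positive count) plus the printed PPV of each row
RECONSTRUCTED = {
    "overall": (27, 8, 636, 6703),
    "stages_2_3": (21, 14, 138, 7201),
    "cardiovascular": (24, 7, 148, 531),
}


def oracle_adjudicate(
    days,
    values,
    baseline,
    rrt_days,
    surgery_day,
    window_end=None,
    scr4_requires_aki=True,
):
    """Brute-force (positive, stage) adjudication for small fixtures."""
    pts = [
        (d, v)
        for d, v in zip(days, values)
        if window_end is None or d <= window_end
    ]
    rrt = [
        d
        for d in rrt_days
        if d >= surgery_day and (window_end is None or d <= window_end)
    ]

    relative = any(v >= 1.5 * baseline for _, v in pts)
    # ordered pairs within 2 calendar days; the baseline acts as a value
    # observed on the surgery day and may share that day with a measurement
    augmented = [(surgery_day, baseline, True)] + [(d, v, False) for d, v in pts]
    absolute = False
    for di, vi, is_base in augmented:
        for dj, vj in pts:
            earlier = di < dj or (is_base and di == dj)
            if earlier and dj - di <= 2 and vj - vi >= 0.3:
                absolute = True
    scr4 = any(v >= 4.0 for _, v in pts)
    rise = relative or absolute
    scr4_counts = scr4 and (rise or not scr4_requires_aki)

    positive = rise or bool(rrt) or scr4_counts
    if not positive:
        return False, 0
    max_ratio = max((v / baseline for _, v in pts), default=0.0)
    if max_ratio >= 3.0 or rrt or scr4_counts:
        return True, 3
    if max_ratio >= 2.0:
        return True, 2
    return True, 1


def random_fixture(rng: np.random.Generator):
    """One random small adjudication problem (daily-max reduced)."""
    n = int(rng.integers(1, 11))
    days = sorted(rng.choice(np.arange(0, 13), size=n, replace=False).tolist())
    values = rng.uniform(0.2, 6.0, size=n).round(2).tolist()
    values = [max(v, 0.2) for v in values]
    baseline = float(rng.uniform(0.4, 3.5))
    rrt_days = [int(rng.integers(0, 13))] if rng.random() < 0.15 else []
    window_end = 7 if rng.random() < 0.5 else None
    gate = bool(rng.random() < 0.5)
    return days, values, baseline, rrt_days, window_end, gate


@pytest.fixture(scope="session")
def fixed_margin_cohort():
    """Deterministic fixed-margin cohort whose 2x2 matches the
    reconstructed overall table (27/8/636/6703) exactly."""
    cfg = CohortConfig(
        n_patients=7374,
        seed=11,
        allocation="expected",
        prop_emergent=0.0,
        prop_cardiovascular=0.0,
        aki_incidence_by_stratum=663 / 7374,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fixed_margin_result(fixed_margin_cohort):
    return analyze_tables(fixed_margin_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=400, seed=7))
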