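"""Diagnostic accuracy of a binary index test against a reference standard.

Computes the seven 2x2-derived statistics reported in coding-validation
studies — sensitivity, specificity, PPV, NPV, LR+, LR-, and the diagnostic
odds ratio — with 95% confidence intervals: exact (Clopper-Pearson) binomial
intervals for the proportions, the Simel log method for likelihood ratios,
and the Woolf log method for the DOR. Ratio estimates with a zero cell are
flagged and their intervals computed with the Haldane-Anscombe 0.5
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "MetricEstimate",
    "MetricSet",
    "clopper_pearson",
    "build_contingency",
    "compute_metrics",
    "stage_restricted_reference",
    "index_from_codes",
    "subgroup_metrics",
    "format_metric_set",
]

N17_PREFIX = "N17"
EXPANDED_EXACT = ("N19", "N990")  # unspecified renal failure; postprocedural renal failure


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: reference standard (rows) x index test (columns)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_reference_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_index_positive(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """One statistic with its 95% CI.

    ``flag`` is None for a regular estimate, ``"undefined"`` when a required
    margin is zero, ``"infinite"`` for a ratio with a zero denominator cell,
    and ``"zero_cell_corrected"`` when the interval (and, for flagged-infinite
    ratios, nothing else) comes from continuity-corrected cells.
    """

    value: float
    ci_low: float
    ci_high: float
    flag: str | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        return self.value, self.ci_low, self.ci_high


@dataclass(frozen=True)
class MetricSet:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    lr_plus: MetricEstimate
    lr_minus: MetricEstimate
    dor: MetricEstimate
    table: ContingencyTable

    def to_dict(self) -> dict:
        out: dict = {
            "tp": self.table.tp,
            "fp": self.table.fp,
            "fn": self.table.fn,
            "tn": self.table.tn,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv", "lr_plus", "lr_minus", "dor"):
            est: MetricEstimate = getattr(self, name)
            out[name] = est.value
            out[f"{name}_ci_low"] = est.ci_low
            out[f"{name}_ci_high"] = est.ci_high
            out[f"{name}_flag"] = est.flag
        return out


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for x/n.

    Bounds are the beta-distribution quantiles Beta(x, n-x+1) and
    Beta(x+1, n-x); the lower bound is 0 when x=0 and the upper 1 when x=n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n and n >= 1, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def build_contingency(reference: Sequence[bool], index: Sequence[bool]) -> ContingencyTable:
    """Cross-classify aligned per-case reference and index calls."""
    ref = np.asarray(reference, dtype=bool)
    idx = np.asarray(index, dtype=bool)
    if ref.shape != idx.shape:
        raise ValueError(f"length mismatch: reference {ref.shape} vs index {idx.shape}")
    return ContingencyTable(
        tp=int(np.sum(ref & idx)),
        fp=int(np.sum(~ref & idx)),
        fn=int(np.sum(ref & ~idx)),
        tn=int(np.sum(~ref & ~idx)),
    )


def _proportion(x: int, n: int, level: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan, math.nan, math.nan, "undefined")
    lo, hi = clopper_pearson(x, n, level)
    return MetricEstimate(x / n, lo, hi)


def _z(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2))


def _log_interval(estimate: float, se: float, z: float) -> tuple[float, float]:
    return estimate * math.exp(-z * se), estimate * math.exp(z * se)


def _lr_plus(tp: float, fp: float, fn: float, tn: float, z: float) -> tuple[float, float, float]:
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    est = sens / (1 - spec)
    se = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    return (est, *_log_interval(est, se, z))


def _lr_minus(tp: float, fp: float, fn: float, tn: float, z: float) -> tuple[float, float, float]:
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    est = (1 - sens) / spec
    se = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    return (est, *_log_interval(est, se, z))


def _dor(tp: float, fp: float, fn: float, tn: float, z: float) -> tuple[float, float, float]:
    est = (tp * tn) / (fp * fn)
    se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    return (est, *_log_interval(est, se, z))


def _ratio_metric(kind, t: ContingencyTable, z: float) -> MetricEstimate:
    """Evaluate one ratio statistic, falling back to Haldane-Anscombe
    corrected cells when a needed cell is zero."""
    cells = (t.tp, t.fp, t.fn, t.tn)
    if t.n_reference_positive == 0 or t.fp + t.tn == 0:
        return MetricEstimate(math.nan, math.nan, math.nan, "undefined")
    zero_denominator = {
        _lr_plus: t.fp == 0,
        _lr_minus: t.tn == 0,
        _dor: t.fp == 0 or t.fn == 0,
    }[kind]
    numerator_zero = {
        _lr_plus: t.tp == 0,
        _lr_minus: t.fn == 0,
        _dor: t.tp == 0 or t.tn == 0,
    }[kind]
    if zero_denominator or numerator_zero:
        corrected = tuple(c + 0.5 for c in cells)
        _, lo, hi = kind(*corrected, z)
        if zero_denominator:
            return MetricEstimate(math.inf, lo, hi, "infinite")
        # numerator cell zero: the raw estimate is a well-defined 0, only
        # the log-method interval needs corrected cells
        sens = t.tp / t.n_reference_positive
        spec = t.tn / (t.fp + t.tn)
        if kind is _lr_plus:
            raw = sens / (1 - spec)
        elif kind is _lr_minus:
            raw = (1 - sens) / spec
        else:
            raw = (t.tp * t.tn) / (t.fp * t.fn)
        return MetricEstimate(raw, lo, hi, "zero_cell_corrected")
    return MetricEstimate(*kind(*cells, z))


def compute_metrics(t: ContingencyTable, level: float = 0.95) -> MetricSet:
    """All seven accuracy statistics with CIs for one 2x2 table.

    Zero margins flag the affected statistic as undefined instead of
    raising; a zero cell in a ratio flags it infinite (denominator) or
    continuity-corrected (numerator), with intervals from corrected cells.
    """
    if t.total == 0:
        raise ValueError("empty contingency table")
    z = _z(level)
    return MetricSet(
        sensitivity=_proportion(t.tp, t.tp + t.fn, level),
        specificity=_proportion(t.tn, t.fp + t.tn, level),
        ppv=_proportion(t.tp, t.tp + t.fp, level),
        npv=_proportion(t.tn, t.fn + t.tn, level),
        lr_plus=_ratio_metric(_lr_plus, t, z),
        lr_minus=_ratio_metric(_lr_minus, t, z),
        dor=_ratio_metric(_dor, t, z),
        table=t,
    )


def stage_restricted_reference(stages: Sequence[int], min_stage: int) -> np.ndarray:
    """Reference-positive flags when only AKI of at least ``min_stage``
    counts; lower-stage AKI cases become reference-negative and the cohort
    denominator is unchanged."""
    if min_stage not in (1, 2, 3):
        raise ValueError("min_stage must be 1, 2 or 3")
    return np.asarray(stages, dtype=int) >= min_stage


def _normalize_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def code_matches(icd10: str, code_set: str) -> bool:
    """Membership of one (dot-optional) ICD-10 code in the AKI code set.

    ``n17_only`` matches the N17 block by prefix; ``expanded`` adds exact
    N19 (unspecified renal failure) and N99.0 (postprocedural renal
    failure).
    """
    c = _normalize_code(icd10)
    if c.startswith(N17_PREFIX):
        return True
    return code_set == "expanded" and c in EXPANDED_EXACT


def index_from_codes(
    diagnoses: pd.DataFrame,
    case_ids: Sequence,
    code_set: str = "n17_only",
) -> np.ndarray:
    """Per-case index-test calls from the diagnosis table.

    A case is index-positive when any diagnosis recorded in the in-hospital
    complication role matches the code set; comorbidity-at-admission entries
    never count.
    """
    if code_set not in ("n17_only", "expanded"):
        raise ValueError("code_set must be 'n17_only' or 'expanded'")
    if len(diagnoses):
        comp = diagnoses[diagnoses["role"] == "complication_in_hospital"]
        mask = comp["icd10"].map(lambda c: code_matches(c, code_set)).astype(bool)
        positive_ids = set(comp.loc[mask, "hospitalization_id"])
    else:
        positive_ids = set()
    return np.asarray([cid in positive_ids for cid in case_ids], dtype=bool)


def subgroup_metrics(
    reference: Sequence[bool],
    index: Sequence[bool],
    strata: Sequence[str],
    level: float = 0.95,
) -> dict[str, MetricSet]:
    """Per-stratum 2x2 tables and metrics; strata partition the cohort.

    Empty strata never arise from data (every case carries a label) but a
    stratum whose table has zero margins is still emitted, with the affected
    metrics flagged undefined.
    """
    df = pd.DataFrame({"ref": list(reference), "idx": list(index), "stratum": list(strata)})
    out: dict[str, MetricSet] = {}
    for name, g in df.groupby("stratum", sort=True):
        out[str(name)] = compute_metrics(
            build_contingency(g["ref"].to_numpy(), g["idx"].to_numpy()), level
        )
    return out


def _fmt_pct(est: MetricEstimate) -> str:
    if est.flag == "undefined" or math.isnan(est.value):
        return "NE"
    return f"{100 * est.value:.1f} ({100 * est.ci_low:.1f}-{100 * est.ci_high:.1f})"


def _fmt_ratio(est: MetricEstimate, decimals: int) -> str:
    if est.flag in ("undefined", "infinite") or not math.isfinite(est.value):
        return "NE"
    return (
        f"{est.value:.{decimals}f} ({est.ci_low:.{decimals}f}-{est.ci_high:.{decimals}f})"
    )


def format_metric_set(ms: MetricSet) -> dict[str, str]:
    """Report-precision strings: percentages and LR+/DOR to 1 decimal,
    LR- to 2 decimals; non-estimable entries print NE."""
    return {
        "sensitivity": _fmt_pct(ms.sensitivity),
        "specificity": _fmt_pct(ms.specificity),
        "ppv": _fmt_pct(ms.ppv),
        "npv": _fmt_pct(ms.npv),
        "lr_plus": _fmt_ratio(ms.lr_plus, 1),
        "lr_minus": _fmt_ratio(ms.lr_minus, 2),
        "dor": _fmt_ratio(ms.dor, 1),
    }
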