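"""Synthetic EHR cohort generator with known ground truth.

Emulates the structure of a Japanese administrative-claims extract linked
to laboratory data: a hospitalization table, a longitudinal serum
creatinine table (outpatient baseline series 7-365 days before surgery plus
post-operative inpatient trajectories), an ICD-10 diagnosis table with
coding roles, and a procedure table carrying dialysis/transplant codes.
Ground-truth AKI status, stage, and coding behavior are latent variables of
the simulation, so every downstream stage of the validation pipeline can be
tested without access to hospital data.

Construction guarantees (``noise_margin`` > 0): a patient drawn as non-AKI
produces a post-operative trajectory that violates every KDIGO creatinine
rule with margin, while a patient drawn as stage *s* produces a trajectory
(or dialysis procedure) that satisfies exactly the stage-*s* rule against
the realized mean-outpatient baseline with margin. The KDIGO phenotyper
therefore recovers the latent truth exactly, which is the basis of the
round-trip tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig
from .kdigo import egfr_japanese, egfr_to_scr, egfr_stratum

__all__ = ["SyntheticCohort", "generate_cohort", "inject_exclusions", "EXCLUSION_REASONS"]

TABLES = ("hospitalizations", "measurements", "diagnoses", "procedures", "truth")

EXCLUSION_REASONS = (
    "under_18",
    "late_surgery",
    "transplant",
    "dialysis",
    "missing_baseline",
    "missing_followup",
    "high_baseline",
)

# non-cardiovascular fee-schedule categories with cohort weights
_NONCV_CATEGORIES = (
    ("skin_subcutaneous", 132),
    ("musculoskeletal", 1360),
    ("nervous_system_skull", 248),
    ("ophthalmic", 32),
    ("otolaryngology", 186),
    ("face_mouth_neck", 238),
    ("thoracic", 1009),
    ("abdominal", 1736),
    ("urinary_adrenal", 663),
    ("genital", 1060),
)

_N17_CODES = ("N17.0", "N17.1", "N17.2", "N17.8", "N17.9")
_MAIN_DIAGNOSES = ("C18.9", "C34.9", "M16.1", "K80.2", "I35.0", "C61", "K40.9", "J93.1")
_COMORBIDITIES = ("I10", "E11.9", "E78.5", "I48.9", "J44.9")

# eGFR sampling ranges per stratum, kept off the 15/30/60 boundaries so the
# realized (noise-perturbed) baseline cannot cross into the adjacent stratum
# relevant for eligibility (eGFR >= 15)
_EGFR_RANGES = ((62.0, 100.0), (31.0, 58.0), (16.5, 29.0))

_OUTPATIENT_NOISE = 0.03  # multiplicative, keeps realized eGFR >= 15
_SCR_CAP = 3.7  # keeps baseline SCr below the 4 mg/dL exclusion


@dataclass
class SyntheticCohort:
    """The four analysis tables plus the latent truth table."""

    hospitalizations: pd.DataFrame
    measurements: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    truth: pd.DataFrame

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(*(getattr(self, t).copy() for t in TABLES))

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in TABLES:
            p = out_dir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "SyntheticCohort":
        in_dir = Path(in_dir)
        frames = {}
        for name in TABLES:
            p = in_dir / f"{name}.csv"
            if name == "truth" and not p.exists():
                frames[name] = pd.DataFrame(
                    columns=["hospitalization_id", "true_aki", "true_stage", "coded"]
                )
                continue
            frames[name] = pd.read_csv(p, dtype={"icd10": str, "code": str} if name in ("diagnoses", "procedures") else None)
        return cls(**frames)

    def to_csv_bytes(self) -> bytes:
        """All five tables serialized to one byte string (determinism checks)."""
        buf = io.StringIO()
        for name in TABLES:
            buf.write(f"## {name}\n")
            getattr(self, name).to_csv(buf, index=False)
        return buf.getvalue().encode()

    def validate(self) -> None:
        """Check structural invariants; raise AssertionError on violation."""
        hids = set(self.hospitalizations["hospitalization_id"])
        assert set(self.truth["hospitalization_id"]) == hids, "truth/hospitalization id mismatch"
        comp = self.diagnoses[
            (self.diagnoses["role"] == "complication_in_hospital")
            & self.diagnoses["icd10"].str.replace(".", "", regex=False).str.startswith("N17")
        ]
        coded_ids = set(comp["hospitalization_id"])
        truth_coded = set(
            self.truth.loc[self.truth["coded"], "hospitalization_id"]
        )
        assert coded_ids == truth_coded, "coded flag inconsistent with N17 complication entries"


def _largest_remainder(targets: np.ndarray) -> np.ndarray:
    """Integer counts summing to round(sum(targets)), by largest remainder."""
    total = int(round(float(np.sum(targets))))
    floors = np.floor(targets).astype(int)
    short = total - int(np.sum(floors))
    if short > 0:
        order = np.argsort(-(targets - floors))
        floors[order[:short]] += 1
    elif short < 0:
        order = np.argsort(targets - floors)
        floors[order[: -short]] -= 1
    return floors


def _stage1_paths_feasible(b: float, m: float) -> tuple[bool, bool]:
    """(absolute feasible, relative feasible) for a stage-1 trajectory at
    baseline ``b`` without crossing the stage-2 band or the 4 mg/dL stage-3
    promotion threshold."""
    peak_abs = b + 0.3 * (1 + m)
    abs_ok = peak_abs < 1.5 * (1 - m) * b and peak_abs < 4.0 * (1 - m)
    rel_ok = b * 1.5 * (1 + m / 3) < 4.0 * (1 - m)
    return abs_ok, rel_ok


def _stage2_feasible(b: float, m: float) -> bool:
    return b * 2.0 * (1 + m / 3) < 4.0 * (1 - m)


def _postop_days(rng: np.random.Generator, n_post: int) -> tuple[list[int], int]:
    """Post-operative test days (offsets from surgery), always including day
    0; returns (days, length_of_stay_after_surgery)."""
    los = int(max(5, n_post + rng.integers(0, 4)))
    extra = min(n_post - 1, los)
    days = [0]
    if extra > 0:
        days += sorted(rng.choice(np.arange(1, los + 1), size=extra, replace=False).tolist())
    return days, los


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort; deterministic given the config.

    Every generated patient passes the eligibility cascade by construction
    (exclusions are added separately with :func:`inject_exclusions`).
    """
    rng = np.random.default_rng(config.seed)
    m = config.noise_margin
    n = config.n_patients

    hosp_rows, meas_rows, diag_rows, proc_rows, truth_rows = [], [], [], [], []

    if n == 0:
        return SyntheticCohort(
            hospitalizations=pd.DataFrame(
                columns=[
                    "hospitalization_id", "age", "sex", "admission_day", "discharge_day",
                    "surgery_days", "admission_type", "surgery_category",
                ]
            ),
            measurements=pd.DataFrame(columns=["hospitalization_id", "day", "value", "setting"]),
            diagnoses=pd.DataFrame(columns=["hospitalization_id", "icd10", "role"]),
            procedures=pd.DataFrame(columns=["hospitalization_id", "code", "day"]),
            truth=pd.DataFrame(
                columns=["hospitalization_id", "true_aki", "true_stage", "coded", "injected_exclusion"]
            ),
        )

    # --- patient-level draws -------------------------------------------------
    sexes = np.where(rng.random(n) < config.prop_male, "male", "female")
    lo, hi = config.age_range
    ages = np.clip(np.rint(rng.normal(61.8, 15.9, n)), lo, hi).astype(int)
    strata = rng.choice(3, size=n, p=np.asarray(config.egfr_stratum_probs) / sum(config.egfr_stratum_probs))
    emergent = rng.random(n) < config.prop_emergent
    cardiovascular = rng.random(n) < config.prop_cardiovascular
    noncv_names = [c for c, _ in _NONCV_CATEGORIES]
    noncv_w = np.array([w for _, w in _NONCV_CATEGORIES], dtype=float)
    noncv_w /= noncv_w.sum()
    categories = np.where(
        cardiovascular, "cardiovascular", rng.choice(noncv_names, size=n, p=noncv_w)
    )
    surgery_days = np.where(emergent, rng.integers(0, 2, n), rng.integers(1, 4, n))

    # --- AKI allocation ------------------------------------------------------
    cell_key = np.array(
        [
            f"{'cardiovascular' if cv else 'noncardiovascular'},{'emergent' if em else 'planned'}"
            for cv, em in zip(cardiovascular, emergent)
        ]
    )
    aki = np.zeros(n, dtype=bool)
    if config.allocation == "random":
        p = np.array([config.aki_incidence_by_stratum[k] for k in cell_key])
        aki = rng.random(n) < p
    else:
        for key, p in config.aki_incidence_by_stratum.items():
            idx = np.flatnonzero(cell_key == key)
            k = int(round(p * len(idx)))
            if k:
                aki[rng.choice(idx, size=k, replace=False)] = True

    stage = np.zeros(n, dtype=int)
    aki_idx = np.flatnonzero(aki)
    if len(aki_idx):
        if config.allocation == "random":
            stage[aki_idx] = rng.choice([1, 2, 3], size=len(aki_idx), p=config.stage_mix)
        else:
            counts = _largest_remainder(np.asarray(config.stage_mix) * len(aki_idx))
            pool = rng.permutation(aki_idx)
            offset = 0
            for s, c in zip((1, 2, 3), counts):
                stage[pool[offset : offset + c]] = s
                offset += c

    # --- per-patient tables --------------------------------------------------
    realized_stage = np.zeros(n, dtype=int)
    rrt_flag = np.zeros(n, dtype=bool)
    for i in range(n):
        hid = f"H{i:06d}"
        age, sex = int(ages[i]), str(sexes[i])
        s_day = int(surgery_days[i])
        e_lo, e_hi = _EGFR_RANGES[strata[i]]
        scr_base = min(egfr_to_scr(rng.uniform(e_lo, e_hi), age, sex), _SCR_CAP)

        n_out = max(1, int(rng.poisson(config.n_outpatient_baseline_tests)))
        offsets = rng.choice(np.arange(7, 366), size=min(n_out, 359), replace=False)
        out_vals = scr_base * (1 + rng.uniform(-_OUTPATIENT_NOISE, _OUTPATIENT_NOISE, len(offsets)))
        for off, v in zip(offsets, out_vals):
            meas_rows.append((hid, s_day - int(off), float(v), "outpatient"))
        b = float(np.mean(out_vals))

        if s_day >= 1:  # pre-operative in-hospital test the day before surgery
            meas_rows.append((hid, s_day - 1, float(b * (1 + rng.uniform(-0.01, 0.01))), "inpatient"))

        n_post = max(1, int(rng.poisson(config.n_postop_tests)))
        days, los = _postop_days(rng, n_post)

        true_stage = int(stage[i])
        use_rrt = False
        if true_stage == 1:
            abs_ok, rel_ok = _stage1_paths_feasible(b, m)
            if abs_ok and rel_ok:
                path = "absolute" if rng.random() < 0.5 else "relative1"
            elif abs_ok:
                path = "absolute"
            elif rel_ok:
                path = "relative1"
            else:
                true_stage, path = 3, "relative3"  # baseline too high for a clean stage 1
        elif true_stage == 2:
            path = "relative2" if _stage2_feasible(b, m) else "relative3"
            if path == "relative3":
                true_stage = 3
        elif true_stage == 3:
            use_rrt = rng.random() < config.rrt_fraction_stage3
            path = "rrt" if use_rrt else "relative3"
        else:
            path = "none"

        if path in ("none", "rrt"):
            # rule-violating trajectory: bounded drift around baseline
            amp = min(0.2, 0.5 - 1.5 * m, 0.3 * (1 - m) / (2 * b))
            values = {d: b * (1 + rng.uniform(-amp, amp)) for d in days}
        else:
            # stage-1/2 peaks must stay below the 4 mg/dL stage-3 promotion
            # threshold (with margin) as well as inside their ratio band
            scr4_cap = 4.0 * (1 - m) / b
            if path == "absolute":
                peak = b + 0.3 * (1 + m)
            elif path == "relative1":
                hi = min(2.0 * (1 - m / 3), scr4_cap)
                peak = b * rng.uniform(1.5 * (1 + m / 3), hi)
            elif path == "relative2":
                hi = min(3.0 * (1 - m / 3), scr4_cap)
                peak = b * rng.uniform(2.0 * (1 + m / 3), hi)
            else:  # relative3
                peak = b * rng.uniform(3.0 * (1 + m / 3), 3.0 * (1 + m / 3) + 0.8)
            t_peak = int(rng.integers(1, 3))  # day 1 or 2 after surgery
            if t_peak not in days:
                days = sorted(set(days) | {t_peak})
            values = {}
            for d in days:
                if d == 0:
                    values[d] = b
                elif d < t_peak:
                    values[d] = b + 0.45 * (peak - b)
                elif d == t_peak:
                    values[d] = peak
                else:
                    values[d] = b + (peak - b) * float(np.exp(-0.35 * (d - t_peak)))

        for d in sorted(values):
            meas_rows.append((hid, s_day + d, float(values[d]), "inpatient"))
        if use_rrt:
            rrt_day = s_day + int(rng.integers(1, 5))
            proc_rows.append((hid, "J038", rrt_day))
            rrt_flag[i] = True

        discharge = s_day + los + int(rng.integers(0, 3))
        hosp_rows.append(
            (
                hid, age, sex, 0, discharge, str(s_day),
                "emergent" if emergent[i] else "planned", str(categories[i]),
            )
        )
        diag_rows.append((hid, str(rng.choice(_MAIN_DIAGNOSES)), "main"))
        if rng.random() < 0.4:
            diag_rows.append((hid, str(rng.choice(_COMORBIDITIES)), "comorbidity_at_admission"))
        realized_stage[i] = true_stage

    # --- coding assignment ---------------------------------------------------
    true_aki = realized_stage > 0
    coded = np.zeros(n, dtype=bool)
    if config.allocation == "random":
        p_code = np.where(
            true_aki,
            np.array([config.coding_sensitivity_by_stage.get(s, 0.0) for s in realized_stage]),
            1.0 - config.coding_specificity,
        )
        coded = rng.random(n) < p_code
    else:
        for s in (1, 2, 3):
            idx = np.flatnonzero(realized_stage == s)
            k = int(round(config.coding_sensitivity_by_stage[s] * len(idx)))
            if k:
                coded[rng.choice(idx, size=k, replace=False)] = True
        neg = np.flatnonzero(~true_aki)
        k = int(round((1.0 - config.coding_specificity) * len(neg)))
        if k:
            coded[rng.choice(neg, size=k, replace=False)] = True
    for i in np.flatnonzero(coded):
        diag_rows.append(
            (f"H{i:06d}", str(rng.choice(_N17_CODES)), "complication_in_hospital")
        )

    for i in range(n):
        truth_rows.append(
            (f"H{i:06d}", bool(true_aki[i]), int(realized_stage[i]), bool(coded[i]), "")
        )

    return SyntheticCohort(
        hospitalizations=pd.DataFrame(
            hosp_rows,
            columns=[
                "hospitalization_id", "age", "sex", "admission_day", "discharge_day",
                "surgery_days", "admission_type", "surgery_category",
            ],
        ),
        measurements=pd.DataFrame(
            meas_rows, columns=["hospitalization_id", "day", "value", "setting"]
        ),
        diagnoses=pd.DataFrame(diag_rows, columns=["hospitalization_id", "icd10", "role"]),
        procedures=pd.DataFrame(proc_rows, columns=["hospitalization_id", "code", "day"]),
        truth=pd.DataFrame(
            truth_rows,
            columns=["hospitalization_id", "true_aki", "true_stage", "coded", "injected_exclusion"],
        ),
    )


def inject_exclusions(
    cohort: SyntheticCohort, counts: dict[str, int], seed: int
) -> SyntheticCohort:
    """Modify a generated cohort so the requested numbers of patients
    trigger each named exclusion; patients are chosen disjointly, so the
    eligibility cascade removes exactly ``sum(counts.values())`` records.

    Valid reasons: under_18, late_surgery, transplant, dialysis,
    missing_baseline, missing_followup, high_baseline.
    """
    unknown = set(counts) - set(EXCLUSION_REASONS)
    if unknown:
        raise ValueError(
            f"unknown exclusion reason(s) {sorted(unknown)}; valid: {list(EXCLUSION_REASONS)}"
        )
    total = sum(counts.values())
    n = len(cohort.hospitalizations)
    if total > n:
        raise ValueError(f"requested {total} exclusions but cohort has {n} patients")
    out = cohort.copy()
    if total == 0:
        return out

    rng = np.random.default_rng(seed)
    chosen = rng.choice(out.hospitalizations["hospitalization_id"].to_numpy(), size=total, replace=False)
    assignment: dict[str, str] = {}
    pos = 0
    for reason in EXCLUSION_REASONS:
        for _ in range(counts.get(reason, 0)):
            assignment[chosen[pos]] = reason
            pos += 1

    hosp = out.hospitalizations.set_index("hospitalization_id", drop=False)
    meas, diag, proc = out.measurements, out.diagnoses, out.procedures
    drop_meas = np.zeros(len(meas), dtype=bool)
    new_diag, new_proc = [], []

    for hid, reason in assignment.items():
        s_day = min(int(d) for d in str(hosp.at[hid, "surgery_days"]).split(";"))
        sel = meas["hospitalization_id"] == hid
        if reason == "under_18":
            hosp.at[hid, "age"] = int(rng.integers(8, 18))
        elif reason == "late_surgery":
            delta = int(8 + rng.integers(0, 3)) - s_day
            hosp.at[hid, "surgery_days"] = ";".join(
                str(int(d) + delta) for d in str(hosp.at[hid, "surgery_days"]).split(";")
            )
            hosp.at[hid, "discharge_day"] = int(hosp.at[hid, "discharge_day"]) + delta
            meas.loc[sel, "day"] += delta
            proc.loc[proc["hospitalization_id"] == hid, "day"] += delta
        elif reason == "transplant":
            new_diag.append((hid, "Z94.0", "comorbidity_at_admission"))
            new_proc.append((hid, "K780", s_day - 100))
        elif reason == "dialysis":
            new_diag.append((hid, "N18.5", "comorbidity_at_admission"))
            new_proc.append((hid, "J038", s_day - 3))
        elif reason == "missing_baseline":
            drop_meas |= (sel & (meas["setting"] == "outpatient")).to_numpy()
        elif reason == "missing_followup":
            drop_meas |= (
                sel
                & (meas["setting"] == "inpatient")
                & (meas["day"] >= s_day)
                & (meas["day"] <= s_day + 2)
            ).to_numpy()
        elif reason == "high_baseline":
            outp = sel & (meas["setting"] == "outpatient")
            factor = 4.4 / float(meas.loc[outp, "value"].mean())
            meas.loc[sel, "value"] *= max(factor, 1.0)

    out.hospitalizations = hosp.reset_index(drop=True)
    out.measurements = meas[~drop_meas].reset_index(drop=True)
    if new_diag:
        out.diagnoses = pd.concat(
            [diag, pd.DataFrame(new_diag, columns=diag.columns)], ignore_index=True
        )
    if new_proc:
        out.procedures = pd.concat(
            [proc, pd.DataFrame(new_proc, columns=proc.columns)], ignore_index=True
        )
    truth = out.truth.set_index("hospitalization_id", drop=False)
    for hid, reason in assignment.items():
        truth.at[hid, "injected_exclusion"] = reason
    out.truth = truth.reset_index(drop=True)
    return out
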