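"""End-to-end orchestration: simulate/load -> eligibility -> KDIGO
phenotyping -> coding validation, with report tables and a hashed run
manifest so a run can be reproduced and audited from one config file.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import (
    MetricSet,
    build_contingency,
    compute_metrics,
    format_metric_set,
    index_from_codes,
    stage_restricted_reference,
    subgroup_metrics,
)
from .config import RunConfig
from .eligibility import AttritionReport, apply_eligibility
from .kdigo import adjudicate_cohort
from .synthetic import SyntheticCohort, generate_cohort

__all__ = ["AnalysisResult", "analyze_tables", "run_pipeline", "run_sensitivity_suite"]

SENSITIVITY_VARIANTS: dict[str, dict] = {
    # 1: detection window limited to 7 days after surgery
    "sa1_window_7d": {"detection_window": "days_0_to_7"},
    # 2: most recent outpatient value instead of the mean
    "sa2_latest_outpatient": {"baseline_method": "latest_outpatient_7_365"},
    # 3: most recent inpatient value before surgery
    "sa3_latest_inpatient": {"baseline_method": "latest_inpatient_presurgery"},
    # 4: expanded code set (N17.x, N19, N99.0)
    "sa4_expanded_codes": {"code_set": "expanded"},
}


@dataclass
class AnalysisResult:
    """One analysis variant: cohort-level case table, attrition, and the
    Table-2-shaped metric rows."""

    cases: pd.DataFrame  # per-case reference/index/stratum columns
    attrition: AttritionReport
    adjudications: pd.DataFrame
    rows: dict[str, MetricSet]

    def report_frame(self) -> pd.DataFrame:
        n_total = len(self.cases)
        out = []
        for label, ms in self.rows.items():
            t = ms.table
            rec = {
                "row": label,
                "n_total": t.total,
                "n_reference_positive": t.n_reference_positive,
                "pct_reference_positive": round(100 * t.n_reference_positive / t.total, 1)
                if t.total
                else float("nan"),
                "n_index_positive": t.n_index_positive,
                "pct_index_positive": round(100 * t.n_index_positive / t.total, 1)
                if t.total
                else float("nan"),
            }
            rec.update(format_metric_set(ms))
            out.append(rec)
        df = pd.DataFrame(out)
        df.attrs["n_total"] = n_total
        return df

    def report_json(self) -> dict:
        return {label: ms.to_dict() for label, ms in self.rows.items()}


def _load_tables(config: RunConfig) -> SyntheticCohort:
    if config.simulation is not None:
        sim = config.simulation.model_copy(update={"seed": config.seed})
        return generate_cohort(sim)
    try:
        return SyntheticCohort.read_csv(config.input_dir)
    except FileNotFoundError as exc:
        raise OSError(
            f"cannot read input tables from {config.input_dir}: {exc}"
        ) from exc


def analyze_tables(
    tables: SyntheticCohort,
    *,
    baseline_method: str = "mean_outpatient_7_365",
    detection_window: str = "through_discharge",
    code_set: str = "n17_only",
    min_stage: int = 1,
    stratifiers: list[str] | None = ("egfr_stratum", "admission_type", "surgery_cv_vs_noncv"),
    scr4_requires_aki: bool = True,
    absolute_comparator: str = "rolling",
    group_missing: bool = False,
) -> AnalysisResult:
    """Run eligibility, phenotyping and the validity analysis on the four
    tables; pure function of its inputs."""
    eligible, attrition = apply_eligibility(
        tables.hospitalizations,
        tables.measurements,
        tables.diagnoses,
        tables.procedures,
        baseline_method=baseline_method,
        group_missing=group_missing,
    )
    ids = eligible["hospitalization_id"]
    keep = lambda df: df[df["hospitalization_id"].isin(set(ids))]
    adj = adjudicate_cohort(
        eligible,
        keep(tables.measurements),
        keep(tables.procedures),
        baseline_method=baseline_method,
        window=detection_window,
        scr4_requires_aki=scr4_requires_aki,
        absolute_comparator=absolute_comparator,
    )
    adj = adj[adj["evaluable"]].reset_index(drop=True)

    cases = eligible.merge(adj, on="hospitalization_id", how="inner")
    cases["surgery_cv_vs_noncv"] = np.where(
        cases["surgery_category"] == "cardiovascular", "cardiovascular", "noncardiovascular"
    )
    cases["reference"] = stage_restricted_reference(cases["stage"], min_stage)
    cases["index_test"] = index_from_codes(
        keep(tables.diagnoses), cases["hospitalization_id"], code_set
    )

    rows: dict[str, MetricSet] = {}
    rows["overall"] = compute_metrics(
        build_contingency(cases["reference"], cases["index_test"])
    )
    ref23 = stage_restricted_reference(cases["stage"], 2)
    rows["stages_2_3"] = compute_metrics(build_contingency(ref23, cases["index_test"]))
    for strat in stratifiers or []:
        col = {"egfr_stratum": "egfr_stratum", "admission_type": "admission_type",
               "surgery_cv_vs_noncv": "surgery_cv_vs_noncv"}[strat]
        per = subgroup_metrics(cases["reference"], cases["index_test"], cases[col])
        for name, ms in per.items():
            rows[f"{strat}:{name}"] = ms
    return AnalysisResult(cases=cases, attrition=attrition, adjudications=adj, rows=rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_outputs(res: AnalysisResult, out_dir: Path, prefix: str = "") -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    p = out_dir / f"{prefix}attrition.csv"
    res.attrition.to_frame().to_csv(p, index=False)
    files["attrition"] = p
    p = out_dir / f"{prefix}adjudications.csv"
    res.adjudications.to_csv(p, index=False)
    files["adjudications"] = p
    p = out_dir / f"{prefix}report.csv"
    res.report_frame().to_csv(p, index=False)
    files["report"] = p
    p = out_dir / f"{prefix}report.json"
    with open(p, "w") as fh:
        json.dump(res.report_json(), fh, indent=2, sort_keys=True, allow_nan=True)
    files["report_json"] = p
    return files


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute one configured run and write attrition, adjudication and
    report tables plus a manifest with content hashes; identical config and
    seed produce byte-identical outputs."""
    tables = _load_tables(config)
    res = analyze_tables(
        tables,
        baseline_method=config.baseline_method,
        detection_window=config.detection_window,
        code_set=config.code_set,
        min_stage=config.min_stage,
        stratifiers=config.stratifiers,
        scr4_requires_aki=config.scr4_requires_aki,
        absolute_comparator=config.absolute_comparator,
        group_missing=config.group_missing,
    )
    out_dir = Path(config.out_dir)
    files = _write_outputs(res, out_dir)
    p = out_dir / "eligible_cohort.csv"
    res.cases.to_csv(p, index=False)
    files["eligible_cohort"] = p
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "versions": {
            "akival": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": {
            "hospitalizations_read": len(tables.hospitalizations),
            "excluded": res.attrition.initial_n - res.attrition.final_n,
            "analyzed": len(res.cases),
            "reference_positive": int(res.cases["reference"].sum()),
            "index_positive": int(res.cases["index_test"].sum()),
        },
        "files": {name: _sha256(path) for name, path in files.items()},
    }
    mp = out_dir / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = mp
    return files


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every file listed in a run manifest; True when all match."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    names = {
        "attrition": "attrition.csv",
        "adjudications": "adjudications.csv",
        "report": "report.csv",
        "report_json": "report.json",
        "eligible_cohort": "eligible_cohort.csv",
    }
    return all(
        _sha256(out_dir / names[name]) == digest
        for name, digest in manifest["files"].items()
    )


def run_sensitivity_suite(config: RunConfig) -> dict[str, dict[str, Path]]:
    """Main analysis plus the four pre-registered variants: 7-day detection
    window, latest-outpatient baseline, latest-inpatient baseline, and the
    expanded (N17.x/N19/N99.0) code set."""
    tables = _load_tables(config)
    out_dir = Path(config.out_dir)
    base_kwargs = dict(
        baseline_method=config.baseline_method,
        detection_window=config.detection_window,
        code_set=config.code_set,
        min_stage=config.min_stage,
        stratifiers=config.stratifiers,
        scr4_requires_aki=config.scr4_requires_aki,
        absolute_comparator=config.absolute_comparator,
        group_missing=config.group_missing,
    )
    all_files: dict[str, dict[str, Path]] = {}
    res = analyze_tables(tables, **base_kwargs)
    all_files["main"] = _write_outputs(res, out_dir, prefix="main_")
    for name, overrides in SENSITIVITY_VARIANTS.items():
        kwargs = {**base_kwargs, **overrides}
        res = analyze_tables(tables, **kwargs)
        all_files[name] = _write_outputs(res, out_dir, prefix=f"{name}_")
    return all_files
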