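"""Configuration models for cohort simulation and pipeline runs."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# Defaults mirror the validation cohort this package emulates: N = 7,374
# adult surgical hospitalizations, overall creatinine-defined AKI incidence
# ~9.0% with a 504/82/77 stage split, 35 coded cases (stage-dependent coding
# sensitivity, specificity 6703/6711), 46.8% men, eGFR strata 73.7/24.5/1.9%,
# 1.5% emergent admissions and 9.6% cardiovascular surgery.
_STAGE_MIX = (504 / 663, 82 / 663, 77 / 663)
_CODING_SENS = {1: 6 / 504, 2: 21 / 159, 3: 21 / 159}

#: Per-(surgery x admission) AKI incidence chosen so the implied margins
#: reproduce the reported subgroup prevalences (cardiovascular 24%,
#: non-cardiovascular 7.4%, emergent 31%, planned 8.7%, overall 9.0%).
DEFAULT_INCIDENCE = {
    "noncardiovascular,planned": 0.072,
    "cardiovascular,planned": 0.229,
    "noncardiovascular,emergent": 0.248,
    "cardiovascular,emergent": 0.810,
}

_CELLS = frozenset(DEFAULT_INCIDENCE)


class CohortConfig(BaseModel):
    """Parameters of the synthetic EHR cohort generator."""

    n_patients: int = Field(7374, ge=0)
    seed: int = 0
    prop_male: float = Field(0.468, ge=0.0, le=1.0)
    age_range: tuple[int, int] = (18, 95)
    egfr_stratum_probs: tuple[float, float, float] = (0.7368, 0.2446, 0.0186)
    prop_emergent: float = Field(107 / 7374, ge=0.0, le=1.0)
    prop_cardiovascular: float = Field(710 / 7374, ge=0.0, le=1.0)
    aki_incidence_by_stratum: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_INCIDENCE)
    )
    stage_mix: tuple[float, float, float] = _STAGE_MIX
    coding_sensitivity_by_stage: dict[int, float] = Field(
        default_factory=lambda: dict(_CODING_SENS)
    )
    coding_specificity: float = Field(6703 / 6711, ge=0.0, le=1.0)
    rrt_fraction_stage3: float = Field(48 / 77, ge=0.0, le=1.0)
    n_outpatient_baseline_tests: int = Field(3, ge=1)
    n_postop_tests: int = Field(6, ge=1)
    noise_margin: float = Field(0.1, gt=0.0, lt=0.2)
    #: "random" draws Bernoulli outcomes; "expected" allocates deterministic
    #: largest-remainder counts (fixed-margin design) for incidence, stage
    #: mix and coding.
    allocation: Literal["random", "expected"] = "random"

    @field_validator("age_range")
    @classmethod
    def _age_range_valid(cls, v):
        lo, hi = v
        if lo < 18 or hi < lo:
            raise ValueError("age_range must satisfy 18 <= min <= max")
        return v

    @field_validator("egfr_stratum_probs", "stage_mix")
    @classmethod
    def _probs_sum_to_one(cls, v):
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"probability vector must be non-negative and sum to 1, got {v}")
        return v

    @field_validator("aki_incidence_by_stratum", mode="before")
    @classmethod
    def _expand_scalar_incidence(cls, v):
        # a bare number means the same incidence in every cell
        if isinstance(v, (int, float)):
            return {cell: float(v) for cell in _CELLS}
        return v

    @model_validator(mode="after")
    def _check_maps(self):
        if set(self.aki_incidence_by_stratum) != _CELLS:
            raise ValueError(
                f"aki_incidence_by_stratum must have keys {sorted(_CELLS)}"
            )
        for k, p in self.aki_incidence_by_stratum.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"incidence for {k} out of [0,1]: {p}")
        if set(self.coding_sensitivity_by_stage) != {1, 2, 3}:
            raise ValueError("coding_sensitivity_by_stage must have keys {1, 2, 3}")
        for s, p in self.coding_sensitivity_by_stage.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"coding sensitivity for stage {s} out of [0,1]: {p}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)


class RunConfig(BaseModel):
    """One reproducible pipeline run: either simulate a cohort or read the
    four CSV tables, then phenotype, select, and validate."""

    input_dir: Optional[Path] = None
    simulation: Optional[CohortConfig] = None
    baseline_method: Literal[
        "mean_outpatient_7_365", "latest_outpatient_7_365", "latest_inpatient_presurgery"
    ] = "mean_outpatient_7_365"
    detection_window: Literal["through_discharge", "days_0_to_7"] = "through_discharge"
    code_set: Literal["n17_only", "expanded"] = "n17_only"
    min_stage: Literal[1, 2, 3] = 1
    stratifiers: list[Literal["egfr_stratum", "admission_type", "surgery_cv_vs_noncv"]] = Field(
        default_factory=lambda: ["egfr_stratum", "admission_type", "surgery_cv_vs_noncv"]
    )
    scr4_requires_aki: bool = True
    absolute_comparator: Literal["rolling", "baseline"] = "rolling"
    group_missing: bool = False
    out_dir: Path = Path("akival_run")
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_dir or simulation")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
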