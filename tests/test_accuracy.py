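"""Diagnostic-accuracy statistics: 2x2 construction, exact and log-method
intervals, code-set logic, subgroup partitioning."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from akival import (
    ContingencyTable,
    build_contingency,
    clopper_pearson,
    compute_metrics,
    format_metric_set,
    index_from_codes,
    stage_restricted_reference,
    subgroup_metrics,
)

from conftest import RECONSTRUCTED


class TestContingency:
    def test_perfect_agreement(self):
        t = build_contingency([True, False], [True, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)

    def test_enumerated(self):
        t = build_contingency([True, True, False, False], [False, False, True, False])
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 1, 2, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_contingency([True], [True, False])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 1)


class TestClopperPearson:
    def test_closed_form_at_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_boundary_at_n(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10))

    @pytest.mark.parametrize("x,n", [(27, 663), (1, 50), (250, 500), (499, 500)])
    def test_matches_statsmodels_beta(self, x, n):
        lo, hi = clopper_pearson(x, n)
        s_lo, s_hi = proportion_confint(x, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(s_lo, abs=1e-12)
        assert hi == pytest.approx(s_hi, abs=1e-12)

    def test_domain_errors(self):
        for bad in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson(*bad)
        with pytest.raises(ValueError):
            clopper_pearson(1, 2, level=1.0)


class TestMetrics:
    def test_degenerate_perfect_test(self):
        ms = compute_metrics(ContingencyTable(5, 0, 0, 5))
        assert ms.sensitivity.value == 1.0
        assert ms.specificity.value == 1.0
        assert ms.lr_plus.flag == "infinite" and math.isinf(ms.lr_plus.value)
        # fn = 0: LR- has a well-defined 0 estimate, interval corrected
        assert ms.lr_minus.value == 0.0
        assert ms.lr_minus.flag == "zero_cell_corrected"
        assert ms.dor.flag == "infinite"

    @pytest.mark.parametrize("cells", list(RECONSTRUCTED.values()))
    def test_dor_identity(self, cells):
        ms = compute_metrics(ContingencyTable(*cells))
        assert ms.dor.value == pytest.approx(
            ms.lr_plus.value / ms.lr_minus.value, abs=1e-9 * ms.dor.value
        )

    @pytest.mark.parametrize("cells", list(RECONSTRUCTED.values()))
    def test_prevalence_odds_identity(self, cells):
        ms = compute_metrics(ContingencyTable(*cells))
        t = ms.table
        prev = t.n_reference_positive / t.total
        lhs = ms.ppv.value / (1 - ms.ppv.value)
        rhs = ms.lr_plus.value * prev / (1 - prev)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_ci_brackets_estimate(self):
        for cells in RECONSTRUCTED.values():
            ms = compute_metrics(ContingencyTable(*cells))
            for name in ("sensitivity", "specificity", "ppv", "npv",
                         "lr_plus", "lr_minus", "dor"):
                est = getattr(ms, name)
                assert est.ci_low <= est.value <= est.ci_high

    def test_zero_margin_flagged_undefined(self):
        ms = compute_metrics(ContingencyTable(0, 3, 0, 7))
        assert ms.sensitivity.flag == "undefined"
        assert math.isnan(ms.sensitivity.value)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ContingencyTable(0, 0, 0, 0))


class TestStageRestriction:
    def test_min_stage_2_counts_only_severe(self):
        stages = [0, 1, 2, 3]
        ref = stage_restricted_reference(stages, 2)
        assert ref.tolist() == [False, False, True, True]

    def test_min_stage_1_is_identity_with_overall(self):
        stages = [0, 1, 2, 3, 0]
        assert stage_restricted_reference(stages, 1).tolist() == [
            s > 0 for s in stages
        ]

    def test_all_negative(self):
        assert not stage_restricted_reference([0, 0], 3).any()

    def test_invalid_stage(self):
        with pytest.raises(ValueError):
            stage_restricted_reference([0], 0)


class TestIndexFromCodes:
    def _diag(self, rows):
        return pd.DataFrame(rows, columns=["hospitalization_id", "icd10", "role"])

    def test_complication_n17_positive_both_sets(self):
        d = self._diag([("A", "N17.9", "complication_in_hospital")])
        for cs in ("n17_only", "expanded"):
            assert index_from_codes(d, ["A"], cs).tolist() == [True]

    def test_comorbidity_role_never_counts(self):
        d = self._diag([("A", "N17.0", "comorbidity_at_admission")])
        assert index_from_codes(d, ["A"], "n17_only").tolist() == [False]
        assert index_from_codes(d, ["A"], "expanded").tolist() == [False]

    def test_n990_only_in_expanded_set(self):
        d = self._diag([("A", "N99.0", "complication_in_hospital")])
        assert index_from_codes(d, ["A"], "n17_only").tolist() == [False]
        assert index_from_codes(d, ["A"], "expanded").tolist() == [True]

    def test_dotless_dialect(self):
        d = self._diag([("A", "N170", "complication_in_hospital"),
                        ("B", "N19", "complication_in_hospital")])
        assert index_from_codes(d, ["A", "B"], "n17_only").tolist() == [True, False]
        assert index_from_codes(d, ["A", "B"], "expanded").tolist() == [True, True]

    def test_unknown_code_set(self):
        with pytest.raises(ValueError):
            index_from_codes(self._diag([]), ["A"], "all")


class TestSubgroups:
    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(5)
        n = 500
        ref = rng.random(n) < 0.1
        idx = rng.random(n) < 0.05
        strata = rng.choice(["a", "b", "c"], size=n)
        per = subgroup_metrics(ref, idx, strata)
        assert sum(ms.table.total for ms in per.values()) == n
        assert set(per) == {"a", "b", "c"}

    def test_single_stratum_equals_overall(self):
        ref = [True, False, True, False]
        idx = [True, False, False, False]
        per = subgroup_metrics(ref, idx, ["only"] * 4)
        overall = compute_metrics(build_contingency(ref, idx))
        assert per["only"].to_dict() == overall.to_dict()


class TestReportFormatting:
    def test_printed_precision(self):
        ms = compute_metrics(ContingencyTable(*RECONSTRUCTED["overall"]))
        fmt = format_metric_set(ms)
        assert fmt["sensitivity"] == "4.1 (2.7-5.9)"
        assert fmt["lr_minus"] == "0.96 (0.95-0.98)"

    def test_not_estimable_marker(self):
        # fp = 0, as in low-eGFR subgroups: LR+ prints NE
        ms = compute_metrics(ContingencyTable(5, 0, 31, 100))
        fmt = format_metric_set(ms)
        assert fmt["lr_plus"] == "NE"
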