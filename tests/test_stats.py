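"""Agreement statistics and mixed-effects grade models."""

import math

import numpy as np
import pandas as pd
import pytest

from achrf import (EstimationError, EyeRecord, ParameterError, compare_groups,
                   grade_model, icc_agreement, pearson, summarize_by_grade)
from achrf.stats import grade_to_step

GRADES = [0, 0.5, 1, 2, 3, 4]


def _record(i, grade, count, eye="OD", group="uveitis", age=40.0, sex="F",
            patient=None):
    return EyeRecord(patient or f"p{i}", eye, group, grade, count,
                     age_years=age, sex=sex)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 5])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_affine_anticorrelation(self):
        x = np.array([1.0, 2, 3, 5])
        assert pearson(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # r = sum((x-mx)(y-my)) / sqrt(sum(x-mx)^2 sum(y-my)^2) = 4/5
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(EstimationError):
            pearson([1, 1, 1], [1, 2, 3])


class TestICCAgreement:
    def test_identical_vectors_give_one(self):
        x = np.array([1.0, 5, 9, 13, 2, 8])
        assert icc_agreement(x, x).icc == 1.0

    def test_matches_balanced_anova_closed_form(self, rng):
        x = rng.normal(20, 8, size=12)
        y = x + rng.normal(0, 1, size=12)
        got = icc_agreement(x, y).icc
        # independent oracle: two-way ANOVA mean squares, k = 2 raters
        n, k = len(x), 2
        v = np.stack([x, y])
        grand = v.mean()
        msr = k * ((v.mean(axis=0) - grand) ** 2).sum() / (n - 1)
        mse = ((v - v.mean(axis=0) - v.mean(axis=1)[:, None] + grand) ** 2).sum() \
            / ((n - 1) * (k - 1))
        sb2 = (msr - mse) / k
        assert got == pytest.approx(sb2 / (sb2 + mse), abs=1e-8)

    def test_matches_reference_consistency_icc(self, rng):
        import pingouin as pg
        x = rng.normal(10, 4, size=15)
        y = 0.9 * x + rng.normal(0, 1.5, size=15)
        got = icc_agreement(x, y).icc
        df = pd.DataFrame({
            "targets": np.tile(np.arange(15), 2),
            "raters": np.repeat(["a", "b"], 15),
            "ratings": np.concatenate([x, y]),
        })
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="ratings").set_index("Type")
        assert got == pytest.approx(float(table.loc["ICC(C,1)", "ICC"]), abs=1e-10)

    def test_independent_vectors_near_zero(self, rng):
        # no shared subject effect: sigma_b ~ 0, ICC ~ 0 up to sampling noise
        iccs = [icc_agreement(rng.normal(0, 1, 200), rng.normal(0, 1, 200)).icc
                for _ in range(20)]
        assert np.mean(iccs) < 0.15

    def test_grade_covariate_absorbs_grade_means(self, rng):
        # counts driven entirely by grade; after adjustment ICC reflects only
        # the within-grade subject signal, which is absent here
        grades = np.repeat(GRADES, 10)
        x = 50.0 * np.array([grade_to_step(g) for g in grades]) + rng.normal(0, 2, 60)
        y = 50.0 * np.array([grade_to_step(g) for g in grades]) + rng.normal(0, 2, 60)
        unadjusted = icc_agreement(x, y).icc
        adjusted = icc_agreement(x, y, grades).icc
        assert unadjusted > 0.99
        assert adjusted < 0.5

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            icc_agreement([1, 2], [1, 2])


class TestGradeModel:
    def test_noiseless_slope_recovered_exactly(self, rng):
        records = [_record(i, GRADES[i % 6], 5 + 38 * grade_to_step(GRADES[i % 6]),
                           age=float(rng.integers(10, 70)), sex="FM"[i % 2])
                   for i in range(24)]
        result = grade_model(records, "raw")
        assert result.slope_per_grade == pytest.approx(38.0, abs=1e-6)

    def test_constructed_log_effect(self):
        # count + 1 = exp(a + b step) with b = ln(3.93) -> +293 % per step
        b = math.log(3.93)
        records = [_record(i, GRADES[i % 6],
                           max(0, round(math.exp(2.5 + b * grade_to_step(GRADES[i % 6])) - 1)))
                   for i in range(30)]
        result = grade_model(records, "log1p")
        assert result.pct_change_per_grade == pytest.approx(293.0, rel=0.02)
        assert result.pct_change_per_grade == \
            pytest.approx(100 * (math.exp(result.log_slope) - 1))

    def test_order_invariance(self, rng):
        records = [_record(i, GRADES[i % 6],
                           int(10 * grade_to_step(GRADES[i % 6]) + rng.integers(0, 5)),
                           age=float(rng.integers(10, 70)), sex="FM"[i % 2])
                   for i in range(30)]
        forward = grade_model(records, "raw")
        backward = grade_model(records[::-1], "raw")
        assert forward.slope_per_grade == pytest.approx(backward.slope_per_grade)
        assert forward.log_slope == pytest.approx(backward.log_slope)

    def test_matches_ols_when_no_between_patient_variance(self, rng):
        # one eye per patient and no patient effect: fixed effects equal the
        # normal-equations solution
        import statsmodels.api as sm
        records = [_record(i, GRADES[i % 6],
                           int(8 * grade_to_step(GRADES[i % 6]) + rng.integers(0, 6)),
                           age=float(rng.integers(10, 70)), sex="FM"[i % 2])
                   for i in range(36)]
        result = grade_model(records, "raw")
        steps = np.array([grade_to_step(r.sun_grade) for r in records], dtype=float)
        design = np.column_stack([
            np.ones(36), steps,
            [r.age_years for r in records],
            [1.0 if r.sex == "M" else 0.0 for r in records],
        ])
        counts = np.array([r.auto_count for r in records], dtype=float)
        beta = np.linalg.solve(design.T @ design, design.T @ counts)
        assert result.slope_per_grade == pytest.approx(beta[1], abs=1e-6)

    def test_single_grade_rejected(self):
        records = [_record(i, 1, 10) for i in range(6)]
        with pytest.raises(EstimationError, match="singular"):
            grade_model(records)


class TestCompareGroups:
    @staticmethod
    def _paired_groups(swap=False):
        records = []
        for i in range(10):
            ga, gb = ("control", "uveitis") if swap else ("uveitis", "control")
            records.append(_record(i, 0, 2 + (i % 3), group=ga, age=30.0 + i,
                                   patient=f"a{i}"))
            records.append(_record(i, 0, i % 2, group=gb, age=30.0 + i,
                                   patient=f"b{i}"))
        return records

    def test_identical_data_zero_difference(self):
        records = []
        for i in range(8):
            records.append(_record(i, 0, i % 4, group="uveitis", age=30.0 + i,
                                   patient=f"u{i}"))
            records.append(_record(i, 0, i % 4, group="control", age=30.0 + i,
                                   patient=f"c{i}"))
        diff, p = compare_groups(records)
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_label_swap_negates_difference(self):
        d1, _ = compare_groups(self._paired_groups(False))
        d2, _ = compare_groups(self._paired_groups(True))
        assert d1 == pytest.approx(-d2, rel=1e-6)

    def test_nonzero_grade_uveitis_rejected(self):
        records = [_record(0, 1, 5, group="uveitis"),
                   _record(1, 0, 0, group="control"),
                   _record(2, 0, 1, group="control")]
        with pytest.raises(ParameterError, match="grade 0"):
            compare_groups(records)


class TestSummarizeByGrade:
    def test_single_record_degenerate(self):
        table = summarize_by_grade([_record(0, 1, 7)])
        row = table.iloc[0]
        assert row["n"] == 1 and row["median"] == 7 and row["q1"] == row["q3"] == 7

    def test_linear_interpolation_quantiles(self):
        records = [_record(i, 0, c) for i, c in enumerate([0, 2, 4])]
        row = summarize_by_grade(records).iloc[0]
        assert row["median"] == 2 and (row["q1"], row["q3"]) == (1.0, 3.0)

    def test_partition_preserves_total(self, rng):
        records = [_record(i, GRADES[int(rng.integers(0, 6))], int(rng.integers(0, 30)))
                   for i in range(40)]
        table = summarize_by_grade(records)
        assert table["n"].sum() == 40
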