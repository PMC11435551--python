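"""Metrology layer: SEM, MDD95, effect size, ICC(3,k) against independent
oracles, classification bins, and the report aggregation rules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from insolegait.io import NormalizedForceCurve
from insolegait.reliability import (
    MDD95_FACTOR,
    EffectSizeInputs,
    SemInputs,
    aggregate_report,
    anova_decompose,
    classify_es,
    classify_icc,
    curve_sem,
    effect_size,
    icc_3k,
    mdd95,
    sem,
    sem_percent,
)
from insolegait.simulate import simulate_parameter_table


class TestSem:
    def test_identical_trial_variances(self):
        assert sem(SemInputs((4.0, 4.0, 4.0), mean=10.0)) == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        # mean of (4, 16, 25) is 15
        assert sem(SemInputs((4.0, 16.0, 25.0), mean=10.0)) == pytest.approx(np.sqrt(15))

    def test_zero_variances(self):
        assert sem(SemInputs((0.0, 0.0, 0.0), mean=10.0)) == 0.0

    @given(st.permutations([4.0, 16.0, 25.0]))
    @settings(deadline=None)
    def test_invariant_under_trial_permutation(self, variances):
        assert sem(SemInputs(tuple(variances), mean=1.0)) == pytest.approx(np.sqrt(15))

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            SemInputs((4.0,), mean=1.0)

    def test_percent_scaling(self):
        assert sem_percent(0.31, 8.13) == pytest.approx(3.813, abs=0.001)
        assert sem_percent(6.77, 408.3) == pytest.approx(1.658, abs=0.001)
        with pytest.raises(ZeroDivisionError):
            sem_percent(1.0, 0.0)


class TestMdd95:
    def test_factor_is_196_sqrt2(self):
        assert MDD95_FACTOR == pytest.approx(2.771859, abs=1e-6)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, max_examples=50)
    def test_ratio_machine_precision(self, s):
        assert mdd95(s) / s == pytest.approx(MDD95_FACTOR, rel=1e-12)

    def test_zero_sem(self):
        assert mdd95(0.0) == 0.0

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            mdd95(-1.0)


class TestCurveSem:
    def _curves(self, rng, n, sd, base=8.0):
        return [
            NormalizedForceCurve(np.clip(base + rng.normal(0, sd, 101), 0, None))
            for _ in range(n)
        ]

    def test_identical_curves_give_zero(self):
        c = NormalizedForceCurve(np.full(101, 8.0))
        assert curve_sem([[c, c, c], [c, c], [c, c, c]]) == 0.0

    def test_recovers_injected_noise_sd(self):
        rng = np.random.default_rng(3)
        trials = [self._curves(rng, 1000, 0.5) for _ in range(3)]
        assert curve_sem(trials) == pytest.approx(0.5, rel=0.05)

    def test_invariant_under_cycle_permutation(self):
        rng = np.random.default_rng(4)
        trials = [self._curves(rng, 20, 0.3) for _ in range(3)]
        shuffled = [list(reversed(t)) for t in trials]
        assert curve_sem(trials) == pytest.approx(curve_sem(shuffled), rel=1e-12)

    def test_single_cycle_trial_rejected(self):
        c = NormalizedForceCurve(np.full(101, 8.0))
        with pytest.raises(ValueError, match="trial 1"):
            curve_sem([[c, c], [c]])


class TestEffectSize:
    def test_equal_means_give_zero(self):
        assert effect_size(EffectSizeInputs(5.0, 5.0, 2.0)) == 0.0

    def test_signed_not_absolute(self):
        assert effect_size(EffectSizeInputs(583.8, 706.9, 11.5)) < 0

    @given(
        st.floats(-100, 100), st.floats(-100, 100), st.floats(0.1, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_antisymmetric_in_means(self, a, b, s):
        x = effect_size(EffectSizeInputs(a, b, s))
        y = effect_size(EffectSizeInputs(b, a, s))
        assert x == pytest.approx(-y, abs=1e-9)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            EffectSizeInputs(1.0, 2.0, 0.0)


def _oracle_icc3k(X: np.ndarray) -> float:
    """Independent ICC(3,k) via projection residuals (double centering)."""
    n, k = X.shape
    row = X.mean(axis=1, keepdims=True)
    col = X.mean(axis=0, keepdims=True)
    grand = X.mean()
    resid = X - row - col + grand
    ems = (resid**2).sum() / ((n - 1) * (k - 1))
    bms = k * ((row - grand) ** 2).sum() / (n - 1)
    return (bms - ems) / bms


class TestIcc3k:
    def test_identical_columns_give_one(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert icc_3k(X) == pytest.approx(1.0)

    def test_columns_differing_by_constants_give_one(self):
        X = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]], float)
        assert icc_3k(X) == pytest.approx(1.0, abs=1e-12)

    def test_matches_projection_oracle_on_random_matrices(self):
        rng = np.random.default_rng(100)
        for _ in range(200):
            X = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
            assert icc_3k(X) == pytest.approx(_oracle_icc3k(X), abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        for _ in range(10):
            X = rng.normal(size=(8, 3)) + 2 * rng.normal(size=(8, 1))
            n, k = X.shape
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "trial": np.tile(np.arange(k), n),
                    "y": X.ravel(),
                }
            )
            res = pingouin.intraclass_corr(
                df, targets="subject", raters="trial", ratings="y"
            )
            want = float(res.loc[res.Type == "ICC(C,k)", "ICC"].iloc[0])
            assert icc_3k(X) == pytest.approx(want, abs=1e-10)

    def test_recovers_population_value(self):
        y, pop = simulate_parameter_table(1.0, 1.0, 500, 3, seed=2024)
        assert pop == pytest.approx(0.75)
        assert icc_3k(y) == pytest.approx(pop, abs=0.05)

    def test_listwise_deletion_and_missing_limit(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3)) + rng.normal(size=(50, 1))
        X_miss = X.copy()
        X_miss[0, 1] = np.nan
        assert icc_3k(X_miss, max_missing_fraction=0.1) == pytest.approx(icc_3k(X[1:]))
        X_bad = X.copy()
        X_bad[:20, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            icc_3k(X_bad, max_missing_fraction=0.1)

    def test_degenerate_bms_rejected(self):
        with pytest.raises(ZeroDivisionError):
            icc_3k(np.zeros((4, 3)))

    def test_anova_preconditions(self):
        with pytest.raises(ValueError):
            anova_decompose(np.zeros((1, 3)))


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.85, "very good"), (0.95, "very good"), (0.70, "good"),
            (0.50, "moderate"), (0.10, "poor"), (-0.2, "poor"),
            (0.80, "very good"), (0.60, "good"), (0.40, "moderate"),
        ],
    )
    def test_icc_bins_with_boundary_policy(self, value, label):
        assert classify_icc(value) == label

    @pytest.mark.parametrize(
        "value,label",
        [
            (1.5, "very large"), (-10.7, "very large"), (1.0, "large"),
            (0.6, "moderate"), (0.3, "small"), (0.1, "very small"),
            (-0.1, "very small"), (1.2, "very large"), (0.8, "large"),
            (0.5, "moderate"), (0.2, "small"),
        ],
    )
    def test_es_bins_on_magnitude(self, value, label):
        assert classify_es(value) == label


class TestAggregation:
    def test_mdd_row_uses_max_sem_across_feet(self, full_run):
        report = aggregate_report(list(full_run.values()))
        cells, summary = report.cells, report.summary
        row = summary[
            (summary.parameter == "stance_ms")
            & (summary.condition_group == "TDM6-SYM-MGAIT")
        ].iloc[0]
        feet_sems = cells[
            (cells.parameter == "stance_ms") & (cells.condition == "TDM6-SYM-MGAIT")
        ]["sem"]
        assert row.sem_max == pytest.approx(feet_sems.max())
        assert row.mdd95 == pytest.approx(MDD95_FACTOR * feet_sems.max())

    def test_pooled_asym_group_uses_max_over_conditions(self, full_run):
        report = aggregate_report(list(full_run.values()))
        cells, summary = report.cells, report.summary
        row = summary[
            (summary.parameter == "swing_ms")
            & (summary.condition_group == "TDM6-ASYM-MGAIT")
        ].iloc[0]
        asym_sems = cells[
            (cells.parameter == "swing_ms") & cells.condition.str.contains("ASYM")
        ]["sem"]
        assert row.sem_max == pytest.approx(asym_sems.max())

    def test_es_census_percentages_sum_to_100(self, full_run):
        report = aggregate_report(list(full_run.values()))
        for pair, sub in report.es_census.groupby("pair"):
            assert sub.percent.sum() == pytest.approx(100.0)

    def test_single_condition_report_has_no_effect_sizes(self, full_run):
        report = aggregate_report([full_run["TDM6-SYM-GROUND"]])
        assert report.effect_sizes.empty

    def test_one_cell_per_parameter_foot_condition(self, full_run):
        report = aggregate_report(list(full_run.values()))
        counts = report.cells.groupby(["parameter", "foot", "condition"]).size()
        assert (counts == 1).all()

    def test_mdd_identity_in_every_cell(self, full_run):
        report = aggregate_report(list(full_run.values()))
        assert np.allclose(
            report.cells.mdd95, MDD95_FACTOR * report.cells["sem"], rtol=1e-12
        )
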