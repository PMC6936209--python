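import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guanrank import (
    SurvivalLabel,
    auc_at_time,
    censoring_km,
    concordance_index,
    evaluate,
    integrated_auc,
    km_eval,
)

from conftest import random_labels


def labels_from(times, statuses):
    return [SurvivalLabel(f"s{i}", float(t), int(s))
            for i, (t, s) in enumerate(zip(times, statuses))]


def brute_force_auc(risk, times, statuses, t):
    """Unweighted case/control AUC oracle, valid on censor-free data."""
    cases = [i for i in range(len(risk)) if statuses[i] == 1 and times[i] <= t]
    controls = [j for j in range(len(risk)) if times[j] > t]
    total = 0.0
    for i in cases:
        for j in controls:
            total += (risk[i] > risk[j]) + 0.5 * (risk[i] == risk[j])
    return total / (len(cases) * len(controls))


class TestConcordance:
    def test_perfect_ranking_on_worked_cohort(self, toy_labels):
        risk = [1.0, 1 / 2.75, 1.25 / 2.75, 0.0]
        assert concordance_index(risk, toy_labels) == 1.0

    def test_reversed_ranking(self, toy_labels):
        risk = [0.0, 1.0, 0.5, 2.0]
        assert concordance_index([-r for r in [0.0, 1.0, 0.5, 2.0]],
                                 toy_labels) == 1 - concordance_index(
            [0.0, 1.0, 0.5, 2.0], toy_labels)

    def test_constant_risk_is_half(self, toy_labels):
        assert concordance_index([0.7] * 4, toy_labels) == 0.5

    def test_anticoncordant_is_zero(self):
        labels = labels_from([1, 2, 3], [1, 1, 1])
        assert concordance_index([0.1, 0.2, 0.3], labels) == 0.0

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], labels_from([5, 9], [0, 0]))

    def test_matches_lifelines_on_random_censored_data(self):
        from lifelines.utils import concordance_index as ll_ci

        rng = np.random.default_rng(7)
        for _ in range(5):
            labels = random_labels(rng, 80, 0.4)
            risk = rng.random(80)
            t = np.array([lab.time for lab in labels])
            s = np.array([lab.status for lab in labels])
            assert concordance_index(risk, labels) == pytest.approx(
                ll_ci(t, -risk, s)
            )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = random_labels(rng, 40, 0.3)
        risk = rng.random(40)
        base = concordance_index(risk, labels)
        assert concordance_index(np.exp(3 * risk) + 7, labels) == pytest.approx(base)


class TestCensoringKM:
    def test_all_events_curve_is_flat_one(self):
        curve = censoring_km(labels_from([1, 2, 3], [1, 1, 1]))
        assert km_eval(curve, 50.0) == 1.0

    def test_all_censored_is_empirical(self):
        curve = censoring_km(labels_from([1, 2, 3], [0, 0, 0]))
        np.testing.assert_allclose(curve.surv, [2 / 3, 1 / 3, 0.0])

    def test_flips_worked_cohort(self, toy_labels):
        curve = censoring_km(toy_labels)
        # censorings at 2 and 4 become the events: steps 2/3 then 0
        np.testing.assert_allclose(curve.times, [2, 4])
        np.testing.assert_allclose(curve.surv, [2 / 3, 0.0])


class TestAUCAtTime:
    def test_perfect_separation(self):
        labels = labels_from([1, 2, 3, 10, 11, 12], [1] * 6)
        risk = [6, 5, 4, 3, 2, 1]
        assert auc_at_time(risk, labels, 5.0) == 1.0

    def test_constant_risk_is_half(self):
        labels = labels_from([1, 2, 3, 10, 11], [1] * 5)
        assert auc_at_time([1.0] * 5, labels, 5.0) == 0.5

    def test_six_patient_worked_example(self):
        labels = labels_from([1, 2, 3, 4, 5, 6], [1] * 6)
        assert auc_at_time([6, 5, 4, 3, 2, 1], labels, 3.0) == 1.0
        # swapping the risks of patients 1 and 6 breaks five case/control
        # pairs: case 1 now loses to all three controls, and cases 2 and 3
        # additionally lose to control 6
        swapped = [1, 5, 4, 3, 2, 6]
        expected = brute_force_auc(swapped, [1, 2, 3, 4, 5, 6], [1] * 6, 3.0)
        assert expected == 4 / 9
        assert auc_at_time(swapped, labels, 3.0) == pytest.approx(expected)

    def test_undefined_without_cases_or_controls(self):
        labels = labels_from([10, 20], [1, 1])
        assert np.isnan(auc_at_time([1, 2], labels, 5.0))
        assert np.isnan(auc_at_time([1, 2], labels, 50.0))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_equals_brute_force_on_censor_free_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        times = rng.integers(1, 60, size=n).astype(float)
        risk = rng.random(n)
        labels = labels_from(times, np.ones(n))
        t = float(np.quantile(times, 0.5))
        if (times <= t).sum() == 0 or (times > t).sum() == 0:
            return
        assert auc_at_time(risk, labels, t) == pytest.approx(
            brute_force_auc(risk, times, np.ones(n), t)
        )

    def test_close_to_scikit_survival_ipcw_estimate(self):
        from sksurv.metrics import cumulative_dynamic_auc

        rng = np.random.default_rng(1)
        n = 120
        t = rng.integers(1, 60, n).astype(float)
        s = rng.integers(0, 2, n)
        s[t >= 50] = 1  # keep the censoring survival positive at case times
        risk = rng.random(n)
        labels = labels_from(t, s)
        y = np.array(list(zip(s.astype(bool), t)),
                     dtype=[("event", bool), ("time", float)])
        horizons = [10.0, 20.0, 30.0]
        theirs, _ = cumulative_dynamic_auc(y, y, risk, horizons)
        mine = [auc_at_time(risk, labels, h) for h in horizons]
        np.testing.assert_allclose(mine, theirs, atol=0.01)


class TestIntegratedAUC:
    def test_constant_auc_integrates_to_itself(self):
        rng = np.random.default_rng(3)
        times = rng.integers(200, 900, size=200).astype(float)
        labels = labels_from(times, np.ones(200))
        grid = integrated_auc([0.5] * 200, labels)
        np.testing.assert_allclose(grid.auc, 0.5)
        assert grid.integrated == pytest.approx(0.5)
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_perfect_ranking_integrates_to_one(self):
        rng = np.random.default_rng(4)
        # exponential horizon scale chosen so the 14-22 month grid spans the bulk
        times = rng.exponential(550.0, size=200) + 1.0
        labels = labels_from(times, np.ones(200))
        grid = integrated_auc(-times, labels)
        assert grid.integrated == pytest.approx(1.0)

    def test_integral_lies_between_grid_extremes(self):
        rng = np.random.default_rng(5)
        labels = random_labels(rng, 150, 0.3)
        times = np.array([lab.time for lab in labels])
        risk = -times + rng.normal(0, 20, 150)
        months = np.quantile(times, [0.2, 0.4, 0.6, 0.8]) / 30.44
        grid = integrated_auc(risk, labels, eval_times_months=months)
        assert grid.auc.min() - 1e-12 <= grid.integrated <= grid.auc.max() + 1e-12

    def test_unusable_grid_points_dropped_with_renormalization(self, caplog):
        times = np.concatenate([np.full(30, 500.0), np.full(30, 550.0)])
        labels = labels_from(times, np.ones(60))
        with caplog.at_level("WARNING", logger="guanrank"):
            grid = integrated_auc(np.linspace(1, 0, 60), labels,
                                  eval_times_months=[1.0, 17.0, 18.5])
        assert len(grid.auc) < 3
        assert grid.weights.sum() == pytest.approx(1.0)

    def test_error_when_every_point_undefined(self):
        labels = labels_from([1000.0, 2000.0], [1, 1])
        with pytest.raises(ValueError, match="every grid point"):
            integrated_auc([0.1, 0.9], labels, eval_times_months=[1.0])


class TestEvaluate:
    def test_bundles_worked_cohort(self, toy_labels):
        # month grid placed inside the toy follow-up window (days 1-4)
        report = evaluate([1.0, 0.36, 0.45, 0.0], toy_labels,
                          eval_times_months=[0.05, 0.1], days_per_month=30.44)
        assert report.c_index == 1.0

    def test_constant_risk_reports_half(self):
        rng = np.random.default_rng(6)
        times = rng.integers(300, 800, size=100).astype(float)
        labels = labels_from(times, np.ones(100))
        report = evaluate([1.0] * 100, labels)
        assert report.c_index == 0.5
        assert report.integrated_auc == pytest.approx(0.5)

    def test_flat_tsv_serialization(self, toy_labels, tmp_path):
        report = evaluate([1.0, 0.36, 0.45, 0.0], toy_labels,
                          eval_times_months=[0.05, 0.1])
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "metric\tvalue"
        assert any(line.startswith("c_index\t1.0") for line in lines)
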