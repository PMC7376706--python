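"""ROC construction, AUC routes, Youden cutoffs, CIs and legend counts."""

import numpy as np
import pytest

from cytoroc import (
    auc_ci_hanley_mcneil,
    auc_mannwhitney,
    auc_trapezoid,
    correctly_predicted,
    roc_curve,
    youden_optimal_cutoff,
)
from cytoroc.diagnostics import confusion_at_cutoff, summarize
from conftest import make_labeled


def _random_cohort(rng):
    n1, n0 = rng.integers(2, 25, size=2)
    # coarse integer levels force heavy ties
    pos = rng.integers(0, 10, n1).astype(float)
    neg = rng.integers(0, 10, n0).astype(float)
    return make_labeled(pos, neg)


class TestCurve:
    def test_candidate_thresholds_are_midpoints(self):
        values, labels = make_labeled([3, 4, 5], [1, 2, 3])
        curve = roc_curve(values, labels)
        assert list(curve.finite_thresholds) == [1.5, 2.5, 3.5, 4.5]
        assert curve.thresholds[0] == -np.inf and curve.thresholds[-1] == np.inf
        assert (curve.tpr[0], curve.fpr[0]) == (1.0, 1.0)
        assert (curve.tpr[-1], curve.fpr[-1]) == (0.0, 0.0)

    def test_rates_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        values, labels = _random_cohort(rng)
        curve = roc_curve(values, labels)
        assert np.all(np.diff(curve.tpr) <= 1e-15)
        assert np.all(np.diff(curve.fpr) <= 1e-15)

    def test_perfect_separation_reaches_corner(self):
        curve = roc_curve(*make_labeled([10, 11], [1, 2]))
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], ["optimal", "optimal"])


class TestAuc:
    def test_worked_example_with_tie(self):
        values, labels = make_labeled([3, 4, 5], [1, 2, 3])
        assert auc_trapezoid(roc_curve(values, labels)) == pytest.approx(8.5 / 9)
        assert auc_mannwhitney(values, labels) == pytest.approx(8.5 / 9)

    def test_degenerate_and_perfect(self):
        same = make_labeled([1, 2, 3], [1, 2, 3])
        assert auc_mannwhitney(*same) == 0.5
        assert auc_mannwhitney(*make_labeled([2], [1])) == 1.0
        assert auc_mannwhitney(*make_labeled([1], [1])) == 0.5

    def test_two_routes_agree_on_random_tied_cohorts(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            values, labels = _random_cohort(rng)
            a_trap = auc_trapezoid(roc_curve(values, labels))
            a_mw = auc_mannwhitney(values, labels)
            assert abs(a_trap - a_mw) <= 1e-12

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        for _ in range(50):
            values, labels = _random_cohort(rng)
            expected = roc_auc_score(labels == "suboptimal", values)
            assert auc_trapezoid(roc_curve(values, labels)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(21)
        values, labels = _random_cohort(rng)
        base = auc_mannwhitney(values, labels)
        assert auc_mannwhitney(np.exp(values / 3.0), labels) == pytest.approx(base)
        assert auc_trapezoid(roc_curve(values**3 + 5 * values, labels)) == (
            pytest.approx(base)
        )

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(31)
        values, labels = _random_cohort(rng)
        flipped = np.where(labels == "suboptimal", "optimal", "suboptimal")
        assert auc_mannwhitney(values, flipped) == pytest.approx(
            1.0 - auc_mannwhitney(values, labels)
        )


class TestYouden:
    def test_tie_broken_toward_smaller_cutoff(self):
        # J = 2/3 at both 2.5 and 3.5; smaller wins (favouring sensitivity)
        res = youden_optimal_cutoff(roc_curve(*make_labeled([3, 4, 5], [1, 2, 3])))
        assert res.cutoff == 2.5
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(2 / 3)

    def test_perfect_separation_midpoint(self):
        res = youden_optimal_cutoff(roc_curve(*make_labeled([10, 11], [1, 2])))
        assert res.cutoff == 6.0 and res.youden_j == pytest.approx(1.0)

    def test_degenerate_single_value(self):
        res = youden_optimal_cutoff(roc_curve(*make_labeled([1], [1])))
        assert res.youden_j == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            values, labels = _random_cohort(rng)
            curve = roc_curve(values, labels)
            res = youden_optimal_cutoff(curve)
            pos = values[labels == "suboptimal"]
            neg = values[labels == "optimal"]
            best_j, best_cut = -2.0, None
            for cut in curve.finite_thresholds:
                j = (pos > cut).mean() + (neg <= cut).mean() - 1.0
                if j > best_j + 1e-12:
                    best_j, best_cut = j, cut
            assert res.cutoff == best_cut
            assert res.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_operating_point_consistent_with_confusion(self):
        rng = np.random.default_rng(13)
        values, labels = _random_cohort(rng)
        res = youden_optimal_cutoff(roc_curve(values, labels))
        s = summarize(confusion_at_cutoff(values, labels, res.cutoff))
        assert res.sensitivity == pytest.approx(s.sensitivity, abs=1e-12)
        assert res.specificity == pytest.approx(s.specificity, abs=1e-12)


class TestIntervalAndCounts:
    def test_hanley_mcneil_reproduces_ca125_interval(self):
        lo, hi = auc_ci_hanley_mcneil(0.767, 56, 53, 0.95)
        assert lo == pytest.approx(0.678, abs=5e-4)
        assert hi == pytest.approx(0.856, abs=5e-4)

    def test_perfect_auc_zero_width(self):
        assert auc_ci_hanley_mcneil(1.0, 10, 10, 0.95) == (1.0, 1.0)

    def test_fasn_interval_closed_form(self):
        lo, hi = auc_ci_hanley_mcneil(0.653, 56, 53, 0.95)
        assert lo == pytest.approx(0.551, abs=5e-4)
        assert hi == pytest.approx(0.755, abs=5e-4)

    @pytest.mark.parametrize(
        "auc, n, expected",
        [(0.767, 109, 84), (0.877, 109, 96), (0.5, 10, 5), (0.653, 109, 71)],
    )
    def test_correctly_predicted_half_up(self, auc, n, expected):
        assert correctly_predicted(auc, n) == expected

    def test_interval_input_validation(self):
        with pytest.raises(ValueError):
            auc_ci_hanley_mcneil(1.2, 10, 10)
        with pytest.raises(ValueError):
            auc_ci_hanley_mcneil(0.5, 10, 10, level=1.5)
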