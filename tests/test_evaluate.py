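import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteopgs import (auc_ci, decile_table, decile_trend_test,
                      empirical_auc, evaluate_contrast, group_summary,
                      logistic_or_per_sd, odds_ratio_2x2, roc_curve,
                      youden_operating_point)


def brute_force_auc(scores, labels):
    """Direct average over all (case, control) pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (cases.size * controls.size)


class TestEmpiricalAuc:
    def test_four_pair_hand_example(self):
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        assert empirical_auc(scores, labels) == pytest.approx(0.75)
        assert empirical_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    def test_perfect_separation_and_total_tie(self):
        labels = np.array([1, 1, 0, 0])
        assert empirical_auc([4, 3, 2, 1], labels) == 1.0
        assert empirical_auc([1, 1, 1, 1], labels) == 0.5

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 5, n).astype(float)  # many ties
            labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            assert empirical_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_negation_complements_auc(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = rng.normal(size=n)
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
        assert empirical_auc(-scores, labels) == pytest.approx(
            1.0 - empirical_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, int), np.zeros(25, int)]
        base = empirical_auc(scores, labels)
        assert empirical_auc(np.exp(scores), labels) == pytest.approx(base)
        assert empirical_auc(3 * scores - 5, labels) == pytest.approx(base)


class TestRocCurve:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(10, int), np.zeros(20, int)]
        roc = roc_curve(scores, labels)
        assert roc.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert roc.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert (np.diff(roc["tpr"]) >= 0).all()
        assert (np.diff(roc["fpr"]) >= 0).all()

    def test_trapezoid_area_equals_mann_whitney(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(6, 60))
            scores = rng.normal(size=n).round(1)  # force some ties
            labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]
            roc = roc_curve(scores, labels)
            area = np.trapezoid(roc["tpr"], roc["fpr"])
            assert area == pytest.approx(
                empirical_auc(scores, labels), abs=1e-12)


class TestAucCi:
    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=80)
        labels = np.r_[np.ones(30, int), np.zeros(50, int)]
        lo, hi = auc_ci(scores, labels)
        assert lo <= empirical_auc(scores, labels) <= hi

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(7)
        widths = []
        for n in (100, 10_000):
            half = n // 2
            scores = np.r_[rng.normal(0.7, 1, half), rng.normal(0, 1, half)]
            labels = np.r_[np.ones(half, int), np.zeros(half, int)]
            lo, hi = auc_ci(scores, labels)
            widths.append(hi - lo)
        assert widths[1] < widths[0] / 5

    def test_bootstrap_close_to_delong(self):
        rng = np.random.default_rng(8)
        scores = np.r_[rng.normal(0.8, 1, 150), rng.normal(0, 1, 150)]
        labels = np.r_[np.ones(150, int), np.zeros(150, int)]
        d = auc_ci(scores, labels, method="delong")
        b = auc_ci(scores, labels, method="bootstrap", n_boot=500, seed=1)
        assert np.allclose(d, b, atol=0.03)

    def test_degenerate_variance_warns_wide(self):
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning):
            lo, hi = auc_ci(scores, labels)
        assert (lo, hi) == (0.0, 1.0)


class TestYouden:
    def test_perfect_classifier(self):
        roc = roc_curve([4, 3, 1, 0], [1, 1, 0, 0])
        _, sens, spec = youden_operating_point(roc)
        assert sens == 1.0 and spec == 1.0

    def test_argmax_property(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=50)
        labels = np.r_[np.ones(20, int), np.zeros(30, int)]
        roc = roc_curve(scores, labels)
        _, sens, spec = youden_operating_point(roc)
        j = sens + spec - 1
        assert (j >= roc["tpr"] - roc["fpr"] - 1e-12).all()


class TestLogisticOrPerSd:
    def test_negation_inverts_or(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-z))).astype(int)
        or1, *_ = logistic_or_per_sd(z, y)
        or2, *_ = logistic_or_per_sd(-z, y)
        assert or2 == pytest.approx(1.0 / or1, rel=1e-6)

    def test_recovers_generative_effect(self):
        rng = np.random.default_rng(11)
        beta = np.log(2.0)
        z = rng.normal(size=5000)
        y = (rng.random(5000) < 1 / (1 + np.exp(-beta * z))).astype(int)
        or_, lo, hi, p = logistic_or_per_sd(z, y)
        se = (np.log(hi) - np.log(lo)) / (2 * 1.959964)
        assert abs(np.log(or_) - beta) < 3 * se
        assert p < 1e-10

    def test_separation_reports_firth(self):
        z = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        with pytest.warns(UserWarning, match="Firth"):
            or_, lo, hi, p = logistic_or_per_sd(z, y)
        assert np.isfinite([or_, lo, hi, p]).all() and or_ > 1


class TestOddsRatio2x2:
    def test_hand_values_and_symmetry(self):
        assert odds_ratio_2x2(10, 10, 10, 10)[0] == pytest.approx(1.0)
        assert odds_ratio_2x2(20, 10, 10, 20)[0] == pytest.approx(4.0)
        or1 = odds_ratio_2x2(20, 10, 10, 20)[0]
        or2 = odds_ratio_2x2(10, 20, 20, 10)[0]
        assert or2 == pytest.approx(1.0 / or1)

    def test_zero_cell_haldane_correction(self):
        or_, lo, hi, _ = odds_ratio_2x2(10, 0, 5, 10)
        assert np.isfinite([or_, lo, hi]).all() and or_ > 1

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(0, 0, 5, 10)


class TestDecileTable:
    def test_even_split_of_one_hundred(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=100)
        labels = np.r_[1, 0, rng.integers(0, 2, 98)]
        table = decile_table(scores, labels)
        assert (table["n"] == 10).all()

    def test_remainder_goes_to_lower_deciles(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=103)
        labels = np.r_[1, 0, rng.integers(0, 2, 101)]
        table = decile_table(scores, labels)
        assert table["n"].tolist() == [11, 11, 11] + [10] * 7

    def test_counts_reconcile_with_cohort(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=97)
        labels = np.r_[1, 0, rng.integers(0, 2, 95)]
        table = decile_table(scores, labels)
        assert table["n_cases"].sum() == labels.sum()
        weighted = (table["case_fraction"] * table["n"]).sum()
        assert weighted == pytest.approx(labels.sum())


class TestDecileTrend:
    def test_flat_fractions_give_p_one(self):
        table = pd.DataFrame({"decile": range(1, 11), "n": [10] * 10,
                              "n_cases": [4] * 10, "n_controls": [6] * 10})
        assert decile_trend_test(table) == 1.0

    def test_strong_monotone_trend_is_significant(self):
        table = pd.DataFrame({
            "decile": range(1, 11), "n": [50] * 10,
            "n_cases": [2, 5, 10, 15, 20, 30, 35, 40, 45, 48]})
        table["n_controls"] = table["n"] - table["n_cases"]
        assert decile_trend_test(table) < 1e-6


class TestGroupSummary:
    def test_translation_equivariance_and_order_statistic(self):
        scores = np.array([1.0, 2.0, 5.0, 0.0, 1.0, 4.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        s = group_summary(scores, labels)
        assert s["median_case"] == 2.0  # odd group {1, 2, 5}
        shifted = group_summary(scores + np.where(labels == 1, 1.0, 0.0),
                                labels)
        assert shifted["median_case"] == s["median_case"] + 1.0
        assert shifted["median_control"] == s["median_control"]


class TestEvaluateContrast:
    def test_report_consistency(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-1.2 * z))).astype(int)
        report = evaluate_contrast(z, y, name="fracture")
        assert report.auc == empirical_auc(z, y)
        assert report.n_cases + report.n_controls == 400
        assert report.decile_table["n"].sum() == 400
        assert 0 <= report.sensitivity <= 1
        assert report.or_per_sd > 1
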