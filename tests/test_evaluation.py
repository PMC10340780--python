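"""Metric panel: exact binomial CIs, confusion arithmetic, AUC, Grad-CAM, strata."""

import math

import numpy as np
import pytest

from pslearn.errors import ConfigurationError
from pslearn.evaluation import (
    ConfusionMatrix,
    auc,
    clopper_pearson,
    grad_cam,
    metrics_from_confusion,
    one_vs_rest_reports,
    stratified_accuracy,
)
from pslearn.insertion import ImageSlice
from pslearn.nn.models import build_classifier


def binomial_tail_inversion(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Independent oracle: invert binomial tail probabilities by bisection,
    using exact integer binomial coefficients."""

    def sf_geq(p):  # P(X >= x | p)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))

    def cdf_leq(p):  # P(X <= x | p)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))

    def bisect(fn, target, increasing):
        lo, hi = 0.0, 1.0
        for _ in range(100):
            mid = (lo + hi) / 2
            if (fn(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else bisect(sf_geq, alpha / 2, increasing=True)
    upper = 1.0 if x == n else bisect(cdf_leq, alpha / 2, increasing=False)
    return lower, upper


class TestClopperPearson:
    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_all_successes_boundary(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 17, 33])
    def test_matches_binomial_tail_inversion(self, n):
        for x in range(n + 1):
            got = clopper_pearson(x, n)
            want = binomial_tail_inversion(x, n)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            clopper_pearson(5, 3)
        with pytest.raises(ConfigurationError):
            clopper_pearson(0, 0)
        with pytest.raises(ConfigurationError):
            clopper_pearson(1, 2, alpha=1.5)

    def test_exact_interval_is_conservative(self):
        """Coverage of the 95% interval at p=0.9, n=100 over 2000 simulations."""
        rng = np.random.default_rng(2024)
        draws = rng.binomial(100, 0.9, size=2000)
        covered = 0
        for x in draws:
            lo, hi = clopper_pearson(int(x), 100)
            covered += lo <= 0.9 <= hi
        assert covered / 2000 >= 0.95


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=50, fp=0, tn=50, fn=0))
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1"):
            assert getattr(rep, name).value == 1.0

    def test_hand_computed_panel(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=8, fn=2, fp=1, tn=9))
        assert rep.sensitivity.value == pytest.approx(0.8)
        assert rep.specificity.value == pytest.approx(0.9)
        assert rep.precision.value == pytest.approx(8 / 9)
        assert rep.accuracy.value == pytest.approx(0.85)
        assert rep.f1.value == pytest.approx(0.8421, abs=1e-4)
        for name in ("accuracy", "sensitivity", "specificity", "precision"):
            m = getattr(rep, name)
            assert m.ci[0] <= m.value <= m.ci[1]

    def test_undefined_precision_reported_absent(self):
        rep = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, tn=9, fn=1))
        assert rep.precision.value is None
        assert "zero denominator" in rep.precision.reason

    def test_f1_is_between_precision_and_sensitivity(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            rep = metrics_from_confusion(ConfusionMatrix(int(tp), int(fp), int(tn), int(fn)))
            lo = min(rep.precision.value, rep.sensitivity.value)
            hi = max(rep.precision.value, rep.sensitivity.value)
            assert lo - 1e-12 <= rep.f1.value <= hi + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            ConfusionMatrix(tp=-1, fp=0, tn=1, fn=0)

    def test_one_vs_rest_reduction_and_macro_average(self):
        y_true = ["a"] * 4 + ["b"] * 4 + ["c"] * 2
        y_pred = ["a", "a", "b", "a", "b", "b", "b", "c", "c", "c"]
        reports = one_vs_rest_reports(y_true, y_pred)
        assert set(reports) == {"a", "b", "c", "macro"}
        # class a: TP=3, FN=1, FP=0, TN=6
        assert reports["a"].sensitivity.value == pytest.approx(0.75)
        assert reports["a"].precision.value == pytest.approx(1.0)
        sens = [reports[c].sensitivity.value for c in "abc"]
        assert reports["macro"].sensitivity.value == pytest.approx(np.mean(sens))


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: concordant pairs + half ties over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 21))
            labels = np.r_[0, 1, rng.integers(0, 2, n - 2)]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        base = auc(scores, labels)
        assert auc(np.exp(5 * scores), labels) == pytest.approx(base)
        assert auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            auc([0.1, 0.9], [1, 1])


class TestGradCam:
    def test_output_contract(self):
        bundle = build_classifier("tinyunet-w4-l2", seed=0)
        bundle.class_names = ("normal", "cancer")
        rng = np.random.default_rng(0)
        img = ImageSlice(rng.normal(50, 30, (32, 32)))
        cam = grad_cam(bundle, img, "cancer")
        assert cam.shape == (32, 32)
        assert cam.min() >= 0.0 and cam.max() <= 1.0
        assert cam.max() == pytest.approx(1.0) or not cam.any()

    def test_repeated_calls_identical(self):
        bundle = build_classifier("tinyunet-w4-l2", seed=1)
        rng = np.random.default_rng(1)
        img = ImageSlice(rng.normal(50, 30, (32, 32)))
        assert np.array_equal(grad_cam(bundle, img, 0), grad_cam(bundle, img, 0))

    def test_requires_classifier(self):
        from pslearn.nn.models import build_segmenter

        with pytest.raises(ConfigurationError):
            grad_cam(build_segmenter("tinyunet-w4-l2"), np.zeros((16, 16)), 0)


class TestStratifiedAccuracy:
    def test_single_stratum_equals_overall(self):
        y_true = ["cancer"] * 6 + ["normal"] * 4
        y_pred = ["cancer"] * 5 + ["normal"] * 5
        sizes = [10.0] * 6 + [float("nan")] * 4
        df = stratified_accuracy(y_true, y_pred, sizes, strata=((0.0, float("inf"), "any"),))
        overall = df[df["stratum"] == "all"].iloc[0]
        assert overall["accuracy"] == pytest.approx(0.9)

    def test_partition_weighted_mean_identity(self):
        rng = np.random.default_rng(3)
        n = 60
        y_true = rng.choice(["cancer", "normal"], n)
        y_pred = rng.choice(["cancer", "normal"], n)
        sizes = np.where(y_true == "cancer", rng.uniform(5, 45, n), np.nan)
        df = stratified_accuracy(y_true, y_pred, sizes)
        parts = df[df["stratum"] != "all"].dropna(subset=["accuracy"])
        weighted = (parts["accuracy"] * parts["n"]).sum() / parts["n"].sum()
        overall = df[df["stratum"] == "all"].iloc[0]["accuracy"]
        assert weighted == pytest.approx(overall)

    def test_empty_stratum_absent_with_reason(self):
        df = stratified_accuracy(["cancer"], ["cancer"], [5.0])
        row = df[df["stratum"].str.startswith("T2")].iloc[0]
        assert np.isnan(row["accuracy"]) and row["reason"] == "empty stratum"
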