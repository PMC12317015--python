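"""Multi-label classification metrics and summary arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualgland import benchmarks
from dualgland.clf import (
    ThresholdConfig,
    balanced_accuracy,
    binarize,
    confusion_counts,
    exact_match_accuracy,
    f1_from_counts,
    accuracy,
    precision,
    recall,
    metric_report,
    minority_report,
    optimize_thresholds,
    robustness_report,
    stratified_split,
)


@pytest.fixture()
def hand_fixture():
    # 4 samples, 2 classes, enumerated by hand
    labels = np.array([[1, 0], [1, 1], [0, 1], [0, 0]])
    preds = np.array([[1, 0], [0, 1], [0, 1], [1, 0]])
    # class 0: TP=1 (s0), FN=1 (s1), FP=1 (s3), TN=1 (s2)
    # class 1: TP=2 (s1,s2), FN=0, FP=0, TN=2 (s0,s3)
    return preds, labels


class TestConfusion:
    def test_hand_enumeration(self, hand_fixture):
        preds, labels = hand_fixture
        c = confusion_counts(preds, labels)
        assert list(c["TP"]) == [1, 2]
        assert list(c["FN"]) == [1, 0]
        assert list(c["FP"]) == [1, 0]
        assert list(c["TN"]) == [1, 2]
        total = c["TP"] + c["TN"] + c["FP"] + c["FN"]
        assert np.all(total == 4)

    def test_perfect_and_all_positive(self, rng):
        labels = (rng.random((20, 5)) > 0.5).astype(int)
        c = confusion_counts(labels, labels)
        assert not c["FP"].any() and not c["FN"].any()
        c2 = confusion_counts(np.ones_like(labels), labels)
        assert not c2["TN"].any()

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_metric_recomputation_property(self, tp, tn, fp, fn):
        c = {"TP": np.array([tp]), "TN": np.array([tn]),
             "FP": np.array([fp]), "FN": np.array([fn])}
        n = tp + tn + fp + fn
        acc, aflag = accuracy(c)
        p, pflag = precision(c)
        r, rflag = recall(c)
        f, _ = f1_from_counts(c)
        if n:
            assert acc[0] == pytest.approx((tp + tn) / n)
        if tp + fp:
            assert p[0] == pytest.approx(tp / (tp + fp))
        else:
            assert p[0] == 0.0 and pflag[0]
        if tp + fn:
            assert r[0] == pytest.approx(tp / (tp + fn))
        if p[0] + r[0] > 0:
            assert f[0] == pytest.approx(2 * p[0] * r[0] / (p[0] + r[0]))


class TestAggregates:
    def test_exact_match(self, hand_fixture):
        preds, labels = hand_fixture
        assert exact_match_accuracy(preds, labels) == 0.5  # samples 0 and 2
        assert exact_match_accuracy(labels, labels) == 1.0
        with pytest.raises(ValueError):
            exact_match_accuracy(np.zeros((0, 2)), np.zeros((0, 2)))

    def test_one_wrong_label_fraction(self):
        labels = np.zeros((10, 19), dtype=int)
        labels[:, 0] = 1
        preds = labels.copy()
        preds[3, 5] = 1
        assert exact_match_accuracy(preds, labels) == pytest.approx(0.9)

    def test_balanced_accuracy_perfect_and_random(self, rng):
        labels = (rng.random((400, 4)) > 0.5).astype(int)
        assert balanced_accuracy(confusion_counts(labels, labels)) == 1.0
        coin = (rng.random((400, 4)) > 0.5).astype(int)
        ba = balanced_accuracy(confusion_counts(coin, labels))
        assert ba == pytest.approx(0.5, abs=0.06)

    def test_balanced_accuracy_prevalence_invariance(self, rng):
        labels = (rng.random((100, 3)) > 0.7).astype(int)
        preds = (rng.random((100, 3)) > 0.6).astype(int)
        ba = balanced_accuracy(confusion_counts(preds, labels))
        # duplicating positive samples rescales prevalence but TPR/TNR per
        # class of the duplicated subset stay the same when duplicating all
        dup = balanced_accuracy(confusion_counts(np.vstack([preds, preds]),
                                                 np.vstack([labels, labels])))
        assert dup == pytest.approx(ba)


class TestThresholds:
    def test_separable_class_lowest_tie(self):
        probs = np.array([[0.9], [0.85], [0.2], [0.1]])
        labels = np.array([[1], [1], [0], [0]])
        cfg = optimize_thresholds(probs, labels)
        # any threshold in (0.2, 0.85] gives F1=1; ties resolve to lowest grid
        assert cfg.thresholds[0] == pytest.approx(0.25)

    def test_degenerate_class_flagged_default(self):
        probs = np.random.default_rng(0).random((10, 2))
        labels = np.zeros((10, 2), dtype=int)
        labels[:5, 0] = 1
        cfg = optimize_thresholds(probs, labels)
        assert 1 in cfg.flags
        assert cfg.thresholds[1] == 0.35

    def test_exhaustive_grid_oracle(self, rng):
        probs = rng.random((10, 3))
        labels = (rng.random((10, 3)) > 0.5).astype(int)
        cfg = optimize_thresholds(probs, labels)
        grid = np.arange(0.25, 0.45 + 0.005, 0.01)
        for c in range(3):
            if labels[:, c].sum() == 0:
                continue
            def f1_at(t):
                pred = probs[:, c] >= t
                tp = (pred & (labels[:, c] == 1)).sum()
                fp = (pred & (labels[:, c] == 0)).sum()
                fn = (~pred & (labels[:, c] == 1)).sum()
                p = tp / (tp + fp) if tp + fp else 0
                r = tp / (tp + fn) if tp + fn else 0
                return 2 * p * r / (p + r) if p + r else 0
            best = max(f1_at(t) for t in grid)
            assert f1_at(cfg.thresholds[c]) == pytest.approx(best)

    def test_threshold_config_validation(self):
        with pytest.raises(ValueError):
            ThresholdConfig(thresholds=np.array([0.0] * 19))


class TestSummaryArithmetic:
    def test_minority_improvement_rows(self):
        rep = minority_report(0.762, 0.881)
        assert round(rep["improvement_ratio"], 3) == 1.156
        rep = minority_report(0.777, 0.896)
        assert round(rep["improvement_pct"], 1) == 15.3
        same = minority_report(0.8, 0.8)
        assert same["improvement_ratio"] == 1.0 and same["improvement_pct"] == 0.0

    def test_minority_ratio_column_regenerates(self):
        # printed ratios occasionally truncate the last digit
        for model, (b, a, _, _) in benchmarks.MINORITY_PERFORMANCE.items():
            ratio = minority_report(b, a)["improvement_ratio"]
            published = {
                "ResNet-50": 1.156, "DenseNet-121": 1.142, "EfficientNet-B3": 1.148,
                "Vision Transformer": 1.173, "MobileNetV3": 1.158,
                "Inception-v4": 1.150, "Swin Transformer": 1.153,
                "ConvNeXt": 1.152, "RegNet-Y": 1.154, "NFNet": 1.152}[model]
            assert ratio == pytest.approx(published, abs=1.1e-3)

    def test_minority_by_gan_percentages(self):
        for name, (b, a) in benchmarks.MINORITY_BY_GAN.items():
            pct = minority_report(b, a)["improvement_pct"]
            published = {"Dual-Gland GAN": 15.3, "ECP-IGANN": 12.8,
                         "GSIP-GAN": 11.2, "MCI-GAN": 9.5, "WGAN": 8.4,
                         "CycleGAN": 7.6, "Conditional GAN": 7.3,
                         "DCGAN": 6.4, "Traditional GAN": 4.5}[name]
            assert pct == pytest.approx(published, abs=0.11)

    def test_robustness_summary(self):
        rep = robustness_report(6.2, 2.7, 74.8, 86.8)
        assert round(rep["gap_reduction_pct"], 1) == 56.5
        assert round(rep["cross_improvement_pct"], 1) == 16.0
        assert round(rep["robustness_score"], 3) == 1.160
        same = robustness_report(5.0, 5.0, 80.0, 80.0)
        assert same["gap_reduction_pct"] == 0.0
        assert same["robustness_score"] == 1.0

    def test_classifier_averages_regenerate(self):
        cols = np.array(list(benchmarks.CLASSIFIER_PERFORMANCE.values()))
        means = cols.mean(axis=0)
        assert round(means[0], 1) == 85.2   # accuracy before
        assert round(means[1], 1) == 92.6   # accuracy after
        assert round(means[2], 3) == 0.847  # F1 before
        assert round(means[3], 3) == 0.922  # F1 after


class TestStratifiedSplit:
    def test_fractions_and_coverage(self, rng):
        primary = rng.integers(0, 5, size=200)
        tr, va, te = stratified_split(primary, seed=1)
        assert len(tr) + len(va) + len(te) == 200
        assert len(set(tr) & set(va)) == 0
        assert abs(len(tr) / 200 - 0.70) < 0.05
        # every class appears in the training split
        assert set(primary[tr]) == set(primary)


class TestMetricReport:
    def test_keys_and_ranges(self, rng):
        probs = rng.random((30, 19))
        labels = (rng.random((30, 19)) > 0.8).astype(int)
        rep = metric_report(probs, labels)
        for key in ("f1_macro", "f1_micro", "balanced_accuracy", "exact_match"):
            assert 0 <= rep[key] <= 1

    def test_binarize_threshold(self):
        probs = np.array([[0.34, 0.36]])
        assert list(binarize(probs, 0.35)[0]) == [0, 1]
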