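"""Multi-label classification metrics and the toy augmentation experiment.

Implements the standard confusion-based metrics (accuracy, precision, recall,
F1) for 19-class multi-label protein-localization predictions, per-class
threshold optimization, minority-class and robustness summaries, and a tiny
MLP classifier harness for before/after-augmentation experiments at desk
scale.

Undefined-denominator cases return 0 together with an explicit flag rather
than NaN.  Macro averaging is the default for per-class summaries; micro
averages are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Dense, LeakyReLU, Sigmoid, Adam
from .genmetrics import f1 as _f1
from .scenes import N_CLASSES


@dataclass
class MultiLabelPredictions:
    probs: np.ndarray   # (n, 19) in [0, 1]
    labels: np.ndarray  # (n, 19) binary

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.probs.shape != self.labels.shape:
            raise ValueError("probs and labels shapes disagree")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


@dataclass
class ThresholdConfig:
    thresholds: np.ndarray = field(default_factory=lambda: np.full(N_CLASSES, 0.35))
    search_range: tuple = (0.25, 0.45)
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(self.thresholds <= 0) or np.any(self.thresholds >= 1):
            raise ValueError("thresholds must lie in (0, 1)")


def binarize(probs: np.ndarray, cfg: ThresholdConfig | float = 0.35) -> np.ndarray:
    thr = cfg.thresholds if isinstance(cfg, ThresholdConfig) else cfg
    return (np.asarray(probs) >= thr).astype(int)


def confusion_counts(preds: np.ndarray, labels: np.ndarray) -> dict:
    """Per-class TP/TN/FP/FN; counts sum to n per class."""
    preds = np.asarray(preds).astype(bool)
    labels = np.asarray(labels).astype(bool)
    return {
        "TP": (preds & labels).sum(axis=0),
        "TN": (~preds & ~labels).sum(axis=0),
        "FP": (preds & ~labels).sum(axis=0),
        "FN": (~preds & labels).sum(axis=0),
    }


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    flag = den == 0
    out = np.where(flag, 0.0, num / np.where(flag, 1.0, den))
    return out, flag


def accuracy(counts):
    v, flag = _safe_div(counts["TP"] + counts["TN"],
                        counts["TP"] + counts["TN"] + counts["FP"] + counts["FN"])
    return v, flag


def precision(counts):
    return _safe_div(counts["TP"], counts["TP"] + counts["FP"])


def recall(counts):
    return _safe_div(counts["TP"], counts["TP"] + counts["FN"])


def f1_from_counts(counts):
    p, pf = precision(counts)
    r, rf = recall(counts)
    denom = p + r
    v, flag = _safe_div(2 * p * r, denom)
    return v, flag | pf | rf


def exact_match_accuracy(preds: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of samples whose complete label vector is predicted exactly."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(np.all(preds == labels, axis=1)))


def balanced_accuracy(counts) -> float:
    """Macro mean over classes of (TPR + TNR) / 2."""
    tpr, _ = _safe_div(counts["TP"], counts["TP"] + counts["FN"])
    tnr, _ = _safe_div(counts["TN"], counts["TN"] + counts["FP"])
    return float(np.mean((tpr + tnr) / 2.0))


def metric_report(probs: np.ndarray, labels: np.ndarray,
                  cfg: ThresholdConfig | float = 0.35) -> dict:
    """Macro and micro multi-label metrics at the given thresholds."""
    preds = binarize(probs, cfg)
    counts = confusion_counts(preds, labels)
    acc, _ = accuracy(counts)
    p, _ = precision(counts)
    r, _ = recall(counts)
    f, _ = f1_from_counts(counts)
    micro = {k: counts[k].sum() for k in counts}
    mp, _ = _safe_div(micro["TP"], micro["TP"] + micro["FP"])
    mr, _ = _safe_div(micro["TP"], micro["TP"] + micro["FN"])
    return {
        "accuracy_macro": float(acc.mean()),
        "precision_macro": float(p.mean()),
        "recall_macro": float(r.mean()),
        "f1_macro": float(f.mean()),
        "precision_micro": float(mp),
        "recall_micro": float(mr),
        "f1_micro": _f1(float(mp), float(mr)),
        "balanced_accuracy": balanced_accuracy(counts),
        "exact_match": exact_match_accuracy(preds, labels),
        "per_class_f1": f,
    }


def optimize_thresholds(probs: np.ndarray, labels: np.ndarray,
                        search_range: tuple = (0.25, 0.45),
                        grid: float = 0.01) -> ThresholdConfig:
    """Per-class threshold maximizing F1 on the given set; grid search over
    ``search_range``, ties resolved to the lowest threshold.  Classes with no
    positive labels keep the 0.35 default and are flagged."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    n_classes = probs.shape[1]
    candidates = np.arange(search_range[0], search_range[1] + grid / 2, grid)
    thresholds = np.full(n_classes, 0.35)
    flags = {}
    for c in range(n_classes):
        y = labels[:, c]
        if y.sum() == 0:
            flags[c] = "no positive labels; default kept"
            continue
        best_f, best_t = -1.0, candidates[0]
        for t in candidates:
            pred = probs[:, c] >= t
            tp = int((pred & (y == 1)).sum())
            fp = int((pred & (y == 0)).sum())
            fn = int((~pred & (y == 1)).sum())
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = _f1(p, r)
            if f > best_f + 1e-12:  # strict improvement: ties keep lowest t
                best_f, best_t = f, t
        thresholds[c] = best_t
    return ThresholdConfig(thresholds=thresholds, search_range=search_range, flags=flags)


# ---------------------------------------------------------------------------
# published-table summary arithmetic
# ---------------------------------------------------------------------------

def minority_report(before_f1, after_f1) -> dict:
    """Minority-class improvement summary.

    improvement_ratio = F1_after / F1_before;
    improvement_pct = 100 * (F1_after - F1_before) / F1_before.
    Scalars or per-class arrays (averaged) are accepted.
    """
    b = float(np.mean(before_f1))
    a = float(np.mean(after_f1))
    if b <= 0:
        raise ValueError("baseline F1 must be positive")
    return {
        "improvement_ratio": a / b,
        "improvement_pct": 100.0 * (a - b) / b,
    }


def robustness_report(gap_before: float, gap_after: float,
                      cross_before: float, cross_after: float) -> dict:
    """Generalization summary: validation-test gap reduction, cross-dataset
    improvement, and the robustness score (cross after/before ratio)."""
    return {
        "gap_reduction_pct": 100.0 * (gap_before - gap_after) / gap_before,
        "cross_improvement_pct": 100.0 * (cross_after - cross_before) / cross_before,
        "robustness_score": cross_after / cross_before,
    }


# ---------------------------------------------------------------------------
# toy before/after-augmentation experiment
# ---------------------------------------------------------------------------

def _scene_features(scenes_or_images, grid: int = 8) -> np.ndarray:
    from scipy import ndimage as ndi

    feats = []
    for s in scenes_or_images:
        img = s.image if hasattr(s, "image") else np.asarray(s, dtype=float)
        parts = [ndi.zoom(ch, (grid / ch.shape[0], grid / ch.shape[1]), order=1).ravel()
                 for ch in img]
        feats.append(np.concatenate(parts))
    return np.asarray(feats)


class TinyClassifier:
    """Tiny multi-label MLP harness (sigmoid outputs, BCE loss, Adam)."""

    def __init__(self, n_features: int, n_classes: int = N_CLASSES,
                 hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = MLP([
            Dense(rng, n_features, hidden, init="kaiming"), LeakyReLU(),
            Dense(rng, hidden, n_classes, init="xavier"), Sigmoid(),
        ])
        self.opt = Adam(self.net, lr=2e-3, beta1=0.9, beta2=0.999, clip_norm=5.0)
        self.rng = rng

    def fit(self, X, Y, epochs: int = 60, batch: int = 32):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        for _ in range(epochs):
            idx = self.rng.permutation(len(X))
            for b0 in range(0, len(X), batch):
                sel = idx[b0:b0 + batch]
                xb, yb = X[sel], Y[sel]
                self.net.zero_grad()
                p = np.clip(self.net.forward(xb, train=True), 1e-7, 1 - 1e-7)
                g = (p - yb) / (p * (1 - p)) / p.size  # d BCE / d p
                self.net.backward(g)
                self.opt.step()
        return self

    def predict_proba(self, X):
        return self.net.forward(np.asarray(X, dtype=float), train=False)


def stratified_split(primary_class: np.ndarray, fractions=(0.70, 0.15, 0.15),
                     seed: int = 0):
    """Index split stratified by primary class (70/15/15 by default)."""
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(primary_class):
        idx = np.where(primary_class == c)[0]
        rng.shuffle(idx)
        n = len(idx)
        n_tr = max(int(round(fractions[0] * n)), 1)
        n_va = int(round(fractions[1] * n))
        train.extend(idx[:n_tr])
        val.extend(idx[n_tr:n_tr + n_va])
        test.extend(idx[n_tr + n_va:])
    return np.array(train), np.array(val), np.array(test)


def toy_experiment(train_scenes, augmenter=None, minority_classes=None,
                   seed: int = 0, epochs: int = 60,
                   n_aug_per_class: int = 20) -> dict:
    """Before/after-augmentation classification experiment.

    Trains the tiny classifier on the original scenes and again on the
    original scenes plus ``augmenter(class_id, n, seed)``-generated minority
    samples, with identical seeds/configs and a 70/15/15 stratified split.
    Returns paired metric reports.
    """
    labels = np.stack([s.class_labels for s in train_scenes]).astype(float)
    primary = labels.argmax(axis=1)
    X = _scene_features(train_scenes)
    tr, va, te = stratified_split(primary, seed=seed)
    if len(te) == 0 or len(va) == 0:
        raise ValueError("dataset too small for a stratified split")

    if minority_classes is None:
        counts = labels[tr].sum(axis=0)
        present = counts > 0
        minority_classes = [int(c) for c in np.where(present & (counts <= np.median(counts[present])))[0]]

    def run(extra_X=None, extra_Y=None):
        Xtr = X[tr] if extra_X is None else np.concatenate([X[tr], extra_X])
        Ytr = labels[tr] if extra_Y is None else np.concatenate([labels[tr], extra_Y])
        model = TinyClassifier(X.shape[1], labels.shape[1], seed=seed)
        model.fit(Xtr, Ytr, epochs=epochs)
        probs_va = model.predict_proba(X[va])
        thr = optimize_thresholds(probs_va, labels[va].astype(int))
        probs_te = model.predict_proba(X[te])
        rep = metric_report(probs_te, labels[te].astype(int), thr)
        mc = [c for c in minority_classes if labels[te][:, c].sum() > 0]
        rep["minority_f1"] = float(np.mean(rep["per_class_f1"][mc])) if mc else 0.0
        rep["per_class_f1"] = rep["per_class_f1"].tolist()
        return rep

    before = run()

    extra_X, extra_Y = None, None
    if augmenter is not None and minority_classes:
        imgs, ys = [], []
        for c in minority_classes:
            gen = augmenter(int(c), n_aug_per_class, seed + 17 * (c + 1))
            for g in gen:
                imgs.append(g)
                y = np.zeros(labels.shape[1])
                y[c] = 1.0
                ys.append(y)
        if imgs:
            extra_X = _scene_features(imgs)
            extra_Y = np.asarray(ys)
    after = run(extra_X, extra_Y)

    result = {"before": before, "after": after,
              "minority_classes": list(map(int, minority_classes))}
    if before["minority_f1"] > 0:
        result["minority_summary"] = minority_report(before["minority_f1"],
                                                     after["minority_f1"])
    return result
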