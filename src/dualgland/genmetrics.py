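"""Generative-model evaluation: FID, IS, SSIM, PSNR, diversity, P/R and the
quality/diversity/combined scoring scheme.

The feature embedder is pluggable; the default is a deterministic analytic
embedder (downsampled channels + per-channel intensity histograms), so the
whole evaluation stack runs without pretrained weights.  Absolute FID/IS
values under the analytic embedder are not comparable to Inception-based
numbers; relative comparisons and all score-aggregation arithmetic are.

Scoring scheme (cohort-relative): each metric is min-max normalized across
the architectures in one report (FID and MS-SSIM inverted since lower is
better), then

    quality  = 0.4 * fid_n + 0.35 * is_n + 0.25 * precision_n
    diversity = 0.6 * msssim_n + 0.4 * recall_n
    combined = sqrt(quality * diversity)

and relative improvement between two combined scores is 100 * (a - b) / b.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# feature embedding
# ---------------------------------------------------------------------------

@dataclass
class FeatureEmbedder:
    """Deterministic analytic image embedder.

    Concatenates each channel downsampled to ``grid`` x ``grid`` with a
    ``bins``-bin intensity histogram per channel.  Every component lies in
    [0, 1] by construction, so the features are used unstandardized.
    """

    grid: int = 8
    bins: int = 16

    def __call__(self, images: np.ndarray) -> np.ndarray:
        imgs = np.asarray(images, dtype=float)
        if imgs.ndim == 3:
            imgs = imgs[None]
        n, c, h, w = imgs.shape
        feats = []
        for img in imgs:
            parts = []
            for ch in img:
                zoom = (self.grid / h, self.grid / w)
                parts.append(ndimage.zoom(ch, zoom, order=1).ravel())
                hist, _ = np.histogram(ch, bins=self.bins, range=(0, 1))
                parts.append(hist / ch.size)
            feats.append(np.concatenate(parts))
        return np.asarray(feats)


# ---------------------------------------------------------------------------
# distribution metrics
# ---------------------------------------------------------------------------

def fid(feats_real: np.ndarray, feats_gen: np.ndarray) -> float:
    """Frechet distance between Gaussian fits of two feature sets:

        ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^(1/2))

    Covariance square root by eigendecomposition with 1e-6 jitter; the result
    is clamped at 0 against numerical noise.  Symmetric in its arguments.
    """
    fr = np.atleast_2d(np.asarray(feats_real, dtype=float))
    fg = np.atleast_2d(np.asarray(feats_gen, dtype=float))
    if fr.shape[1] != fg.shape[1]:
        raise ValueError("feature dimension mismatch")
    if len(fr) < 2 or len(fg) < 2:
        raise ValueError("need at least 2 samples per set")
    mu_r, mu_g = fr.mean(0), fg.mean(0)
    s_r = np.atleast_2d(np.cov(fr, rowvar=False)) + 1e-6 * np.eye(fr.shape[1])
    s_g = np.atleast_2d(np.cov(fg, rowvar=False)) + 1e-6 * np.eye(fg.shape[1])
    val = float(np.sum((mu_r - mu_g) ** 2)
                + np.trace(s_r) + np.trace(s_g) - 2 * _trace_sqrt_product(s_r, s_g))
    return max(val, 0.0)


def _trace_sqrt_product(s_r: np.ndarray, s_g: np.ndarray) -> float:
    """Tr((S_r S_g)^(1/2)) via the symmetric form Tr((S_r^1/2 S_g S_r^1/2)^1/2).

    Both steps are eigendecompositions of symmetric matrices, which stays
    stable for the rank-deficient sample covariances of small feature sets.
    """
    w, v = linalg.eigh(s_r)
    root_r = (v * np.sqrt(np.maximum(w, 0.0))) @ v.T
    m = root_r @ s_g @ root_r
    evals = linalg.eigvalsh((m + m.T) / 2.0)
    return float(np.sum(np.sqrt(np.maximum(evals, 0.0))))


def gaussian_fid(mu_r, sigma_r, mu_g, sigma_g) -> float:
    """FID from population statistics directly (1-D closed form:
    (mu_r-mu_g)^2 + (sigma_r-sigma_g)^2 for scalars)."""
    mu_r, mu_g = np.atleast_1d(mu_r).astype(float), np.atleast_1d(mu_g).astype(float)
    s_r = np.atleast_2d(sigma_r).astype(float)
    s_g = np.atleast_2d(sigma_g).astype(float)
    return float(np.sum((mu_r - mu_g) ** 2)
                 + np.trace(s_r) + np.trace(s_g) - 2 * _trace_sqrt_product(s_r, s_g))


def inception_score(class_probs: np.ndarray) -> float:
    """exp of the mean KL divergence between per-sample class posteriors and
    their marginal; in [1, K] for K classes (nats internally)."""
    p = np.asarray(class_probs, dtype=float)
    if p.ndim != 2 or np.any(p < -1e-12) or np.any(np.abs(p.sum(1) - 1) > 1e-6):
        raise ValueError("rows must be probability distributions")
    p = np.clip(p, 1e-12, 1.0)
    marginal = p.mean(axis=0)
    kl = np.sum(p * (np.log(p) - np.log(marginal)), axis=1)
    return float(np.exp(kl.mean()))


# ---------------------------------------------------------------------------
# image-pair metrics
# ---------------------------------------------------------------------------

def _window_view(x: np.ndarray, win: int):
    h, w = x.shape
    xs = x[: (h // win) * win, : (w // win) * win]
    return xs.reshape(h // win, win, w // win, win).swapaxes(1, 2).reshape(-1, win * win)


def ssim(x: np.ndarray, y: np.ndarray, C1: float = 0.01 ** 2, C2: float = 0.03 ** 2,
         window: int = 8) -> float:
    """Structural similarity index, standard form, averaged over non-
    overlapping ``window`` x ``window`` tiles.  ssim(x, x) = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if x.ndim == 3:
        return float(np.mean([ssim(a, b, C1, C2, window) for a, b in zip(x, y)]))
    win = min(window, *x.shape)
    wx, wy = _window_view(x, win), _window_view(y, win)
    mx, my = wx.mean(1), wy.mean(1)
    vx, vy = wx.var(1), wy.var(1)
    cxy = ((wx - mx[:, None]) * (wy - my[:, None])).mean(1)
    s = ((2 * mx * my + C1) * (2 * cxy + C2)) / ((mx ** 2 + my ** 2 + C1) * (vx + vy + C2))
    return float(s.mean())


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    """10 * log10(MAX^2 / MSE); +inf for identical inputs."""
    mse = float(np.mean((np.asarray(x, float) - np.asarray(y, float)) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / mse))


def ms_ssim(x: np.ndarray, y: np.ndarray, scales: int = 3) -> float:
    """Multi-scale SSIM: geometric mean of per-scale SSIM over ``scales``
    dyadic scales (signs preserved via signed magnitude)."""
    vals = []
    xs, ys = np.asarray(x, float), np.asarray(y, float)
    for s in range(scales):
        vals.append(ssim(xs, ys))
        if s < scales - 1:
            xs = _downsample2(xs)
            ys = _downsample2(ys)
    vals = np.asarray(vals)
    mag = np.prod(np.abs(vals)) ** (1.0 / len(vals))
    return float(np.sign(np.prod(vals)) * mag)


def _downsample2(x):
    if x.ndim == 3:
        return np.stack([_downsample2(c) for c in x])
    blur = ndimage.gaussian_filter(x, 1.0, mode="reflect")
    return blur[0:2 * (x.shape[0] // 2):2, 0:2 * (x.shape[1] // 2):2]


def msssim_diversity(samples, max_samples: int = 100, seed: int = 0) -> float:
    """Mean pairwise MS-SSIM over all unordered sample pairs (lower = more
    diverse).  Beyond ``max_samples`` a seeded subsample is used."""
    samples = np.asarray(samples, dtype=float)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if len(samples) > max_samples:
        rng = np.random.default_rng(seed)
        samples = samples[rng.choice(len(samples), max_samples, replace=False)]
    vals = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            vals.append(ms_ssim(samples[i], samples[j]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# k-NN manifold precision / recall
# ---------------------------------------------------------------------------

def gen_precision_recall(feats_real: np.ndarray, feats_gen: np.ndarray,
                         k: int = 3) -> tuple[float, float]:
    """Manifold precision (fidelity) and recall (coverage) via k-NN radii.

    A generated point counts as precise if it falls within the k-NN-radius
    ball of at least one real point; recall swaps the roles.
    """
    fr = np.atleast_2d(np.asarray(feats_real, float))
    fg = np.atleast_2d(np.asarray(feats_gen, float))
    if len(fr) < k + 1 or len(fg) < k + 1:
        raise ValueError(f"need at least {k + 1} points per set")

    def covered(anchor, query):
        d_self = cdist(anchor, anchor)
        np.fill_diagonal(d_self, np.inf)
        radii = np.sort(d_self, axis=1)[:, k - 1]
        d = cdist(query, anchor)
        return float(np.mean(np.any(d <= radii[None, :], axis=1)))

    return covered(fr, fg), covered(fg, fr)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# cohort scoring
# ---------------------------------------------------------------------------

def minmax_normalize(values, invert: bool = False) -> np.ndarray:
    """(v - min) / (max - min), optionally negating first (lower-is-better
    metrics); constant input maps to all 0.5."""
    v = np.asarray(values, dtype=float)
    if invert:
        v = -v
    span = v.max() - v.min()
    if span < 1e-15:
        return np.full_like(v, 0.5)
    return (v - v.min()) / span


def quality_score(fid_n, is_n, precision_n):
    """0.4 * FID_n (inverted upstream) + 0.35 * IS_n + 0.25 * precision_n."""
    return 0.4 * np.asarray(fid_n) + 0.35 * np.asarray(is_n) + 0.25 * np.asarray(precision_n)


def diversity_score(msssim_n_inverted, recall_n):
    """0.6 * MS-SSIM_n (inverted upstream) + 0.4 * recall_n."""
    return 0.6 * np.asarray(msssim_n_inverted) + 0.4 * np.asarray(recall_n)


def combined_score(quality, diversity):
    """Geometric mean sqrt(quality * diversity)."""
    return np.sqrt(np.asarray(quality, dtype=float) * np.asarray(diversity, dtype=float))


def relative_improvement(a, b) -> float:
    """Percent improvement of ``a`` over ``b``: 100 * (a - b) / b."""
    return 100.0 * (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) / np.asarray(b, dtype=float)


@dataclass
class EvalReport:
    """Per-architecture metrics plus cohort-relative scores."""

    names: list
    metrics: dict                      # name -> {fid, is_mean, msssim, precision, recall, f1}
    scores: dict = field(default_factory=dict)

    def table(self):
        import pandas as pd

        rows = []
        for n in self.names:
            row = {"architecture": n}
            row.update(self.metrics[n])
            row.update({k: v[n] for k, v in self.scores.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def score_cohort(raw: dict) -> dict:
    """Compute quality / diversity / combined / relative-improvement columns
    for a cohort of architectures given raw metric values.

    ``raw`` maps architecture name -> dict with keys fid, is_mean, msssim,
    precision, recall.  Normalization is cohort-relative.
    """
    names = list(raw)
    fid_n = minmax_normalize([raw[n]["fid"] for n in names], invert=True)
    is_n = minmax_normalize([raw[n]["is_mean"] for n in names])
    prec_n = minmax_normalize([raw[n]["precision"] for n in names])
    mss_n = minmax_normalize([raw[n]["msssim"] for n in names], invert=True)
    rec_n = minmax_normalize([raw[n]["recall"] for n in names])
    q = quality_score(fid_n, is_n, prec_n)
    d = diversity_score(mss_n, rec_n)
    c = combined_score(q, d)
    best = names[int(np.argmax(c))]
    # cohort normalization can send the worst architecture to exactly 0
    rel = {n: (float(relative_improvement(c[names.index(best)], c[i]))
               if c[i] > 0 else float("inf"))
           for i, n in enumerate(names)}
    return {
        "quality": dict(zip(names, q.tolist())),
        "diversity": dict(zip(names, d.tolist())),
        "combined": dict(zip(names, c.tolist())),
        "relative_improvement_vs_best": rel,
    }


def evaluate_generators(real_images, generated: dict, embedder=None,
                        class_probs: dict | None = None, k: int = 3) -> EvalReport:
    """Full evaluation of several generators against one real set.

    ``generated`` maps architecture name -> image array (n, C, H, W).
    ``class_probs`` optionally supplies per-architecture class posteriors for
    the inception score (otherwise IS is computed from histogram soft-labels
    of the embedder features, a crude but deterministic stand-in).
    """
    embedder = embedder or FeatureEmbedder()
    fr = embedder(np.asarray(real_images))
    metrics = {}
    for name, imgs in generated.items():
        fg = embedder(np.asarray(imgs))
        p, r = gen_precision_recall(fr, fg, k=k)
        if class_probs and name in class_probs:
            is_val = inception_score(class_probs[name])
        else:
            logits = fg[:, : max(4, min(8, fg.shape[1]))]
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            is_val = inception_score(e / e.sum(axis=1, keepdims=True))
        metrics[name] = {
            "fid": fid(fr, fg),
            "is_mean": is_val,
            "msssim": msssim_diversity(np.asarray(imgs)),
            "precision": p,
            "recall": r,
            "f1": f1(p, r),
        }
    raw = {n: {k2: metrics[n][k2] for k2 in ("fid", "is_mean", "msssim", "precision", "recall")}
           for n in metrics}
    report = EvalReport(names=list(generated), metrics=metrics, scores=score_cohort(raw))
    return report
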