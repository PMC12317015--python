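"""Confidence-weighted fusion of the two generator outputs.

The fused sample is a convex combination

    G_final = gamma_SG * G_SG + gamma_PG * G_PG

with weights from a temperature-scaled softmax of the generator confidences,
modulated by two image-derived state measures: secretory activity (mean
gradient magnitude of the protein channel) and structural organization
(variance of gradient magnitude along organelle boundaries),

    gamma_SG = exp(C_SG/T) * S_sec / (exp(C_SG/T) * S_sec + exp(C_PG/T) * S_str).

At temperature T=1 with the state measures folded in, the plain
softmax-weighted form is recovered.  When both state measures vanish the
weights fall back to the plain softmax of the confidences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def sobel_magnitude(channel: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the classical 3x3 Sobel kernels (reflect)."""
    ch = np.asarray(channel, dtype=float)
    gx = ndimage.convolve(ch, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(ch, _SOBEL_Y, mode="reflect")
    return np.sqrt(gx ** 2 + gy ** 2)


@dataclass
class FusionState:
    C_SG: float
    C_PG: float
    S_secretion: float
    S_structure: float
    temperature: float = 2.0
    gamma_SG: float = 0.5
    gamma_PG: float = 0.5

    def resolve(self) -> "FusionState":
        self.gamma_SG, self.gamma_PG = fusion_weights(
            self.C_SG, self.C_PG, self.S_secretion, self.S_structure, self.temperature)
        return self


def secretion_measure(image: np.ndarray) -> float:
    """Secretory-activity measure: mean Sobel gradient magnitude of the
    protein channel (channel 0).  Zero iff the channel is constant."""
    img = np.asarray(image, dtype=float)
    protein = img[0] if img.ndim == 3 else img
    if np.ptp(protein) == 0:
        return 0.0
    return float(sobel_magnitude(protein).mean())


def structure_measure(image: np.ndarray, labels: np.ndarray) -> float:
    """Structural-organization measure: variance of Sobel gradient magnitudes
    sampled at organelle boundary pixels (label transitions); 0 when fewer
    than 2 boundary pixels exist."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=0)
    labels = np.asarray(labels)
    boundary = np.zeros(labels.shape, dtype=bool)
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    boundary[:, :-1] |= labels[:, 1:] != labels[:, :-1]
    boundary[1:, :] |= labels[1:, :] != labels[:-1, :]
    boundary[:-1, :] |= labels[1:, :] != labels[:-1, :]
    boundary &= labels != 0
    if boundary.sum() < 2:
        return 0.0
    return float(np.var(sobel_magnitude(img)[boundary]))


def fusion_weights(C_SG: float, C_PG: float, S_sec: float, S_str: float,
                   temperature: float = 2.0) -> tuple[float, float]:
    """Temperature-scaled, state-modulated softmax weights (sum to 1)."""
    vals = [C_SG, C_PG, S_sec, S_str, temperature]
    if not all(np.isfinite(vals)):
        raise ValueError("fusion inputs must be finite")
    if S_sec < 0 or S_str < 0:
        raise ValueError("state measures must be nonnegative")
    if S_sec == 0 and S_str == 0:
        S_sec = S_str = 1.0  # fallback: plain softmax of confidences
    m = max(C_SG, C_PG) / temperature
    a = np.exp(C_SG / temperature - m) * S_sec
    b = np.exp(C_PG / temperature - m) * S_str
    g = float(a / (a + b))
    return g, 1.0 - g


def fuse(g_sg: np.ndarray, g_pg: np.ndarray, weights) -> np.ndarray:
    """Pixelwise convex combination of the two generator outputs."""
    g_sg = np.asarray(g_sg, dtype=float)
    g_pg = np.asarray(g_pg, dtype=float)
    if g_sg.shape != g_pg.shape:
        raise ValueError("generator outputs must have the same shape")
    if isinstance(weights, FusionState):
        gamma_sg, gamma_pg = weights.gamma_SG, weights.gamma_PG
    else:
        gamma_sg, gamma_pg = weights
    return gamma_sg * g_sg + gamma_pg * g_pg
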