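"""Training losses: binary cross-entropy, Dice, and their weighted sum.

All three operate on a predicted probability vector ``q`` and a binary
target vector ``h`` of equal length.  The combined loss is
``v · BCE + Dice``, linear in the weight ``v``.  Gradients with respect to
``q`` are provided for the training loop.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bce_loss", "dice_loss", "combined_loss", "combined_loss_grad"]

_CLIP = 1e-7


def _check(q, h):
    q = np.asarray(q, dtype=float).ravel()
    h = np.asarray(h, dtype=float).ravel()
    if q.size != h.size:
        raise ValueError("prediction and target lengths differ")
    return q, h


def bce_loss(q: np.ndarray, h: np.ndarray) -> float:
    """Mean negative log-likelihood of binary targets (natural log).

    Predictions are clipped to ``[1e-7, 1 - 1e-7]`` before the logs, so the
    loss is finite everywhere and ~0 for a perfect prediction.
    """
    q, h = _check(q, h)
    qc = np.clip(q, _CLIP, 1.0 - _CLIP)
    return float(-np.mean(h * np.log(qc) + (1.0 - h) * np.log(1.0 - qc)))


def dice_loss(q: np.ndarray, h: np.ndarray) -> float:
    """Soft Dice loss ``1 − 2Σqh / (Σq² + Σh² + ε)``; in [0, 1].

    0 for an exact binary match, 1 for disjoint supports; the ``ε = 1e-7``
    smoothing defines the all-zero case as 0.
    """
    q, h = _check(q, h)
    num = 2.0 * np.sum(q * h) + _CLIP
    den = np.sum(q * q) + np.sum(h * h) + _CLIP
    return float(1.0 - num / den)


def combined_loss(q: np.ndarray, h: np.ndarray, v: float = 1.0) -> float:
    """Weighted sum ``v · BCE + Dice``."""
    if v < 0:
        raise ValueError("v must be nonnegative")
    return v * bce_loss(q, h) + dice_loss(q, h)


def combined_loss_grad(q: np.ndarray, h: np.ndarray, v: float = 1.0) -> np.ndarray:
    """Gradient of :func:`combined_loss` with respect to ``q``."""
    q, h = _check(q, h)
    qc = np.clip(q, _CLIP, 1.0 - _CLIP)
    g_bce = -(h / qc - (1.0 - h) / (1.0 - qc)) / q.size
    num = 2.0 * np.sum(q * h) + _CLIP
    den = np.sum(q * q) + np.sum(h * h) + _CLIP
    g_dice = -(2.0 * h * den - num * 2.0 * q) / den**2
    return v * g_bce + g_dice
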