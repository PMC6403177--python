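"""Smoothed soft-Dice loss.

The training objective scores the overlap between a probability map
``p`` and a binary ground truth ``g`` with the Laplace-smoothed Dice
coefficient

    D = (2 * sum(p*g) + s) / (sum(p^2) + sum(g^2) + s),    s = 1,

which for binary ``p`` reduces to the familiar 2TP/(2TP+FP+FN) and,
thanks to the smoothing term, is well defined (D = 1) when both maps are
empty.  The loss minimized is ``1 - D``.  Its insensitivity to the
overwhelming background class is what makes it suitable for vessel
segmentation, where foreground is well under 1% of voxels.

``soft_dice_gradient`` returns the exact differential of the smoothed
coefficient,

    dD/dp_j = 2 * [ g_j * (sum(p^2)+sum(g^2)+s) - p_j * (2*sum(p*g)+s) ]
              / (sum(p^2)+sum(g^2)+s)^2,

which agrees with central finite differences of :func:`soft_dice` and
reduces to the widely quoted V-net expression as s -> 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_dice", "soft_dice_gradient", "soft_dice_loss_gradient"]


def _check(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    return pred, truth


def soft_dice(pred: np.ndarray, truth: np.ndarray, s: float = 1.0) -> float:
    """Smoothed soft-Dice coefficient in [0, 1]; loss = 1 - soft_dice."""
    p, g = _check(pred, truth)
    num = 2.0 * np.sum(p * g) + s
    den = np.sum(p * p) + np.sum(g * g) + s
    return float(num / den)


def soft_dice_gradient(pred: np.ndarray, truth: np.ndarray, s: float = 1.0) -> np.ndarray:
    """Analytic gradient dD/dp of the smoothed soft-Dice coefficient."""
    p, g = _check(pred, truth)
    sp2 = np.sum(p * p)
    sg2 = np.sum(g * g)
    spg = np.sum(p * g)
    den = sp2 + sg2 + s
    grad = 2.0 * (g * den - p * (2.0 * spg + s)) / (den * den)
    return grad.astype(np.float64)


def soft_dice_loss_gradient(
    pred: np.ndarray, truth: np.ndarray, s: float = 1.0
) -> tuple[float, np.ndarray]:
    """Loss ``1 - D`` and its gradient w.r.t. the predictions."""
    return 1.0 - soft_dice(pred, truth, s), -soft_dice_gradient(pred, truth, s)
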