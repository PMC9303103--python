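"""Segmentation losses: channel-wise distillation, cross-entropy, soft Dice.

Two distinct softmaxes coexist here and are deliberately named apart:

* the **per-pixel class softmax** (over the C channels at each pixel), used
  by cross-entropy and Dice;
* the **channel-wise spatial softmax** :func:`channel_softmax` (over all
  W·H pixels within one channel, after dividing logits by the temperature
  τ), which turns each class-channel logit map into a spatial probability
  distribution.

The distillation loss aligns teacher and student spatial distributions per
channel with a KL divergence scaled by τ²/C, where C counts all classes
including background.  When the teacher's logits only exist inside a
restored ROI, an optional binary support mask restricts both the softmax
normalisation and the KL sum to those pixels.

All public losses accept H×W×C logits and return plain floats; the private
``*_grad`` companions return the gradient with respect to the (student)
logits and are pinned against central differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "channel_softmax",
    "kd_loss",
    "ce_loss",
    "dice_loss",
    "combined_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined objective α·CE + β·Dice + γ·KD and temperature τ."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.0
    tau: float = 1.0

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.tau)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("loss weights must be finite")
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")
        if self.tau <= 0:
            raise ValueError("temperature tau must be strictly positive")


class LossBreakdown(NamedTuple):
    total: float
    ce: float
    dice: float
    kd: float


def _check_logits(logits: np.ndarray, name: str = "logits") -> np.ndarray:
    arr = np.asarray(logits, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"{name} must be H×W×C, got shape {arr.shape}")
    if arr.shape[2] < 2:
        raise ValueError(f"{name} needs C ≥ 2 channels, got {arr.shape[2]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _support_index(support: np.ndarray | None, h: int, w: int) -> np.ndarray | None:
    if support is None:
        return None
    sup = np.asarray(support)
    if sup.shape != (h, w):
        raise ValueError(f"support shape {sup.shape} does not match logits ({h}, {w})")
    flat = sup.reshape(-1).astype(bool)
    if not flat.any():
        raise ValueError("support mask is empty")
    return flat


def _log_channel_softmax(flat: np.ndarray, tau: float, keep: np.ndarray | None) -> np.ndarray:
    """log of the spatial softmax per channel; ``flat`` is (H·W, C).

    Rows outside ``keep`` are excluded from the normalisation and returned
    as -inf (probability 0).
    """
    z = flat / tau
    if keep is not None:
        z = z[keep]
    z = z - z.max(axis=0, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=0, keepdims=True))
    if keep is None:
        return logp
    out = np.full(flat.shape, -np.inf)
    out[keep] = logp
    return out


def channel_softmax(
    logits: np.ndarray, tau: float, support: np.ndarray | None = None
) -> np.ndarray:
    """Spatial softmax within each channel: exp(y/τ) normalised over pixels.

    Each channel of the output sums to 1 over all W·H pixels (over the
    supported pixels when ``support`` is given; unsupported pixels get 0).
    """
    arr = _check_logits(logits)
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    h, w, c = arr.shape
    keep = _support_index(support, h, w)
    logp = _log_channel_softmax(arr.reshape(-1, c), tau, keep)
    return np.exp(logp).reshape(h, w, c)


def kd_loss(
    teacher: np.ndarray,
    student: np.ndarray,
    tau: float,
    support: np.ndarray | None = None,
) -> float:
    """Channel-wise distillation loss.

    (τ²/C) · Σ_c Σ_i φ(yᵀ)[c,i] · log(φ(yᵀ)[c,i] / φ(yˢ)[c,i]), with φ the
    channel-wise spatial softmax at temperature τ.  Non-negative; zero iff
    the per-channel distributions coincide.  The teacher side is a constant
    target (no gradient is defined for it).
    """
    loss, _ = _kd_loss_grad(teacher, student, tau, support, need_grad=False)
    return loss


def _kd_loss_grad(
    teacher: np.ndarray,
    student: np.ndarray,
    tau: float,
    support: np.ndarray | None,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    t = _check_logits(teacher, "teacher")
    s = _check_logits(student, "student")
    if t.shape != s.shape:
        raise ValueError(f"teacher shape {t.shape} != student shape {s.shape}")
    if tau <= 0:
        raise ValueError("tau must be strictly positive")
    h, w, c = s.shape
    keep = _support_index(support, h, w)
    tf, sf = t.reshape(-1, c), s.reshape(-1, c)
    if keep is not None:
        tf, sf = tf[keep], sf[keep]
    log_pt = _log_channel_softmax(tf, tau, None)
    log_ps = _log_channel_softmax(sf, tau, None)
    pt = np.exp(log_pt)
    loss = float(tau**2 / c * np.sum(pt * (log_pt - log_ps)))
    grad = None
    if need_grad:
        g = (tau / c) * (np.exp(log_ps) - pt)
        if keep is None:
            grad = g.reshape(h, w, c)
        else:
            grad = np.zeros((h * w, c))
            grad[keep] = g
            grad = grad.reshape(h, w, c)
    return loss, grad


def _check_gt(gt: np.ndarray, c: int, shape: tuple[int, int]) -> np.ndarray:
    mask = np.asarray(gt)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match logits {shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("ground-truth mask must be integer-valued")
    if mask.min() < 0 or mask.max() >= c:
        raise ValueError(f"mask classes must lie in [0, {c}), got max {mask.max()}")
    return mask


def _pixel_log_softmax(flat: np.ndarray) -> np.ndarray:
    """Per-pixel log softmax across classes; ``flat`` is (H·W, C)."""
    z = flat - flat.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def ce_loss(gt: np.ndarray, logits: np.ndarray) -> float:
    """Mean per-pixel cross-entropy with the per-pixel class softmax."""
    loss, _ = _ce_loss_grad(gt, logits, need_grad=False)
    return loss


def _ce_loss_grad(
    gt: np.ndarray, logits: np.ndarray, need_grad: bool = True
) -> tuple[float, np.ndarray | None]:
    arr = _check_logits(logits)
    h, w, c = arr.shape
    mask = _check_gt(gt, c, (h, w))
    flat = arr.reshape(-1, c)
    logp = _pixel_log_softmax(flat)
    idx = mask.reshape(-1)
    n = idx.size
    loss = float(-logp[np.arange(n), idx].mean())
    grad = None
    if need_grad:
        g = np.exp(logp)
        g[np.arange(n), idx] -= 1.0
        grad = (g / n).reshape(h, w, c)
    return loss, grad


def dice_loss(gt: np.ndarray, logits: np.ndarray, smooth: float = 1e-6) -> float:
    """Multi-class soft Dice loss averaged over all C classes.

    1 − mean_c (2·Σᵢ p_{c,i} g_{c,i} + ε) / (Σᵢ p_{c,i} + Σᵢ g_{c,i} + ε)
    with p the per-pixel class softmax and g the one-hot ground truth.
    Background participates like any other class.
    """
    loss, _ = _dice_loss_grad(gt, logits, smooth, need_grad=False)
    return loss


def _dice_loss_grad(
    gt: np.ndarray, logits: np.ndarray, smooth: float = 1e-6, need_grad: bool = True
) -> tuple[float, np.ndarray | None]:
    arr = _check_logits(logits)
    h, w, c = arr.shape
    mask = _check_gt(gt, c, (h, w))
    flat = arr.reshape(-1, c)
    p = np.exp(_pixel_log_softmax(flat))
    onehot = np.zeros_like(p)
    onehot[np.arange(mask.size), mask.reshape(-1)] = 1.0
    inter = (p * onehot).sum(axis=0)
    psum, gsum = p.sum(axis=0), onehot.sum(axis=0)
    denom = psum + gsum + smooth
    dice_c = (2.0 * inter + smooth) / denom
    loss = float(1.0 - dice_c.mean())
    grad = None
    if need_grad:
        # dL/dp_{i,c}, then chain through the per-pixel softmax
        dldp = -(2.0 * onehot * denom[None, :] - (2.0 * inter + smooth)[None, :]) / (
            c * denom[None, :] ** 2
        )
        dot = (dldp * p).sum(axis=1, keepdims=True)
        grad = (p * (dldp - dot)).reshape(h, w, c)
    return loss, grad


def combined_loss(
    gt: np.ndarray,
    student_logits: np.ndarray,
    teacher_logits: np.ndarray | None = None,
    weights: LossWeights = LossWeights(),
    support: np.ndarray | None = None,
) -> LossBreakdown:
    """Combined objective α·CE + β·Dice + γ·KD with a per-term breakdown.

    The teacher is required exactly when γ > 0 and is ignored (not even
    touched) when γ = 0, so a γ=0 run is code-path identical to training
    without a teacher.
    """
    breakdown, _ = combined_loss_grad(
        gt, student_logits, teacher_logits, weights, support, need_grad=False
    )
    return breakdown


def combined_loss_grad(
    gt: np.ndarray,
    student_logits: np.ndarray,
    teacher_logits: np.ndarray | None = None,
    weights: LossWeights = LossWeights(),
    support: np.ndarray | None = None,
    need_grad: bool = True,
) -> tuple[LossBreakdown, np.ndarray | None]:
    if weights.gamma > 0 and teacher_logits is None:
        raise ValueError("gamma > 0 requires teacher logits")
    ce, g_ce = _ce_loss_grad(gt, student_logits, need_grad=need_grad)
    dice, g_dice = _dice_loss_grad(gt, student_logits, need_grad=need_grad)
    kd, g_kd = 0.0, None
    if weights.gamma > 0:
        kd, g_kd = _kd_loss_grad(
            teacher_logits, student_logits, weights.tau, support, need_grad=need_grad
        )
    total = weights.alpha * ce + weights.beta * dice + weights.gamma * kd
    grad = None
    if need_grad:
        grad = weights.alpha * g_ce + weights.beta * g_dice
        if g_kd is not None:
            grad = grad + weights.gamma * g_kd
    return LossBreakdown(total=float(total), ce=ce, dice=dice, kd=kd), grad
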