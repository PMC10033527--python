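"""Segmentation losses: soft dice, class-weighted focal, and their fusion.

The fusion loss is  L = L_dice + lambda * L_focal  with lambda = 0.3 by
default.  The focal loss uses gamma = 2 and per-class weights alpha of
0.25 / 0.75 / 0.75 for background / disc rim / cup: the two anatomical
classes cover a few percent of a fundus image, and the focal term
down-weights the easy background majority.

Aggregation conventions (the published formulas leave the pixel axis
implicit): the soft dice sums over all pixels of the batch inside each
class term and averages the per-class dice over the K classes, so a
perfect prediction scores exactly 0; the focal term is averaged over
pixels, making both terms batch-size invariant.  The unnormalized dice
(1 - sum of per-class dice, which is negative for a perfect multi-class
prediction) is available with ``normalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ShapeError
from .nn import tensor as T
from .nn.tensor import Tensor

CLASS_ORDER = ("background", "rim", "cup")


@dataclass
class LossConfig:
    lambda_weight: float = 0.3
    gamma: float = 2.0
    alpha: tuple = (0.25, 0.75, 0.75)      # per class, in class_order
    epsilon: float = 1e-6
    class_order: tuple = CLASS_ORDER
    normalize: bool = True                 # average dice over classes

    def validate(self, num_classes: int | None = None):
        if self.lambda_weight < 0 or self.gamma < 0:
            raise ConfigurationError("lambda and gamma must be non-negative")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha):
            raise ConfigurationError("alpha weights must lie in [0, 1]")
        if len(self.alpha) != len(self.class_order):
            raise ConfigurationError("alpha length must match class_order")
        if num_classes is not None and len(self.alpha) != num_classes:
            raise ConfigurationError(
                f"alpha has {len(self.alpha)} entries for {num_classes} classes")


def one_hot(mask: np.ndarray, num_classes: int = 3) -> np.ndarray:
    """(H,W) integer labels -> (K,H,W) binary float32."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ShapeError(f"labels outside [0, {num_classes})")
    out = np.zeros((num_classes, *mask.shape), dtype=np.float32)
    for k in range(num_classes):
        out[k] = mask == k
    return out


def _as_batched(x) -> Tensor:
    t = T.as_tensor(x)
    if t.ndim == 3:
        t = T.reshape(t, (1, *t.shape))
    if t.ndim != 4:
        raise ShapeError(f"expected (K,H,W) or (N,K,H,W), got {t.shape}")
    return t


def _check_pair(m: Tensor, p: Tensor):
    if m.shape != p.shape:
        raise ShapeError(f"target shape {m.shape} != prediction shape {p.shape}")


def dice_loss(m, p, config: LossConfig | None = None):
    """Soft dice loss: 1 - mean_k [ (2 sum m_k p_k + eps) / (sum m_k^2 + sum p_k^2 + eps) ]."""
    config = config or LossConfig()
    m, p = _as_batched(m), _as_batched(p)
    _check_pair(m, p)
    eps = config.epsilon
    inter = T.tsum(T.mul(m, p), axis=(0, 2, 3))
    denom = T.add(T.tsum(T.power(m, 2.0), axis=(0, 2, 3)),
                  T.tsum(T.power(p, 2.0), axis=(0, 2, 3)))
    dice_k = T.mul(T.add(T.mul(inter, 2.0), eps), T.power(T.add(denom, eps), -1.0))
    total = T.tsum(dice_k)
    if config.normalize:
        return T.add(1.0, T.mul(total, -1.0 / m.shape[1]))
    return T.add(1.0, T.mul(total, -1.0))


def focal_loss(m, p, config: LossConfig | None = None):
    """Class-weighted focal loss, averaged over pixels.

    Per pixel and class:  -m a (1-p)^g log p  -  (1-m)(1-a) p^g log(1-p).
    """
    config = config or LossConfig()
    m, p = _as_batched(m), _as_batched(p)
    _check_pair(m, p)
    config.validate(num_classes=m.shape[1])
    eps = config.epsilon
    alpha = np.asarray(config.alpha, dtype=np.float64).reshape(1, -1, 1, 1)
    g = config.gamma
    pc = T.clip(p, eps, 1.0 - eps)
    one_m_p = T.add(1.0, T.mul(pc, -1.0))
    pos = T.mul(T.mul(m, Tensor(alpha)),
                T.mul(T.power(one_m_p, g), T.log(pc)))
    neg = T.mul(T.mul(T.add(1.0, T.mul(m, -1.0)), Tensor(1.0 - alpha)),
                T.mul(T.power(pc, g), T.log(one_m_p)))
    per_pixel = T.mul(T.add(pos, neg), -1.0)           # (N,K,H,W)
    n, k, h, w = m.shape
    return T.mul(T.tsum(per_pixel), 1.0 / (n * h * w))


def fusion_loss(m, p, config: LossConfig | None = None):
    """dice_loss + lambda * focal_loss."""
    config = config or LossConfig()
    return T.add(dice_loss(m, p, config),
                 T.mul(focal_loss(m, p, config), config.lambda_weight))


def cross_entropy_loss(m, p, config: LossConfig | None = None):
    """Plain per-pixel multi-class cross-entropy (comparison utility)."""
    config = config or LossConfig()
    m, p = _as_batched(m), _as_batched(p)
    _check_pair(m, p)
    pc = T.clip(p, config.epsilon, 1.0 - config.epsilon)
    n, k, h, w = m.shape
    return T.mul(T.tsum(T.mul(T.mul(m, T.log(pc)), -1.0)), 1.0 / (n * h * w))
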