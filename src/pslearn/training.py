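"""Shared training utilities: config, intensity normalization, losses.

Intensities are normalized with a fixed soft-tissue window before entering
a network: clip to ``center ± width/2`` and scale to ``[-0.5, 0.5]``.  With
the default (center 50 HU, width 400 HU) air saturates at -0.5, soft tissue
sits near 0 and enhanced parenchyma near +0.15, which keeps activations
well-scaled without any per-image statistics (so train/test processing is
identical by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError

WINDOW_CENTER = 50.0
WINDOW_WIDTH = 400.0


@dataclass
class TrainConfig:
    """Hyperparameters shared by pretext training and fine-tuning.

    ``patience`` enables early stopping on the validation metric (epochs
    without improvement); ``None`` disables it.  ``device`` is a hint only —
    this stack runs on CPU.
    """

    epochs: int = 20
    batch_size: int = 8
    lr: float = 3e-3
    lr_schedule: str = "cosine"  # or "constant"
    bce_weight: float = 1.0
    dice_weight: float = 1.0
    seed: int = 0
    patience: int | None = None
    val_fraction: float = 0.25
    freeze_encoder: bool = False
    warmup_epochs: int = 0  # head-only epochs before unfreezing the encoder
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.lr <= 0:
            raise ConfigurationError("epochs must be >= 0; batch_size and lr positive")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ConfigurationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if not (0 < self.val_fraction < 1):
            raise ConfigurationError("val_fraction must be in (0, 1)")
        if self.patience is not None and self.patience < 1:
            raise ConfigurationError("patience must be >= 1 or None")
        if self.warmup_epochs < 0:
            raise ConfigurationError("warmup_epochs must be >= 0")


def window_norm(pixels: np.ndarray, center: float = WINDOW_CENTER, width: float = WINDOW_WIDTH) -> np.ndarray:
    lo, hi = center - width / 2, center + width / 2
    return (np.clip(pixels, lo, hi) - center) / width


def to_batch(images: list[np.ndarray], dtype=np.float32) -> np.ndarray:
    """Stack 2D pixel arrays into a windowed (N, 1, H, W) batch."""
    return np.stack([window_norm(im) for im in images])[:, None].astype(dtype)


def bce_soft_dice(
    logits: np.ndarray, targets: np.ndarray, bce_weight: float = 1.0, dice_weight: float = 1.0,
    eps: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Compound per-pixel loss for the segmentation pretext.

    Binary cross-entropy handles per-pixel calibration; the soft-Dice term
    counteracts the extreme foreground/background imbalance that small
    lesions create.  Returns ``(loss, dlogits)``.
    """
    z, t = logits, targets.astype(logits.dtype)
    p = expit(z)
    n = z.size
    bce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dbce = (p - t) / n
    num = 2.0 * float((p * t).sum()) + eps
    den = float(p.sum() + t.sum()) + eps
    dice_loss = 1.0 - num / den
    ddice_dp = (num - 2.0 * t * den) / (den * den)
    ddice = ddice_dp * p * (1.0 - p)
    loss = bce_weight * bce + dice_weight * dice_loss
    dz = (bce_weight * dbce + dice_weight * ddice).astype(logits.dtype)
    return loss, dz


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over integer labels; returns ``(loss, dlogits)``."""
    z = logits - logits.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsum
    n = len(labels)
    loss = float(-logp[np.arange(n), labels].mean())
    soft = np.exp(logp)
    soft[np.arange(n), labels] -= 1.0
    return loss, (soft / n).astype(logits.dtype)


def epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i : i + batch_size]
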