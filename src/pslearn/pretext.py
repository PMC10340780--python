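"""Pretext training: segment the inserted pseudo-lesions.

The network never sees a human annotation — the ground truth masks come
from the insertion step and are pixel-perfect by construction.  After
training, the encoder is exported and transferred to the downstream
classifier.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .insertion import PSExample
from .nn.models import EncoderState, ModelBundle
from .nn.optim import Adam, cosine_lr
from .training import TrainConfig, bce_soft_dice, epoch_batches, to_batch


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    if a.shape != b.shape:
        raise ConfigurationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def predict_masks(bundle: ModelBundle, images: list[np.ndarray], batch_size: int = 16) -> list[np.ndarray]:
    """Threshold the segmenter's sigmoid output at 0.5."""
    out = []
    for i in range(0, len(images), batch_size):
        x = to_batch(images[i : i + batch_size])
        logits = bundle.forward(x)
        out.extend(list(expit(logits[:, 0]) >= 0.5))
    return out


def _mean_val_dice(bundle: ModelBundle, images, masks) -> float:
    preds = predict_masks(bundle, images)
    return float(np.mean([dice_score(p, m) for p, m in zip(preds, masks)]))


def pretrain_segmenter(
    bundle: ModelBundle, dataset: list[PSExample], config: TrainConfig
) -> tuple[ModelBundle, pd.DataFrame]:
    """Train the segmentation bundle on pseudo-lesion examples.

    Minimizes BCE + soft-Dice, evaluates Dice on a held-out split each
    epoch, and restores the best-validation-Dice weights at the end.  Fully
    seeded: identical ``(seed, config, dataset)`` give identical weights and
    logs.  ``epochs=0`` returns the initial weights bit-exactly.
    """
    if bundle.task != "segmentation":
        raise ConfigurationError("bundle head must be a segmentation decoder")
    if not dataset:
        raise ConfigurationError("dataset must be nonempty")
    log_rows: list[dict] = []
    if config.epochs == 0:
        return bundle, pd.DataFrame(log_rows, columns=["epoch", "train_loss", "val_dice", "lr"])

    n = len(dataset)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if n >= 4 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if n_val == 0:
        train_idx = perm
        val_idx = perm
    train_imgs = [dataset[i].image.pixels for i in train_idx]
    train_masks = [dataset[i].mask for i in train_idx]
    val_imgs = [dataset[i].image.pixels for i in val_idx]
    val_masks = [dataset[i].mask for i in val_idx]

    xtr = to_batch(train_imgs)
    ytr = np.stack(train_masks)[:, None].astype(xtr.dtype)

    opt = Adam(bundle.params(), lr=config.lr)
    steps_per_epoch = math.ceil(len(train_idx) / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    best_dice, best_state, since_best = -1.0, bundle.get_state(), 0
    step = 0
    for epoch in range(config.epochs):
        erng = np.random.default_rng([config.seed, 1000 + epoch])
        losses = []
        for idx in epoch_batches(len(train_idx), config.batch_size, erng):
            logits = bundle.forward(xtr[idx])
            loss, dz = bce_soft_dice(logits, ytr[idx], config.bce_weight, config.dice_weight)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {step}; "
                    f"lr={config.lr}, batch={list(idx)}"
                )
            bundle.backward(dz)
            lr = cosine_lr(config.lr, step, total_steps) if config.lr_schedule == "cosine" else config.lr
            opt.step(bundle.grads(), lr=lr)
            losses.append(loss)
            step += 1
        val_dice = _mean_val_dice(bundle, val_imgs, val_masks)
        log_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": val_dice, "lr": lr}
        )
        # ties prefer the later epoch (more optimization at equal Dice)
        if val_dice >= best_dice:
            best_dice, best_state, since_best = val_dice, bundle.get_state(), 0
        else:
            since_best += 1
            if config.patience is not None and since_best >= config.patience:
                break
    bundle.set_state(best_state)
    return bundle, pd.DataFrame(log_rows)


def export_encoder(bundle: ModelBundle) -> EncoderState:
    """Extract the transferable encoder weights.

    Works on a trained bundle or an untrained one — exporting the random
    initialization gives the "without pretraining" baseline path.
    """
    return bundle.encoder_state()
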