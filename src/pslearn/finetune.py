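"""Classification fine-tuning and the labeled-data-fraction experiment.

The encoder learned on the pretext task (or a random initialization, for
the baseline condition) is attached to a global-pooling + linear head and
the whole network is trained end-to-end with cross-entropy.  The fraction
experiment measures how classification performance degrades as the labeled
training set shrinks, with and without pretext pretraining, under otherwise
identical conditions (same subsample, same seed, same schedule).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nn.models import EncoderState, ModelBundle, build_classifier, build_segmenter
from .nn.optim import Adam, cosine_lr
from .phantoms import LabeledSlice
from .pretext import export_encoder, pretrain_segmenter
from .training import TrainConfig, epoch_batches, softmax_cross_entropy, to_batch

DEFAULT_ARCH = "tinyunet-w8-l3"


@dataclass
class FractionExperimentSpec:
    """What the data-fraction sweep runs: fractions × seeds × conditions."""

    fractions: tuple[float, ...] = (0.10, 0.25, 0.50, 0.75, 1.0)
    seeds: tuple[int, ...] = (0, 1, 2)
    conditions: tuple[str, ...] = ("with_ps", "without_ps")
    metrics: tuple[str, ...] = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")

    def __post_init__(self) -> None:
        if not self.fractions or any(not (0 < f <= 1) for f in self.fractions):
            raise ConfigurationError("fractions must be within (0, 1]")
        if list(self.fractions) != sorted(self.fractions):
            raise ConfigurationError("fractions must be sorted ascending")
        for c in self.conditions:
            if c not in ("with_ps", "without_ps"):
                raise ConfigurationError(f"unknown condition {c!r}")


def subsample_training_set(
    dataset: list[LabeledSlice], fraction: float, seed: int = 0
) -> list[LabeledSlice]:
    """Stratified random subset with round-half-up per-class counts.

    The per-class selection is the first ``round(fraction * n_c)`` entries of
    one seeded permutation per class, so subsets at increasing fractions are
    nested (the 10% subset is contained in the 25% subset, and so on), which
    makes the fraction curve monotone-comparable.  ``fraction=1`` returns the
    full set in original order.
    """
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(dataset)
    by_class: dict[str, list[int]] = {}
    for i, ls in enumerate(dataset):
        by_class.setdefault(ls.label, []).append(i)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for c in sorted(by_class):
        idx = np.asarray(by_class[c])
        m = int(math.floor(fraction * len(idx) + 0.5))
        if m == 0:
            raise ConfigurationError(
                f"fraction {fraction} yields zero examples for class {c!r} (n={len(idx)})"
            )
        perm = rng.permutation(len(idx))
        chosen.extend(idx[perm[:m]].tolist())
    return [dataset[i] for i in sorted(chosen)]


def _class_names(dataset: list[LabeledSlice]) -> tuple[str, ...]:
    return tuple(sorted({ls.label for ls in dataset}))


def predict_proba(bundle: ModelBundle, slices: list[LabeledSlice], batch_size: int = 32) -> np.ndarray:
    """Softmax class scores, rows ordered like ``slices``."""
    out = []
    for i in range(0, len(slices), batch_size):
        x = to_batch([ls.slice.pixels for ls in slices[i : i + batch_size]])
        z = bundle.forward(x).astype(np.float64)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        out.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(out, axis=0)


def finetune_classifier(
    encoder_state: EncoderState | None,
    dataset: list[LabeledSlice],
    config: TrainConfig,
    arch_id: str | None = None,
) -> tuple[ModelBundle, pd.DataFrame]:
    """Fine-tune a classifier, optionally from pretrained encoder weights.

    All layers train by default ("full fine-tuning"); set
    ``config.freeze_encoder`` to update the head only.  Best-validation-
    accuracy weights are restored at the end.  ``epochs=0`` leaves the
    randomly initialized (or transferred) weights untouched.
    """
    classes = _class_names(dataset)
    if len(classes) < 2:
        raise ConfigurationError(f"dataset must contain >= 2 classes, got {classes}")
    if encoder_state is not None:
        if arch_id is not None and arch_id != encoder_state.arch_id:
            raise ConfigurationError(
                f"arch_id {arch_id!r} conflicts with encoder state {encoder_state.arch_id!r}"
            )
        arch_id = encoder_state.arch_id
    bundle = build_classifier(
        arch_id or DEFAULT_ARCH, n_classes=len(classes), seed=config.seed,
        encoder_state=encoder_state,
    )
    bundle.class_names = classes
    log_rows: list[dict] = []
    if config.epochs == 0:
        return bundle, pd.DataFrame(log_rows, columns=["epoch", "train_loss", "val_accuracy", "lr"])

    label_of = {c: k for k, c in enumerate(classes)}
    y = np.array([label_of[ls.label] for ls in dataset])
    n = len(dataset)
    rng = np.random.default_rng(config.seed)
    val_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == label_of[c])
        k = max(1, int(round(config.val_fraction * len(idx)))) if len(idx) >= 2 else 0
        val_idx.extend(idx[rng.permutation(len(idx))[:k]].tolist())
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    train_idx = np.flatnonzero(~val_mask)
    if len(train_idx) == 0:
        train_idx = np.arange(n)
    x_all = to_batch([ls.slice.pixels for ls in dataset])
    xtr, ytr = x_all[train_idx], y[train_idx]
    xva, yva = x_all[val_mask], y[val_mask]
    if len(yva) == 0:
        xva, yva = xtr, ytr

    params = bundle.params()
    if config.freeze_encoder:
        params = {k: v for k, v in params.items() if k.startswith("head.")}
    opt = Adam(params, lr=config.lr)
    steps_per_epoch = math.ceil(len(train_idx) / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    best_acc, best_state, since_best, step = -1.0, bundle.get_state(), 0, 0
    for epoch in range(config.epochs):
        erng = np.random.default_rng([config.seed, 2000 + epoch])
        losses = []
        for idx in epoch_batches(len(train_idx), config.batch_size, erng):
            logits = bundle.forward(xtr[idx])
            loss, dz = softmax_cross_entropy(logits, ytr[idx])
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, step {step}")
            bundle.backward(dz)
            lr = cosine_lr(config.lr, step, total_steps) if config.lr_schedule == "cosine" else config.lr
            grads = bundle.grads()
            if config.freeze_encoder or epoch < config.warmup_epochs:
                grads = {k: v for k, v in grads.items() if k.startswith("head.")}
            opt.step(grads, lr=lr)
            losses.append(loss)
            step += 1
        pred = bundle.forward(xva).argmax(axis=1)
        val_acc = float((pred == yva).mean())
        log_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc, "lr": lr}
        )
        # ties prefer the later epoch (a coarse validation accuracy on small
        # splits would otherwise freeze near-initial weights)
        if val_acc >= best_acc:
            best_acc, best_state, since_best = val_acc, bundle.get_state(), 0
        else:
            since_best += 1
            if config.patience is not None and since_best >= config.patience:
                break
    bundle.set_state(best_state)
    return bundle, pd.DataFrame(log_rows)


def run_fraction_experiment(
    spec: FractionExperimentSpec,
    train_cohort: list[LabeledSlice],
    val_cohort: list[LabeledSlice],
    ps_examples: list,
    pretext_config: TrainConfig,
    finetune_config: TrainConfig,
    arch_id: str = DEFAULT_ARCH,
    positive: str = "cancer",
) -> pd.DataFrame:
    """Run the fraction × seed × condition grid and return a long-format table.

    For every seed, the pretext pretraining runs once on the full unlabeled
    pool (self-supervision needs no labels) and its encoder is reused across
    fractions; the two conditions then differ *only* in encoder
    initialization — the labeled subsample, schedule and seed are identical.
    Columns: fraction, seed, condition, metric, value.
    """
    from .evaluation import evaluate_classifier  # local import avoids a cycle

    rows = []
    for seed in spec.seeds:
        enc_ps = None
        if "with_ps" in spec.conditions:
            seg = build_segmenter(arch_id, seed=seed)
            seg, _ = pretrain_segmenter(
                seg, ps_examples, dataclasses.replace(pretext_config, seed=seed)
            )
            enc_ps = export_encoder(seg)
        for fraction in spec.fractions:
            subset = subsample_training_set(train_cohort, fraction, seed)
            for cond in spec.conditions:
                try:
                    enc = enc_ps if cond == "with_ps" else None
                    bundle, _ = finetune_classifier(
                        enc, subset, dataclasses.replace(finetune_config, seed=seed),
                        arch_id=arch_id,
                    )
                    report = evaluate_classifier(bundle, val_cohort, positive=positive)
                except Exception as err:
                    raise RuntimeError(
                        f"fraction={fraction}, seed={seed}, condition={cond}: {err}"
                    ) from err
                values = report.metric_values()
                for metric in spec.metrics:
                    rows.append(
                        {
                            "fraction": fraction,
                            "seed": seed,
                            "condition": cond,
                            "metric": metric,
                            "value": values.get(metric),
                        }
                    )
    return pd.DataFrame(rows)
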