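"""Evaluation: confusion-matrix metrics with exact binomial CIs, AUC,
Grad-CAM localization, and tumor-size-stratified accuracy.

Every proportion (accuracy, sensitivity, specificity, precision) is
reported with an exact 95% Clopper–Pearson interval computed on its own
denominator.  Ratios with a zero denominator are reported as absent with a
reason rather than zero-filled, so averages are never silently corrupted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from skimage.transform import resize
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError
from .insertion import ImageSlice
from .nn.models import ModelBundle
from .training import to_batch


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta-distribution quantiles.

    ``lower = Q_Beta(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``upper = Q_Beta(1-alpha/2; x+1, n-x)`` (1 when x = n); inverting the
    binomial tail probabilities gives the same endpoints.
    """
    x, n = int(successes), int(trials)
    if n < 1 or not (0 <= x <= n):
        raise ConfigurationError(f"need 0 <= successes <= trials, trials >= 1; got x={x}, n={n}")
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class Metric:
    """A point estimate with optional CI, or an absence with its reason."""

    value: float | None
    ci: tuple[float, float] | None = None
    n: int | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with a declared positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive: str = "cancer"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ConfigurationError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = "cancer") -> "ConfusionMatrix":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            tp=int((yt & yp).sum()),
            fp=int((~yt & yp).sum()),
            tn=int((~yt & ~yp).sum()),
            fn=int((yt & ~yp).sum()),
            positive=positive,
        )


@dataclass
class EvalReport:
    """The metric panel: proportions with exact CIs, plus F1 and AUC."""

    accuracy: Metric
    sensitivity: Metric
    specificity: Metric
    precision: Metric
    f1: Metric
    auc: Metric | None
    n: int
    confusion: ConfusionMatrix | None = None

    def metric_values(self) -> dict[str, float | None]:
        out = {
            "accuracy": self.accuracy.value,
            "sensitivity": self.sensitivity.value,
            "specificity": self.specificity.value,
            "precision": self.precision.value,
            "f1": self.f1.value,
        }
        out["auc"] = self.auc.value if self.auc is not None else None
        return out

    def to_dict(self) -> dict:
        def enc(m: Metric | None):
            if m is None:
                return None
            return {"value": m.value, "ci": m.ci, "n": m.n, "reason": m.reason}

        d = {k: enc(getattr(self, k)) for k in
             ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")}
        d["n"] = self.n
        if self.confusion is not None:
            d["confusion"] = {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "tn": self.confusion.tn, "fn": self.confusion.fn,
                "positive": self.confusion.positive,
            }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_table(self) -> str:
        """Human-readable one-row table: accuracy … AUC with 95% CIs."""
        cells = []
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc"):
            m = getattr(self, name)
            if m is None or not m.defined:
                reason = m.reason if m is not None else "not computed"
                cells.append(f"{name}: — ({reason})")
            elif m.ci is not None:
                cells.append(f"{name}: {100 * m.value:.1f}% ({100 * m.ci[0]:.1f}–{100 * m.ci[1]:.1f}%)")
            else:
                cells.append(f"{name}: {m.value:.3f}")
        return f"n={self.n} | " + " | ".join(cells)


def _ratio(x: int, d: int, what: str, alpha: float) -> Metric:
    if d == 0:
        return Metric(None, reason=f"{what} undefined: zero denominator", n=0)
    return Metric(x / d, ci=clopper_pearson(x, d, alpha), n=d)


def metrics_from_confusion(cm: ConfusionMatrix, alpha: float = 0.05) -> EvalReport:
    """Accuracy, sensitivity, specificity, precision (with exact CIs) and F1."""
    acc = _ratio(cm.tp + cm.tn, cm.total, "accuracy", alpha)
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", alpha)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", alpha)
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision", alpha)
    if prec.defined and sens.defined and (prec.value + sens.value) > 0:
        f1 = Metric(2 * prec.value * sens.value / (prec.value + sens.value))
    else:
        f1 = Metric(None, reason="F1 undefined: precision or sensitivity absent or both zero")
    return EvalReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec,
        f1=f1, auc=None, n=cm.total, confusion=cm,
    )


def auc(scores, labels) -> float:
    """ROC AUC (Mann–Whitney statistic with midrank tie handling)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def evaluate_classifier(
    bundle: ModelBundle, slices, positive: str = "cancer", alpha: float = 0.05
) -> EvalReport:
    """Full metric panel for a trained classifier on labeled slices."""
    from .finetune import predict_proba

    if bundle.class_names is None or positive not in bundle.class_names:
        raise ConfigurationError(f"bundle does not know class {positive!r}")
    proba = predict_proba(bundle, slices)
    names = list(bundle.class_names)
    pos_idx = names.index(positive)
    y_true = [ls.label for ls in slices]
    y_pred = [names[i] for i in proba.argmax(axis=1)]
    cm = ConfusionMatrix.from_labels(y_true, y_pred, positive)
    report = metrics_from_confusion(cm, alpha)
    y_bin = np.array([t == positive for t in y_true], dtype=int)
    if len(np.unique(y_bin)) == 2:
        report.auc = Metric(auc(proba[:, pos_idx], y_bin), n=len(slices))
    else:
        report.auc = Metric(None, reason="AUC undefined: single-class labels")
    return report


def grad_cam(bundle: ModelBundle, image: ImageSlice | np.ndarray, target_class) -> np.ndarray:
    """Gradient-weighted class activation map in [0, 1] at image resolution.

    The gradient of the target-class logit w.r.t. the last encoder feature
    map is pooled channel-wise into weights; the rectified weighted feature
    sum is bilinearly upsampled and max-normalized (an all-zero map stays
    all-zero).
    """
    if bundle.task != "classification":
        raise ConfigurationError("grad_cam needs a classifier bundle")
    pixels = image.pixels if isinstance(image, ImageSlice) else np.asarray(image)
    if isinstance(target_class, str):
        if bundle.class_names is None or target_class not in bundle.class_names:
            raise ConfigurationError(f"unknown class {target_class!r}")
        target_idx = list(bundle.class_names).index(target_class)
    else:
        target_idx = int(target_class)
    x = to_batch([pixels])
    logits = bundle.forward(x)
    feat = bundle.last_feat
    # target score = softmax probability: its gradient contrasts the target
    # class against the others, removing the class-agnostic component that a
    # raw-logit gradient would keep
    z = logits[0].astype(np.float64)
    z -= z.max()
    p = np.exp(z) / np.exp(z).sum()
    dlogits = (-p[target_idx] * p).astype(logits.dtype)[None]
    dlogits[0, target_idx] += p[target_idx]
    dfeat, _ = bundle.head.backward(dlogits)
    weights = dfeat.mean(axis=(2, 3))[0]  # (C,)
    cam = np.maximum((weights[:, None, None] * feat[0]).sum(axis=0), 0.0)
    cam = resize(cam.astype(np.float64), pixels.shape, order=1, preserve_range=True,
                 anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam


def one_vs_rest_reports(y_true, y_pred, alpha: float = 0.05) -> dict[str, EvalReport]:
    """Multiclass reduction: one binary report per class, plus a macro average.

    Each class in turn is the positive class against the rest.  The
    ``"macro"`` entry averages the defined point estimates across classes
    (absent metrics are skipped, not zero-filled) and carries no CIs.
    """
    classes = sorted(set(y_true))
    out: dict[str, EvalReport] = {}
    for c in classes:
        cm = ConfusionMatrix.from_labels(y_true, y_pred, positive=c)
        out[c] = metrics_from_confusion(cm, alpha)
    names = ("accuracy", "sensitivity", "specificity", "precision", "f1")
    macro = {}
    for name in names:
        vals = [getattr(out[c], name).value for c in classes if getattr(out[c], name).defined]
        macro[name] = (
            Metric(float(np.mean(vals)), n=len(vals)) if vals
            else Metric(None, reason=f"{name} undefined for every class")
        )
    out["macro"] = EvalReport(
        accuracy=macro["accuracy"], sensitivity=macro["sensitivity"],
        specificity=macro["specificity"], precision=macro["precision"],
        f1=macro["f1"], auc=None, n=len(y_true),
    )
    return out


DEFAULT_STRATA = ((0.0, 20.0, "T1-like (<=20 mm)"), (20.0, 40.0, "T2-like (20-40 mm)"),
                  (40.0, float("inf"), ">40 mm"))


def stratified_accuracy(
    y_true, y_pred, stage_proxy_mm, strata=DEFAULT_STRATA, alpha: float = 0.05
) -> pd.DataFrame:
    """Accuracy with exact CI per tumor-size stratum, plus an all-cases row.

    Slices whose stage proxy is NaN (no tumor) form their own stratum.  An
    empty stratum yields an absent-with-reason row, never an exception.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    size = np.asarray(stage_proxy_mm, dtype=float)
    correct = y_true == y_pred
    rows = []

    def add(name, sel):
        n = int(sel.sum())
        if n == 0:
            rows.append({"stratum": name, "n": 0, "accuracy": None, "ci_low": None,
                         "ci_high": None, "reason": "empty stratum"})
            return
        k = int(correct[sel].sum())
        lo, hi = clopper_pearson(k, n, alpha)
        rows.append({"stratum": name, "n": n, "accuracy": k / n, "ci_low": lo,
                     "ci_high": hi, "reason": None})

    add("no tumor", np.isnan(size))
    for lo_mm, hi_mm, name in strata:
        add(name, (~np.isnan(size)) & (size > lo_mm) & (size <= hi_mm))
    add("all", np.ones_like(correct, dtype=bool))
    return pd.DataFrame(rows)
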