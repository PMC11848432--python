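"""Evaluation artifacts: confusion matrix, per-class accuracy, one-vs-rest
ROC/AUC, SmoothGrad saliency, and 2-D feature embeddings."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.metrics import silhouette_score

from ._seeding import substream
from .nn import core as nn_core
from .records import LABELS
from .sleepnet import SleepNet, extract_features

__all__ = ["EvalReport", "SaliencyMap", "evaluate", "smoothgrad", "embed_2d"]


@dataclass
class EvalReport:
    confusion: np.ndarray              # (6, 6) rows = true, cols = predicted
    per_class_accuracy: np.ndarray     # (6,)
    overall_accuracy: float
    roc: dict                          # label -> (fpr, tpr) arrays
    auc: dict                          # label -> float or None (class absent)
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "labels": list(LABELS),
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": [
                None if np.isnan(a) else float(a) for a in self.per_class_accuracy
            ],
            "overall_accuracy": self.overall_accuracy,
            "auc": {k: (None if v is None else float(v)) for k, v in self.auc.items()},
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "n_evaluated": self.n_evaluated,
        }

    @property
    def macro_auc(self) -> float | None:
        vals = [v for v in self.auc.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    micro_auc: float | None = None


def evaluate(model_or_scores, X_or_labels, y=None) -> EvalReport:
    """Evaluate a classifier (or pre-computed scores) on labeled epochs.

    Either ``evaluate(model, X, y)`` with a model exposing ``predict_proba``,
    or ``evaluate(scores, y)`` with an ``(n, 6)`` score matrix. Predictions
    are argmax with ties to the lowest class index; ROC is one-vs-rest on the
    class score; AUC is the trapezoidal area over the full threshold sweep.
    A class absent from ``y`` gets ``None`` AUC rather than a fabricated one.
    """
    if y is None:
        scores = np.asarray(model_or_scores, dtype=float)
        y = np.asarray(X_or_labels, dtype=int)
    else:
        scores = model_or_scores.predict_proba(np.asarray(X_or_labels))
        y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    n_cls = len(LABELS)
    preds = scores.argmax(axis=1)  # np.argmax ties -> lowest index
    conf = np.zeros((n_cls, n_cls), dtype=int)
    np.add.at(conf, (y, preds), 1)
    row = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(conf) / np.maximum(row, 1), np.nan)
    roc, aucs = {}, {}
    present_mask = np.zeros(len(y), dtype=bool)
    for c, lab in enumerate(LABELS):
        pos = y == c
        if pos.sum() == 0 or pos.sum() == len(y):
            roc[lab], aucs[lab] = None, None
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), scores[:, c])
        roc[lab] = (fpr, tpr)
        aucs[lab] = float(_trapezoid_auc(fpr, tpr))
        present_mask |= pos
    # micro-average over the pooled one-vs-rest decisions of present classes
    present = [c for c, lab in enumerate(LABELS) if aucs[lab] is not None]
    micro = None
    if present:
        onehot = np.concatenate([(y == c).astype(int) for c in present])
        pooled = np.concatenate([scores[:, c] for c in present])
        fpr, tpr, _ = roc_curve(onehot, pooled)
        micro = float(_trapezoid_auc(fpr, tpr))
    report = EvalReport(
        confusion=conf,
        per_class_accuracy=per_class,
        overall_accuracy=float(np.trace(conf) / conf.sum()),
        roc=roc,
        auc=aucs,
        n_evaluated=len(y),
    )
    report.micro_auc = micro
    return report


# --------------------------------------------------------------------------

@dataclass
class SaliencyMap:
    contributions: np.ndarray
    target_class: int
    n_samples: int
    noise_sd: float
    epoch_reference: str = ""


def smoothgrad(
    model: SleepNet,
    epoch_values: np.ndarray,
    target_class: int,
    n: int = 50,
    noise_sd: float | None = None,
    seed: int = 0,
) -> SaliencyMap:
    """SmoothGrad saliency: mean input gradient over noise-perturbed copies.

    ``noise_sd=None`` uses 0.1 x the input standard deviation (the common
    convention). With ``noise_sd=0, n=1`` this reduces exactly to the plain
    gradient of the target-class logit.
    """
    x = np.asarray(epoch_values, dtype=nn_core.DTYPE)
    if x.ndim != 1:
        raise ValueError("smoothgrad expects a single epoch vector")
    if noise_sd is None:
        noise_sd = 0.1 * float(x.std())
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "smoothgrad")
    if noise_sd == 0:
        batch = np.repeat(x[None, :], n, axis=0)
    else:
        batch = x[None, :] + rng.normal(0.0, noise_sd, size=(n, x.size)).astype(x.dtype)
    grads = model.input_gradient(batch, target_class)
    return SaliencyMap(
        contributions=np.asarray(grads, dtype=float).mean(axis=0),
        target_class=int(target_class),
        n_samples=int(n),
        noise_sd=float(noise_sd),
    )


# --------------------------------------------------------------------------

def embed_2d(
    features: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    labels: np.ndarray | None = None,
) -> dict:
    """Seeded t-SNE embedding of feature vectors to 2-D.

    Returns ``{"coords": (n, 2), "silhouette": float | None}``; the
    silhouette score by class (when labels are given) is the quantitative
    proxy for visual cluster separation.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 10:
        raise ValueError("need at least 10 feature vectors")
    if np.allclose(features.var(axis=0), 0):
        raise ValueError("degenerate identical feature vectors")
    perplexity = min(perplexity, (features.shape[0] - 1) / 3)
    ts = TSNE(
        n_components=2,
        random_state=int(seed),
        perplexity=perplexity,
        init="pca",
    )
    coords = ts.fit_transform(features)
    sil = None
    if labels is not None and len(np.unique(labels)) > 1:
        sil = float(silhouette_score(coords, labels))
    return {"coords": coords, "silhouette": sil}
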