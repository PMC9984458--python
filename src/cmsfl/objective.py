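"""Class weighting, weighted categorical cross-entropy, and AS/F1 metrics.

The loss is the class-weighted categorical cross-entropy

    L = -(1/M) * sum_j sum_i  omega_j * y_i^j * log p_i^j

which reduces to the ordinary cross-entropy when all omega_j = 1. Class
weights can come from three sources: ``uniform`` (all ones),
``inverse_frequency`` (omega_j proportional to 1/count_j, normalized to sum
to J so balanced data gives all ones — the conventional imbalance remedy),
or ``cosine_softmax`` (the softmax of scaled cosine similarities between a
feature vector and the l2-normalized last-layer class vectors, i.e. the
cosine-classifier output itself used as a weight). Evaluation reports the
accuracy score AS (fraction of correctly classified instances) and the
macro-averaged one-vs-rest F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import CosineHeadParams

PROB_CLAMP = 1e-12


@dataclass
class ClassWeights:
    """Per-class positive loss weights omega and their provenance."""

    omega: np.ndarray
    source: str = "uniform"

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=np.float64)
        if self.omega.ndim != 1 or np.any(self.omega <= 0):
            raise ValueError("omega must be a vector of positive reals")
        if self.source not in ("cosine_softmax", "inverse_frequency", "uniform"):
            raise ValueError(f"unknown weight source {self.source!r}")
        if self.source == "cosine_softmax" and abs(self.omega.sum() - 1.0) > 1e-6:
            raise ValueError("cosine_softmax weights must sum to 1")


def cosine_class_weights(features: np.ndarray, head: CosineHeadParams) -> ClassWeights:
    """Softmax of scale * cosine(feature, class vector), per class.

    Invariant to positive rescaling of the feature and of any class vector.
    """
    f = np.asarray(features, dtype=np.float64).ravel()
    norm = np.linalg.norm(f)
    if norm == 0:
        raise ValueError("feature vector must be nonzero")
    u = f / norm
    v = head.class_vectors / np.linalg.norm(head.class_vectors, axis=1, keepdims=True)
    z = head.scale_value * (v @ u)
    z -= z.max()
    w = np.exp(z)
    return ClassWeights(w / w.sum(), source="cosine_softmax")


def frequency_class_weights(labels: np.ndarray, n_classes: int) -> ClassWeights:
    """Inverse-frequency weights, normalized so they sum to n_classes."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_classes)
    if np.any(counts[:n_classes] == 0):
        empty = np.flatnonzero(counts[:n_classes] == 0).tolist()
        raise ValueError(
            f"classes {empty} have no samples; inverse-frequency weights are "
            f"undefined — use uniform weights instead"
        )
    w = 1.0 / counts[:n_classes]
    w *= n_classes / w.sum()
    return ClassWeights(w, source="inverse_frequency")


def uniform_class_weights(n_classes: int) -> ClassWeights:
    return ClassWeights(np.ones(n_classes), source="uniform")


def _check_stochastic(probabilities: np.ndarray) -> np.ndarray:
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("probabilities must be a matrix (M, J)")
    if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must be non-negative and sum to 1")
    return p


def weighted_cce(probabilities: np.ndarray, targets: np.ndarray,
                 omega: ClassWeights) -> float:
    """Weighted categorical cross-entropy of a row-stochastic matrix against
    one-hot targets; probabilities are clamped at 1e-12 before the log."""
    p = _check_stochastic(probabilities)
    t = np.asarray(targets, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError(f"targets shape {t.shape} != probabilities {p.shape}")
    m = p.shape[0]
    logs = np.log(np.maximum(p, PROB_CLAMP))
    return float(-(omega.omega[None, :] * t * logs).sum() / m)


def weighted_cce_grad(probabilities: np.ndarray, targets: np.ndarray,
                      omega: ClassWeights) -> np.ndarray:
    """Analytic gradient of :func:`weighted_cce` w.r.t. the probabilities."""
    p = _check_stochastic(probabilities)
    t = np.asarray(targets, dtype=np.float64)
    m = p.shape[0]
    g = np.zeros_like(p)
    mask = p > PROB_CLAMP
    g[mask] = -(omega.omega[None, :] * t)[mask] / (m * p[mask])
    return g


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_wcce_with_grad(scores: np.ndarray, labels: np.ndarray,
                           omega: ClassWeights) -> tuple[float, np.ndarray]:
    """Fused softmax + weighted cross-entropy for training.

    Returns the loss and its gradient with respect to the raw scores:
    for sample i with true class c, d L / d s_i = omega_c / M * (p_i - e_c).
    """
    p = softmax(np.asarray(scores, dtype=np.float64))
    m, j = p.shape
    labels = np.asarray(labels)
    w = omega.omega[labels]
    loss = float(-(w * np.log(np.maximum(p[np.arange(m), labels], PROB_CLAMP))).sum() / m)
    g = p * w[:, None]
    g[np.arange(m), labels] -= w
    return loss, (g / m).astype(scores.dtype)


@dataclass
class EvalReport:
    """Accuracy score, macro F1 and per-class confusion summaries."""

    as_score: float
    f1_macro: float
    per_class: list[dict] = field(default_factory=list)
    absent_classes: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "as": self.as_score,
                "f1_macro": self.f1_macro,
                "per_class": self.per_class,
                "absent_classes": self.absent_classes,
            },
            indent=2,
        )


def evaluate(predictions: np.ndarray, truth: np.ndarray, n_classes: int
             ) -> EvalReport:
    """AS = fraction correct; per-class one-vs-rest precision/recall/F1 and
    their unweighted (macro) mean.

    A class absent from both predictions and truth contributes F1 = 0 and is
    flagged in ``absent_classes``; precision/recall with a zero denominator
    are reported as 0.
    """
    yhat = np.asarray(predictions)
    y = np.asarray(truth)
    if yhat.shape != y.shape or yhat.ndim != 1:
        raise ValueError(
            f"predictions and truth must be equal-length vectors, got "
            f"{yhat.shape} vs {y.shape}"
        )
    if y.size == 0:
        raise ValueError("cannot evaluate an empty label vector")
    for v, name in ((yhat, "predictions"), (y, "truth")):
        if v.min() < 0 or v.max() >= n_classes:
            raise ValueError(f"{name} contain labels outside [0, {n_classes})")
    m = y.size
    as_score = float((yhat == y).sum() / m)
    per_class, f1s, absent = [], [], []
    for c in range(n_classes):
        tp = int(((yhat == c) & (y == c)).sum())
        fp = int(((yhat == c) & (y != c)).sum())
        fn = int(((yhat != c) & (y == c)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if tp + fp + fn == 0:
            absent.append(c)
        per_class.append(
            {"class": c, "tp": tp, "fp": fp, "fn": fn,
             "precision": prec, "recall": rec, "f1": f1}
        )
        f1s.append(f1)
    return EvalReport(as_score, float(np.mean(f1s)), per_class, absent)
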