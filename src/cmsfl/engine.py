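"""Training and inference orchestration.

The training pipeline follows the fixed order tensorize -> resize ->
standardize (training statistics only) -> augment, minimizes the weighted
categorical cross-entropy with Adam (first-moment decay gamma = 0.9 by
default, second-moment decay 0.999, epsilon 1e-8), and records per-epoch
loss/AS/F1. Inference re-applies the identical pipeline *minus
augmentation*; :func:`predict` refuses standardization statistics whose
digest does not match the one stored with the trained parameters, so the
train/test-distribution contract is enforced structurally rather than by
convention.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import preprocessing as pp
from .accounting import network_cost
from .network import (
    NetworkConfig,
    NetworkParams,
    backward,
    build_network,
    forward,
    forward_with_cache,
    save_checkpoint,
)
from .objective import (
    ClassWeights,
    evaluate,
    frequency_class_weights,
    softmax,
    softmax_wcce_with_grad,
    uniform_class_weights,
    weighted_cce,
)
from .synthetic import LabeledImageSet

ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8
LARGE_SCALE_SIDE = 96  # image-side threshold switching the batch default


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule constants.

    Defaults: 50 epochs, Adam with learning rate 1e-4 and first-moment
    decay 0.9; mini-batch 64 for small-scale images and 16 at or above a
    96-pixel side (set ``batch_size`` explicitly to override).
    """

    epochs: int = 50
    learning_rate: float = 1e-4
    momentum_beta: float = 0.9
    batch_size: int | None = None
    seed: int = 0
    augmentation: str | tuple | None = None  # "default", explicit policy, or None
    weight_mode: str = "inverse_frequency"
    target_train_as: float | None = None  # optional early-stop on train AS

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if not 0.0 <= self.momentum_beta < 1.0:
            raise ValueError(
                f"momentum_beta must be in [0, 1), got {self.momentum_beta}"
            )
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.weight_mode not in ("inverse_frequency", "uniform"):
            raise ValueError(f"unsupported weight_mode {self.weight_mode!r}")

    def resolve_batch_size(self, input_side: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 16 if input_side >= LARGE_SCALE_SIDE else 64

    def resolve_policy(self):
        if self.augmentation is None:
            return ()
        if self.augmentation == "default":
            return pp.DEFAULT_POLICY
        return tuple(self.augmentation)


@dataclass
class History:
    """Per-epoch training records (wall-clock deliberately excluded)."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int | None = None

    def __len__(self) -> int:
        return len(self.records)

    def append(self, **kv) -> None:
        self.records.append(kv)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.records[0].keys()))
            writer.writeheader()
            writer.writerows(self.records)


class _Adam:
    def __init__(self, arrays: dict[str, np.ndarray], lr: float, beta1: float):
        self.arrays = arrays
        self.lr, self.b1, self.b2 = lr, beta1, ADAM_BETA2
        self.m = {k: np.zeros_like(a, dtype=np.float64) for k, a in arrays.items()}
        self.v = {k: np.zeros_like(a, dtype=np.float64) for k, a in arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, a in self.arrays.items():
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            update = (self.lr / bc1) * self.m[k] / (
                np.sqrt(self.v[k] / bc2) + ADAM_EPS
            )
            a -= update.astype(a.dtype)


def _class_weights(labels: np.ndarray, n_classes: int, mode: str) -> ClassWeights:
    if mode == "uniform":
        return uniform_class_weights(n_classes)
    return frequency_class_weights(labels, n_classes)


def _eval_scores(params: NetworkParams, x: np.ndarray, batch: int) -> np.ndarray:
    out = [forward(params, x[i : i + batch], mode="eval")
           for i in range(0, x.shape[0], batch)]
    return np.concatenate(out, axis=0)


def _one_hot(labels: np.ndarray, j: int) -> np.ndarray:
    out = np.zeros((labels.size, j))
    out[np.arange(labels.size), labels] = 1.0
    return out


def train(
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    net_cfg: NetworkConfig,
    tc: TrainConfig,
    out_dir: str | Path | None = None,
) -> tuple[NetworkParams, History]:
    """Fit the network; returns final parameters and the full history.

    The best-validation-AS epoch is recorded in ``history.best_epoch`` and,
    when ``out_dir`` is given, checkpointed there alongside the config
    snapshot, statistics digest and per-epoch CSV.
    """
    j = train_set.n_classes
    missing = set(np.unique(val_set.labels)) - set(np.unique(train_set.labels))
    if missing:
        raise ValueError(
            f"classes {sorted(missing)} present in validation but absent from "
            f"training: class weights are undefined"
        )
    side = net_cfg.input_side
    batch = tc.resolve_batch_size(side)

    xtr = pp.resize(train_set.images, side)
    stats = pp.fit_stats(xtr)
    xtr = pp.standardize(xtr, stats)
    ytr = train_set.labels
    policy = tc.resolve_policy()
    if policy:
        xtr, src = pp.augment_batch(xtr, policy, seed=tc.seed)
        ytr = ytr[src]
    xval = pp.standardize(pp.resize(val_set.images, side), stats)
    yval = val_set.labels

    omega = _class_weights(ytr, j, tc.weight_mode)
    params = build_network(net_cfg, seed=tc.seed)
    params.stats_digest = stats.digest()
    arrays = dict(params.named_arrays(trainable_only=True))
    opt = _Adam(arrays, tc.learning_rate, tc.momentum_beta)
    rng = np.random.default_rng(tc.seed)

    history = History()
    best_as, best_params = -1.0, None
    yval_1h = _one_hot(yval, j)
    for epoch in range(1, tc.epochs + 1):
        perm = rng.permutation(xtr.shape[0])
        losses = []
        for lo in range(0, perm.size, batch):
            sel = perm[lo : lo + batch]
            scores, caches = forward_with_cache(params, xtr[sel], mode="train")
            loss, dscores = softmax_wcce_with_grad(scores, ytr[sel], omega)
            grads, _ = backward(params, dscores, caches)
            opt.step(grads)
            losses.append(loss)
        val_scores = _eval_scores(params, xval, batch)
        val_probs = softmax(val_scores)
        val_loss = weighted_cce(val_probs, yval_1h, omega)
        val_report = evaluate(val_scores.argmax(axis=1), yval, j)
        rec = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_as": val_report.as_score,
            "val_f1": val_report.f1_macro,
        }
        if tc.target_train_as is not None:
            tr_scores = _eval_scores(params, xtr, batch)
            rec["train_as"] = evaluate(tr_scores.argmax(axis=1), ytr, j).as_score
        history.append(**rec)
        if val_report.as_score > best_as:
            best_as = val_report.as_score
            history.best_epoch = epoch
            best_params = copy.deepcopy(params)
        if tc.target_train_as is not None and rec["train_as"] >= tc.target_train_as:
            break

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(params, out / "final.npz")
        save_checkpoint(best_params, out / "best.npz")
        history.to_csv(out / "history.csv")
        (out / "stats.json").write_text(json.dumps({
            "mean": np.asarray(stats.mean).tolist(),
            "sd": np.asarray(stats.sd).tolist(),
            "digest": stats.digest(),
        }))
        (out / "config.json").write_text(json.dumps({
            "network": params.config.__dict__,
            "train": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in tc.__dict__.items()
                      if not isinstance(v, tuple) or k != "augmentation"},
        }, default=str))
    params._train_stats = stats  # convenience handle for predict()
    return params, history


def predict(
    params: NetworkParams,
    stats: pp.StandardizationStats,
    raw: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify raw images with the trained model.

    Applies the training pipeline minus augmentation (resize, standardize
    with the *training* statistics, eval-mode forward), then row-normalizes
    the scores with a softmax and takes the arg-max (ties resolve to the
    lower class index). Statistics whose digest differs from the one stored
    at training time are rejected.
    """
    if params.stats_digest is None:
        raise ValueError("parameters carry no training-statistics digest")
    if stats.digest() != params.stats_digest:
        raise ValueError(
            "standardization statistics do not match the training run: "
            "inference must standardize with the training-set distribution"
        )
    x = pp.as_batch(raw)
    if x.shape[1] != params.config.input_channels:
        raise ValueError(
            f"expected {params.config.input_channels} channels, got {x.shape[1]}"
        )
    x = pp.standardize(pp.resize(x, params.config.input_side), stats)
    scores = _eval_scores(params, x, 64)
    probs = softmax(scores)
    return probs.argmax(axis=1), probs


@dataclass
class AblationRow:
    num_modules: int
    trainable_params: int
    val_as: float
    val_f1: float


def run_ablation(
    sizes,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
    net_cfg: NetworkConfig,
    tc: TrainConfig,
) -> list[AblationRow]:
    """Re-train the network at several module counts on fixed data.

    Each size gets a fresh network built and trained under the same
    TrainConfig; the parameter column comes from the cost ledger.
    Deterministic given the TrainConfig seed.
    """
    rows = []
    for n in sizes:
        cfg = NetworkConfig(**{**net_cfg.__dict__, "num_modules": int(n)})
        params, history = train(train_set, val_set, cfg, tc)
        last = history.records[-1]
        rows.append(AblationRow(
            num_modules=int(n),
            trainable_params=network_cost(cfg).total_params,
            val_as=last["val_as"],
            val_f1=last["val_f1"],
        ))
    return rows
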