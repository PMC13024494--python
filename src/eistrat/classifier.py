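"""Desk-scale joint classification/regression model for affect recognition.

Stand-in for a large pretrained vision backbone with parallel heads: a small
feed-forward encoder (two tanh hidden layers) shared by a binary
classification head (one logit -> sigmoid) and a regression head predicting
the frame's continuous affect estimate. The training objective is the
weighted sum

    L = L_BCE + lambda * L_MSE        (lambda = 0.4 by default)

with inverse-frequency class weighting on the BCE term. Training follows a
two-stage schedule — stage 1 freezes the encoder and trains only the heads,
stage 2 fine-tunes everything — using AdamW (decoupled weight decay),
global gradient-norm clipping at 1.0, and a per-stage linear warm-up +
cosine decay learning-rate schedule. The decision threshold is chosen on the
validation set by macro-F1 grid search over [0.2, 0.8] and then applied
unchanged everywhere. All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TrainingConfig

_ENCODER = ("W1", "b1", "W2", "b2")
_HEADS = ("wc", "bc", "wr", "br")
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


class TrainingError(ValueError):
    """Raised when the training data cannot support model fitting."""


@dataclass
class TrainedModel:
    """Fitted encoder + heads with the selected decision threshold."""

    params: dict[str, np.ndarray]
    threshold: float
    group_tag: str  # "High" | "Low" | "Total"
    init_tag: str  # "fresh" | "from-High" | "from-Low"
    config: TrainingConfig = field(repr=False, default=None)
    class_weights: tuple[float, float] = (1.0, 1.0)
    loss_history: list[float] = field(default_factory=list, repr=False)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid output of the classification head, in (0, 1)."""
        logit, _ = _forward(np.asarray(X, dtype=float), self.params)[:2]
        return _sigmoid(logit)

    def regression_output(self, X: np.ndarray) -> np.ndarray:
        return _forward(np.asarray(X, dtype=float), self.params)[1]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_params(n_features: int, config: TrainingConfig, seed: int) -> dict[str, np.ndarray]:
    h1, h2 = config.hidden_sizes
    rng = np.random.default_rng([17, seed])
    return {
        "W1": rng.normal(0.0, 1.0 / math.sqrt(n_features), (n_features, h1)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0.0, 1.0 / math.sqrt(h1), (h1, h2)),
        "b2": np.zeros(h2),
        "wc": rng.normal(0.0, 1.0 / math.sqrt(h2), h2),
        "bc": np.zeros(()),
        "wr": rng.normal(0.0, 1.0 / math.sqrt(h2), h2),
        "br": np.zeros(()),
    }


def _forward(X, params):
    h1 = np.tanh(X @ params["W1"] + params["b1"])
    h2 = np.tanh(h1 @ params["W2"] + params["b2"])
    logit = h2 @ params["wc"] + params["bc"]
    reg = h2 @ params["wr"] + params["br"]
    return logit, reg, h1, h2


def bce_with_logits(logit, y, sample_weight=None) -> float:
    """Numerically stable weighted binary cross-entropy (mean over items)."""
    logit = np.asarray(logit, dtype=float)
    y = np.asarray(y, dtype=float)
    per = np.maximum(logit, 0.0) - logit * y + np.log1p(np.exp(-np.abs(logit)))
    if sample_weight is not None:
        per = per * sample_weight
    return float(per.mean())


def joint_loss(class_logit, class_label, reg_pred, reg_target, config: TrainingConfig,
               sample_weight=None) -> float:
    """Joint objective: weighted BCE on the logit + lambda × mean squared error."""
    mse = float(np.mean((np.asarray(reg_pred, float) - np.asarray(reg_target, float)) ** 2))
    return bce_with_logits(class_logit, class_label, sample_weight) + config.lambda_reg * mse


def _grads(X, y, t, w, params, lam):
    """Backprop of the joint loss for one batch (mean reduction)."""
    n = len(y)
    logit, reg, h1, h2 = _forward(X, params)
    dlogit = w * (_sigmoid(logit) - y) / n
    dreg = 2.0 * lam * (reg - t) / n
    g = {}
    g["wc"] = h2.T @ dlogit
    g["bc"] = np.asarray(dlogit.sum())
    g["wr"] = h2.T @ dreg
    g["br"] = np.asarray(dreg.sum())
    dh2 = (np.outer(dlogit, params["wc"]) + np.outer(dreg, params["wr"])) * (1.0 - h2**2)
    g["W2"] = h1.T @ dh2
    g["b2"] = dh2.sum(axis=0)
    dh1 = (dh2 @ params["W2"].T) * (1.0 - h1**2)
    g["W1"] = X.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return g


def inverse_frequency_weights(y: np.ndarray) -> tuple[float, float]:
    """Per-class loss weights proportional to 1/frequency, normalized to mean 1."""
    y = np.asarray(y)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise TrainingError("training data must contain both classes")
    inv = np.array([1.0 / n0, 1.0 / n1])
    w = 2.0 * inv / inv.sum()
    return float(w[0]), float(w[1])


def _lr_at(step, total_steps, warmup_steps, base_lr):
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    denom = max(total_steps - warmup_steps, 1)
    prog = (step - warmup_steps) / denom
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * min(prog, 1.0)))


def train_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    reg_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainingConfig,
    seed: int = 0,
    group_tag: str = "Total",
    init: dict[str, np.ndarray] | None = None,
    init_tag: str = "fresh",
) -> TrainedModel:
    """Fit the joint model under the staged schedule; deterministic given seed."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    reg_train = np.asarray(reg_train, dtype=float)
    if len(X_train) == 0 or len(X_val) == 0:
        raise TrainingError("train and validation sets must be nonempty")
    w0, w1 = inverse_frequency_weights(y_train)
    sample_w = np.where(y_train == 1, w1, w0)

    params = {k: v.copy() for k, v in (init or init_params(X_train.shape[1], config, seed)).items()}
    rng = np.random.default_rng([19, seed])
    state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
    adam_t = 0
    n = len(y_train)
    bs = config.batch_size
    steps_per_epoch = max(1, math.ceil(n / bs))
    history: list[float] = []

    for stage in config.stage_schedule:
        trainable = _HEADS if stage.scope == "heads" else _ENCODER + _HEADS
        total_steps = stage.epochs * steps_per_epoch
        warmup = min(config.warmup_epochs, max(stage.epochs - 1, 0)) * steps_per_epoch
        step = 0
        for _ in range(stage.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for b0 in range(0, n, bs):
                idx = order[b0 : b0 + bs]
                Xb = X_train[idx]
                if config.feature_jitter_sd > 0:
                    Xb = Xb + rng.normal(0.0, config.feature_jitter_sd, Xb.shape)
                g = _grads(Xb, y_train[idx], reg_train[idx], sample_w[idx], params, config.lambda_reg)
                norm = math.sqrt(sum(float((g[k] ** 2).sum()) for k in trainable))
                scale = config.clip_norm / norm if norm > config.clip_norm else 1.0
                lr = _lr_at(step, total_steps, warmup, stage.lr)
                adam_t += 1
                for k in trainable:
                    m, v = state[k]
                    gk = g[k] * scale
                    m[...] = _ADAM_B1 * m + (1 - _ADAM_B1) * gk
                    v[...] = _ADAM_B2 * v + (1 - _ADAM_B2) * gk**2
                    mhat = m / (1 - _ADAM_B1**adam_t)
                    vhat = v / (1 - _ADAM_B2**adam_t)
                    params[k] = params[k] - lr * (
                        mhat / (np.sqrt(vhat) + _ADAM_EPS) + config.weight_decay * params[k]
                    )
                logit, reg, _, _ = _forward(Xb, params)
                epoch_loss += joint_loss(logit, y_train[idx], reg, reg_train[idx], config,
                                         sample_w[idx])
                step += 1
            history.append(epoch_loss / steps_per_epoch)

    val_scores = _sigmoid(_forward(np.asarray(X_val, dtype=float), params)[0])
    threshold = select_threshold(val_scores, np.asarray(y_val), config)
    return TrainedModel(
        params=params,
        threshold=threshold,
        group_tag=group_tag,
        init_tag=init_tag,
        config=config,
        class_weights=(w0, w1),
        loss_history=history,
    )


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of the two per-class F1 scores (0 when undefined)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    f1s = []
    for cls in (0, 1):
        tp = int(((y_pred == cls) & (y_true == cls)).sum())
        fp = int(((y_pred == cls) & (y_true != cls)).sum())
        fn = int(((y_pred != cls) & (y_true == cls)).sum())
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def threshold_grid(config: TrainingConfig) -> np.ndarray:
    n = int(round((config.threshold_hi - config.threshold_lo) / config.threshold_step))
    return config.threshold_lo + config.threshold_step * np.arange(n + 1)


def select_threshold(scores: np.ndarray, labels: np.ndarray, config: TrainingConfig) -> float:
    """Macro-F1-maximizing decision threshold on the validation grid.

    Ties break toward 0.5, then toward the lower threshold. With
    single-class validation labels the threshold defaults to 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class validation labels: threshold defaults to 0.5")
        return 0.5
    grid = threshold_grid(config)
    f1 = np.array([macro_f1(labels, scores >= t) for t in grid])
    best = f1.max()
    cands = grid[f1 >= best - 1e-12]
    return float(min(cands, key=lambda t: (abs(t - 0.5), t)))


def predict(model: TrainedModel, X: np.ndarray, labels: np.ndarray | None = None) -> pd.DataFrame:
    """Score items and apply the model's threshold (class 1 when score ≥ τ)."""
    X = np.asarray(X, dtype=float)
    d = model.params["W1"].shape[0]
    if X.shape[1] != d:
        raise ValueError(f"feature dimension mismatch: model expects {d}, got {X.shape[1]}")
    score = model.decision_scores(X)
    pred = (score >= model.threshold).astype(int)
    out = pd.DataFrame({"score": score, "pred": pred})
    if labels is not None:
        out["label"] = np.asarray(labels).astype(int)
        out["correct"] = (out["pred"] == out["label"]).astype(int)
    return out


def pretrain_transfer(
    datasets: dict[str, tuple],
    config: TrainingConfig,
    seed: int = 0,
    transfer: bool = False,
) -> dict[str, TrainedModel]:
    """Train the model family: fresh High/Low/Total, optionally High→Total, Low→Total.

    ``datasets`` maps group tag -> (X_train, y_train, reg_train, X_val,
    y_val). Transfer models reuse a group-pretrained model's parameters as
    initialization and continue training on the Total data, holding the
    architecture and config constant.
    """
    for g in ("High", "Low", "Total"):
        if g not in datasets:
            raise ValueError(f"missing training partition for group {g!r}")
    models: dict[str, TrainedModel] = {}
    for g in ("High", "Low", "Total"):
        models[g] = train_model(*datasets[g], config=config, seed=seed, group_tag=g)
    if transfer:
        for g in ("High", "Low"):
            models[f"{g}->Total"] = train_model(
                *datasets["Total"],
                config=config,
                seed=seed,
                group_tag="Total",
                init=models[g].params,
                init_tag=f"from-{g}",
            )
    return models
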