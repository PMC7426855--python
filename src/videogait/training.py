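"""Training loop, losses, segment-count weighting and prediction debiasing.

Regression uses a segment-weighted squared error: a window of video *i*
contributes (y_i - yhat)^2 / c(i), where c(i) is the number of retained
windows of that video, so videos with more usable footage are not overly
emphasized.  Classification uses cross-entropy with the same 1/c(i)
weighting.  Per-video predictions are the mean over the video's windows, and
a linear calibration ("debiasing") fitted on training-set (prediction,
truth) pairs removes the systematic bias the window averaging introduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from videogait.nn import DTYPE, Network, RMSProp
from videogait.windowing import Segment, SegmentSet

PROB_CLIP = 1e-7


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published schedule
    (RMSProp, batch 32, initial lr 1e-3 decayed by 20% every 10 epochs,
    early stopping)."""

    batch_size: int = 32
    initial_lr: float = 1e-3
    lr_decay: float = 0.8
    lr_decay_every: int = 10
    max_epochs: int = 50
    early_stopping_patience: int = 10
    rho: float = 0.9
    seed: int = 0

    def learning_rate(self, epoch: int) -> float:
        """Learning rate in effect during ``epoch`` (0-based)."""
        return self.initial_lr * self.lr_decay ** (epoch // self.lr_decay_every)


@dataclass
class DebiasModel:
    """Linear calibration truth ≈ slope·prediction + intercept, fitted on
    training data only."""

    slope: float
    intercept: float


def weighted_mse_loss(y: np.ndarray | float, yhat: np.ndarray | float,
                      c: np.ndarray | int) -> np.ndarray | float:
    """Segment-weighted squared error (y - yhat)^2 / c.

    Summed over all of a video's identically-predicting segments this equals
    a single segment's squared error, so each video's total contribution is
    its mean segment error regardless of how many windows survived.
    """
    c = np.asarray(c)
    if np.any(c < 1):
        raise ValueError("segment count c must be >= 1")
    out = (np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)) ** 2 / c
    return float(out) if out.ndim == 0 else out


def cross_entropy_loss(y: np.ndarray | float, p: np.ndarray | float,
                       clip: float = PROB_CLIP) -> np.ndarray | float:
    """Cross-entropy -(y log p + (1-y) log(1-p)), probabilities clipped away
    from {0, 1} for stability.

    For multiclass inputs (last axis = classes, ``y`` one-hot or a
    distribution) returns -sum_k y_k log p_k.
    """
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), clip, 1.0 - clip)
    if y.ndim and y.shape == p.shape and y.shape[-1] > 1:
        out = -np.sum(y * np.log(p), axis=-1)
    else:
        out = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(out) if np.ndim(out) == 0 else out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _stack(segments: list[Segment]) -> np.ndarray:
    return np.stack([s.data for s in segments]).astype(DTYPE)


def _eval_loss(model: Network, X: np.ndarray, y: np.ndarray, w: np.ndarray,
               task: str, batch: int = 256) -> float:
    total, n = 0.0, X.shape[0]
    for i in range(0, n, batch):
        out = model.forward(X[i:i + batch], training=False)
        if task == "regression":
            total += float(np.sum(w[i:i + batch] * (y[i:i + batch] - out[:, 0]) ** 2))
        else:
            p = _softmax(out)
            onehot = np.eye(p.shape[1])[y[i:i + batch].astype(int)]
            total += float(np.sum(w[i:i + batch] * cross_entropy_loss(onehot, p)))
    return total / n


def train(model: Network, train_set: SegmentSet, config: TrainConfig,
          val_set: SegmentSet | None = None, task: str = "regression",
          verbose: bool = False) -> dict:
    """Train ``model`` on a segment set with RMSProp and early stopping.

    ``train_set`` and ``val_set`` must come from disjoint patients (the
    caller splits at the patient level).  Early stopping watches the
    validation loss with the configured patience and restores the best
    weights.  Deterministic given ``config.seed``.  Returns a history dict
    with per-epoch train/validation losses and learning rates.
    """
    if task not in ("regression", "classification"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(config.seed)
    X = _stack(train_set.segments)
    y = train_set.y().astype(float)
    w = train_set.weights().astype(float)
    if val_set is not None and len(val_set):
        Xv, yv, wv = _stack(val_set.segments), val_set.y().astype(float), val_set.weights()
    else:
        Xv = None
    opt = RMSProp(rho=config.rho)
    n = X.shape[0]
    history: dict = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(config.max_epochs):
        lr = config.learning_rate(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            sel = order[i:i + config.batch_size]
            xb, yb, wb = X[sel], y[sel], w[sel]
            out = model.forward(xb, training=True, rng=rng)
            B = xb.shape[0]
            if task == "regression":
                resid = out[:, 0] - yb
                batch_loss = float(np.mean(wb * resid ** 2))
                grad = (2.0 * wb * resid / B)[:, None].astype(DTYPE)
            else:
                p = _softmax(out)
                onehot = np.eye(p.shape[1])[yb.astype(int)]
                batch_loss = float(np.mean(wb * cross_entropy_loss(onehot, p)))
                grad = (wb[:, None] * (p - onehot) / B).astype(DTYPE)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            model.backward(grad)
            opt.step(model, lr)
            epoch_loss += batch_loss * B
        history["train_loss"].append(epoch_loss / n + model.l2_loss())
        history["lr"].append(lr)
        if Xv is not None:
            val_loss = _eval_loss(model, Xv, yv, wv, task)
            history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} "
                      f"val {val_loss:.4f} lr {lr:.2e}")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = model.get_weights()
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.early_stopping_patience:
                    break
    if Xv is not None:
        model.set_weights(best_weights)
    return history


def predict_segments(model: Network, segments: list[Segment],
                     task: str = "regression", batch: int = 256) -> np.ndarray:
    """Per-segment model outputs in evaluation mode (no dropout, running BN)."""
    X = _stack(segments)
    outs = []
    for i in range(0, X.shape[0], batch):
        out = model.forward(X[i:i + batch], training=False)
        outs.append(out[:, 0] if task == "regression" else _softmax(out))
    return np.concatenate(outs)


def predict_video(model: Network, segments: list[Segment],
                  task: str = "regression") -> float | np.ndarray:
    """Video-level prediction: arithmetic mean over the video's segments.

    For classification the probability vectors are averaged (they still sum
    to one); take the argmax downstream for a hard label.
    """
    if not segments:
        raise ValueError("predict_video needs at least one segment")
    preds = predict_segments(model, segments, task=task)
    return float(preds.mean()) if task == "regression" else preds.mean(axis=0)


def fit_debias(train_predictions: np.ndarray,
               train_truths: np.ndarray) -> DebiasModel:
    """Ordinary least squares of truth on prediction (training set only)."""
    pred = np.asarray(train_predictions, dtype=float)
    truth = np.asarray(train_truths, dtype=float)
    if pred.size < 2:
        raise ValueError("need at least two training predictions")
    var = np.var(pred)
    if var <= 1e-15:
        warnings.warn("constant training predictions; debias falls back to the mean")
        return DebiasModel(slope=0.0, intercept=float(truth.mean()))
    slope = float(np.cov(pred, truth, bias=True)[0, 1] / var)
    intercept = float(truth.mean() - slope * pred.mean())
    return DebiasModel(slope=slope, intercept=intercept)


def apply_debias(model: DebiasModel, prediction: np.ndarray | float):
    """Apply the calibration a·prediction + b."""
    return model.slope * np.asarray(prediction, dtype=float) + model.intercept
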