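"""Model definitions: the 1-D CNN and the ridge / random-forest baselines.

The CNN maps a 124 × 12 window of normalized keypoint channels to a scalar
gait metric (regression head) or a class distribution (softmax head).  It
stacks ``n_blocks`` convolution blocks — each ``convs_per_block`` 1-D
convolutions (32 filters, length 8, same-padding) with ReLU then batch
normalization, closed by max-pooling and dropout — followed by flatten and a
single dense output layer.  An L2 penalty is applied to the weights of the
last four convolutional layers.

The baselines consume per-video summary statistics instead of raw time
series: five percentiles and the standard deviation of each of the 12
channels over the full trial (72 features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from videogait import nn
from videogait.preprocess import FeatureSeries

SUMMARY_PERCENTILES = (10, 25, 50, 75, 90)


@dataclass
class CNNConfig:
    """Architecture hyperparameters of the gait CNN.

    Defaults are the published winners of the original tuning: k = 3
    convolutions per block, 32 filters of length 8, pooling 2, dropout 0.5.
    ``l2_lambda`` = 3.16e-3 (10^-2.5 on a log-spaced grid) on the last four
    conv layers.  ``head`` is "regression" (one linear output) or
    "classification" (``n_classes`` softmax outputs).
    """

    input_shape: tuple[int, int] = (124, 12)
    convs_per_block: int = 3
    n_blocks: int = 2
    filters: int = 32
    filter_length: int = 8
    pool_size: int = 2
    dropout_rate: float = 0.5
    l2_lambda: float = 3.16e-3
    l2_last_n_convs: int = 4
    head: str = "regression"
    n_classes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head == "regression":
            self.n_classes = 1

    @property
    def flattened_width(self) -> int:
        """Temporal width after all pooling stages times the filter count."""
        w = self.input_shape[0]
        for _ in range(self.n_blocks):
            w //= self.pool_size
            if w < 1:
                raise ValueError("pooling collapses the temporal width below 1")
        return w * self.filters

    def param_count(self) -> int:
        """Analytic trainable-parameter count: (F·D + 1)·D2 per conv layer,
        2 per batch-norm channel, (in + 1)·out for the dense head."""
        total = 0
        depth = self.input_shape[1]
        for _ in range(self.n_blocks * self.convs_per_block):
            total += (self.filter_length * depth + 1) * self.filters
            total += 2 * self.filters
            depth = self.filters
        total += (self.flattened_width + 1) * self.n_classes
        return total


def build_cnn(config: CNNConfig) -> nn.Network:
    """Construct the network described by ``config``.

    The returned model reports its trainable-parameter count via
    ``n_params()``, which equals :meth:`CNNConfig.param_count` by design.
    """
    _ = config.flattened_width  # raises on temporal-width collapse
    rng = np.random.default_rng(config.seed)
    n_convs = config.n_blocks * config.convs_per_block
    layers: list[nn.Layer] = []
    depth = config.input_shape[1]
    conv_index = 0
    for _ in range(config.n_blocks):
        for _ in range(config.convs_per_block):
            l2 = (config.l2_lambda
                  if conv_index >= n_convs - config.l2_last_n_convs else 0.0)
            layers.append(nn.Conv1D(depth, config.filters, config.filter_length,
                                    l2=l2, rng=rng))
            layers.append(nn.ReLU())
            layers.append(nn.BatchNorm(config.filters))
            depth = config.filters
            conv_index += 1
        layers.append(nn.MaxPool1D(config.pool_size))
        layers.append(nn.Dropout(config.dropout_rate))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(config.flattened_width, config.n_classes, rng=rng))
    return nn.Network(layers)


def summary_features(feature: FeatureSeries | np.ndarray) -> np.ndarray:
    """Per-channel 10/25/50/75/90th percentiles and standard deviation.

    Returns a 72-vector in channel-major, statistic-minor order (channel 0's
    five percentiles then its sd, channel 1's, …).  Percentiles use the
    linear-interpolation convention.  Uses the full-length series, not
    windows.
    """
    data = feature.data if isinstance(feature, FeatureSeries) else np.asarray(feature)
    if data.ndim != 2:
        raise ValueError("expected a (T, channels) array")
    pcts = np.percentile(data, SUMMARY_PERCENTILES, axis=0)      # (5, C)
    sd = data.std(axis=0)
    return np.concatenate([pcts, sd[None, :]], axis=0).T.ravel()


def fit_ridge(features: np.ndarray, y: np.ndarray, alpha: float = 0.0):
    """Exact ridge regression: minimize sum((y - X b)^2) + alpha * sum(b_j^2).

    Features are standardized to zero mean and unit variance on the training
    set (the penalty needs comparable scales); the intercept is unpenalized.
    At alpha = 0 this is ordinary least squares; a singular system falls back
    to the minimum-norm solution (via pseudo-inverse) with a warning.
    Returns a predictor with ``coef_``, ``intercept_`` and ``predict``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    ymean = y.mean()
    A = Z.T @ Z + alpha * np.eye(Z.shape[1])
    b = Z.T @ (y - ymean)
    try:
        coef = np.linalg.solve(A, b)
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular ridge system; returning the minimum-norm solution")
        coef = np.linalg.pinv(A) @ b
    return _RidgeModel(coef=coef, mu=mu, sd=sd, intercept=ymean)


@dataclass
class _RidgeModel:
    coef: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    intercept: float

    @property
    def coef_(self) -> np.ndarray:
        return self.coef

    @property
    def intercept_(self) -> float:
        return self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mu) / self.sd
        return Z @ self.coef + self.intercept


def fit_random_forest(features: np.ndarray, y: np.ndarray, n_trees: int = 200,
                      max_depth: int = 10, seed: int = 0,
                      task: str = "regression"):
    """Random forest with the published hyperparameters (n = 200, d = 10).

    Prediction is the mean over trees (regression) or the mean class
    probability (classification); deterministic given ``seed``.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
    model = cls(n_estimators=n_trees, max_depth=max_depth, random_state=seed)
    model.fit(np.asarray(features), np.asarray(y))
    return model
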