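"""The two-block 1-D convolutional 4mC classifier and its training protocol.

Architecture: ``n_blocks`` repetitions of [Conv1D (ELU, L2 on weights and
biases) -> group normalization -> max pooling -> dropout], then flatten ->
dense (ELU, L2) -> dense(1, sigmoid). Defaults follow the reference
configuration: 2 blocks, 32 filters of width 5 (stride 1), 4 normalization
groups, pool size 4 / stride 2, dropout 0.25, 32 dense units, L2 1e-4.

Training: SGD with momentum 0.95 at learning rate 0.005 on binary
cross-entropy, batch size 32, at most 100 epochs, early stopping on
validation loss with patience 30, restoring the best-validation-epoch
weights (checkpointing).

The public surface is the scikit-learn style estimator
:class:`Conv4mCClassifier`; ``build_model``/``train``/``predict`` are thin
functional wrappers over the same internals.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .nn import Network, SGDMomentum

logger = logging.getLogger(__name__)


class ShapeError(ValueError):
    """The input length cannot pass through the convolution/pooling chain."""


@dataclass
class ArchitectureSpec:
    """Every architectural hyperparameter, with the reference defaults."""

    n_blocks: int = 2
    filters: int = 32
    kernel_size: int = 5
    conv_stride: int = 1
    groups: int = 4
    pool_size: int = 4
    pool_stride: int = 2
    dropout: float = 0.25
    dense_units: int = 32
    l2_weight: float = 1e-4

    def __post_init__(self):
        counts = dict(n_blocks=self.n_blocks, filters=self.filters,
                      kernel_size=self.kernel_size, conv_stride=self.conv_stride,
                      groups=self.groups, pool_size=self.pool_size,
                      pool_stride=self.pool_stride, dense_units=self.dense_units)
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.filters % self.groups:
            raise ValueError(
                f"filters ({self.filters}) must be divisible by "
                f"group-normalization groups ({self.groups})")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.l2_weight < 0:
            raise ValueError(f"l2_weight must be non-negative, got {self.l2_weight}")


@dataclass
class TrainConfig:
    """Optimization schedule (SGD + momentum on binary cross-entropy)."""

    learning_rate: float = 0.005
    momentum: float = 0.95
    epochs: int = 100
    batch_size: int = 32
    early_stopping_patience: int = 30
    checkpoint_best: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if not 0 < self.early_stopping_patience <= self.epochs:
            raise ValueError("early_stopping_patience must be in [1, epochs]")


@dataclass
class GridSpec:
    """Hyperparameter candidate lists for the exhaustive grid search."""

    conv_layers: Sequence[int] = (1, 2, 3, 4, 5)
    filters: Sequence[int] = (8, 12, 16, 22, 32, 42, 64, 128)
    kernel_size: Sequence[int] = (2, 3, 4, 5, 6, 7, 8, 10, 12, 14)
    pool_size: Sequence[int] = (2, 4)
    pool_stride: Sequence[int] = (2, 4)
    dropout: Sequence[float] = (0.2, 0.25, 0.3, 0.35, 0.4)

    def __post_init__(self):
        for name in ("conv_layers", "filters", "kernel_size",
                     "pool_size", "pool_stride", "dropout"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"candidate list {name!r} is empty")

    def n_combinations(self) -> int:
        return (len(self.conv_layers) * len(self.filters) * len(self.kernel_size)
                * len(self.pool_size) * len(self.pool_stride) * len(self.dropout))

    def combinations(self):
        """Yield dicts over the Cartesian product, outermost field first."""
        for nb, f, k, l, r, d in product(self.conv_layers, self.filters,
                                         self.kernel_size, self.pool_size,
                                         self.pool_stride, self.dropout):
            yield dict(n_blocks=nb, filters=f, kernel_size=k,
                       pool_size=l, pool_stride=r, dropout=d)


def build_network(arch: ArchitectureSpec, input_shape: tuple[int, int],
                  rng: np.random.Generator) -> Network:
    positions, channels = input_shape
    layers: list[nn.Layer] = []
    c_in = channels
    length = positions
    for _ in range(arch.n_blocks):
        if length < arch.kernel_size:
            raise ShapeError(
                f"input of {positions} positions shrinks to {length} before a "
                f"convolution of width {arch.kernel_size}; reduce n_blocks, "
                f"kernel_size or pool_stride")
        conv = nn.Conv1D(c_in, arch.filters, arch.kernel_size,
                         stride=arch.conv_stride, l2=arch.l2_weight, rng=rng)
        pool = nn.MaxPool1D(arch.pool_size, arch.pool_stride)
        layers += [conv, nn.ELU(), nn.GroupNorm(arch.filters, arch.groups),
                   pool, nn.Dropout(arch.dropout)]
        length = pool.out_length(conv.out_length(length))
        c_in = arch.filters
    layers += [nn.Flatten(),
               nn.Dense(length * c_in, arch.dense_units, l2=arch.l2_weight, rng=rng),
               nn.ELU(),
               nn.Dense(arch.dense_units, 1, rng=rng)]
    return Network(layers)


def build_model(arch: ArchitectureSpec | None = None,
                input_shape: tuple[int, int] = (41, 5),
                seed: int = 0) -> Network:
    """Construct an untrained network for ``input_shape`` = (positions, channels)."""
    arch = arch or ArchitectureSpec()
    return build_network(arch, input_shape, np.random.default_rng(seed))


def count_parameters(arch: ArchitectureSpec, input_shape: tuple[int, int]) -> int:
    """Trainable-parameter count as a pure function of spec + input shape."""
    return build_model(arch, input_shape).n_params()


def _fit_network(net: Network, X_tr, y_tr, X_val, y_val, cfg: TrainConfig,
                 rng: np.random.Generator) -> dict:
    opt = SGDMomentum(cfg.learning_rate, cfg.momentum)
    n = len(X_tr)
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    wait = 0
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            batch_losses.append(net.train_step(X_tr[idx], y_tr[idx], opt, rng))
        val_loss = net.loss(X_val, y_val)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            wait = 0
            if cfg.checkpoint_best:
                best_weights = net.get_weights()
        else:
            wait += 1
            if wait >= cfg.early_stopping_patience:
                break
    if cfg.checkpoint_best:
        net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return history


class Conv4mCClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style CNN classifier for encoded 41-nt windows.

    ``X`` is a float array of shape (n_samples, positions, channels) as
    produced by :func:`fourmc.encoders.encode_dataset`; ``y`` is binary
    (1 = 4mC). See the module docstring for the architecture and defaults.

    Parameters mirror :class:`ArchitectureSpec` and :class:`TrainConfig`.
    ``validation_fraction`` is used only when ``fit`` is not given an explicit
    validation set (as in the cross-validation protocol, where the validation
    fold is passed separately).
    """

    def __init__(self, n_blocks=2, filters=32, kernel_size=5, conv_stride=1,
                 groups=4, pool_size=4, pool_stride=2, dropout=0.25,
                 dense_units=32, l2_weight=1e-4, learning_rate=0.005,
                 momentum=0.95, epochs=100, batch_size=32,
                 early_stopping_patience=30, checkpoint_best=True,
                 validation_fraction=0.1, random_state=0):
        self.n_blocks = n_blocks
        self.filters = filters
        self.kernel_size = kernel_size
        self.conv_stride = conv_stride
        self.groups = groups
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.dropout = dropout
        self.dense_units = dense_units
        self.l2_weight = l2_weight
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stopping_patience = early_stopping_patience
        self.checkpoint_best = checkpoint_best
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- config assembly ------------------------------------------------
    def _arch(self) -> ArchitectureSpec:
        return ArchitectureSpec(
            n_blocks=self.n_blocks, filters=self.filters,
            kernel_size=self.kernel_size, conv_stride=self.conv_stride,
            groups=self.groups, pool_size=self.pool_size,
            pool_stride=self.pool_stride, dropout=self.dropout,
            dense_units=self.dense_units, l2_weight=self.l2_weight)

    def _cfg(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            epochs=self.epochs, batch_size=self.batch_size,
            early_stopping_patience=self.early_stopping_patience,
            checkpoint_best=self.checkpoint_best, seed=self.random_state)

    @staticmethod
    def _check_X(X, input_shape=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must be 3-D (n_samples, positions, channels), got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if input_shape is not None and X.shape[1:] != input_shape:
            raise ValueError(
                f"X has per-sample shape {X.shape[1:]}, model expects {input_shape}")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError(f"X and y disagree on n_samples: {len(X)} vs {len(y)}")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary (0/1)")
        cfg = self._cfg()
        rng = np.random.default_rng(cfg.seed)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            if len(tr_idx) == 0:
                raise ValueError("not enough samples to carve a validation split")
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = self._check_X(X_val, X.shape[1:])
            y_val = np.asarray(y_val, dtype=float).ravel()
        self.input_shape_ = X.shape[1:]
        self.network_ = build_network(self._arch(), self.input_shape_, rng)
        self.history_ = _fit_network(self.network_, X, y, X_val, y_val, cfg, rng)
        self.best_epoch_ = self.history_["best_epoch"]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = int(np.prod(self.input_shape_))
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("this Conv4mCClassifier instance is not fitted yet")

    def decision_function(self, X) -> np.ndarray:
        """Pre-sigmoid scores (logits)."""
        self._check_fitted()
        X = self._check_X(X, self.input_shape_)
        return self.network_.forward(X, train=False)

    def predict_proba(self, X) -> np.ndarray:
        p1 = nn.sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def input_gradient(self, X) -> np.ndarray:
        """Gradient of the logit with respect to the encoded input."""
        self._check_fitted()
        return self.network_.input_gradient(self._check_X(X, self.input_shape_))

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        """Serialize hyperparameters + learned weights to one .npz archive."""
        self._check_fitted()
        meta = dict(params=self.get_params(),
                    input_shape=[int(v) for v in self.input_shape_],
                    best_epoch=int(self.best_epoch_))
        weights = self.network_.get_weights()
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{f"w{i}": w for i, w in enumerate(weights)})

    @classmethod
    def load(cls, path) -> "Conv4mCClassifier":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["meta"]).decode())
            weights = [archive[f"w{i}"] for i in range(len(archive.files) - 1)]
        est = cls(**meta["params"])
        est.input_shape_ = tuple(meta["input_shape"])
        est.best_epoch_ = meta["best_epoch"]
        est.network_ = build_network(est._arch(), est.input_shape_,
                                     np.random.default_rng(0))
        est.network_.set_weights(weights)
        est.history_ = {"best_epoch": est.best_epoch_}
        est.classes_ = np.array([0, 1])
        est.n_features_in_ = int(np.prod(est.input_shape_))
        return est


def train(X_tr, y_tr, X_val, y_val, arch: ArchitectureSpec | None = None,
          cfg: TrainConfig | None = None) -> Conv4mCClassifier:
    """Functional wrapper: build and fit a classifier with an explicit
    validation set, returning the fitted estimator."""
    arch = arch or ArchitectureSpec()
    cfg = cfg or TrainConfig()
    est = Conv4mCClassifier(**asdict(arch),
                            learning_rate=cfg.learning_rate, momentum=cfg.momentum,
                            epochs=cfg.epochs, batch_size=cfg.batch_size,
                            early_stopping_patience=cfg.early_stopping_patience,
                            checkpoint_best=cfg.checkpoint_best,
                            random_state=cfg.seed)
    return est.fit(X_tr, y_tr, X_val=X_val, y_val=y_val)


def predict(model, X) -> np.ndarray:
    """Probability of the positive (4mC) class for each input record."""
    if isinstance(model, Network):
        return model.predict_proba(np.asarray(X, dtype=float))
    return model.predict_proba(X)[:, 1]


def grid_search(grid: GridSpec, ds, scheme: str, cfg: TrainConfig | None = None,
                selection_metric: str = "mcc", k: int = 10,
                base_arch: ArchitectureSpec | None = None,
                seed: int = 0) -> tuple[ArchitectureSpec, pd.DataFrame]:
    """Exhaustively evaluate the grid's Cartesian product by k-fold CV.

    Returns the best :class:`ArchitectureSpec` (argmax of the mean validation
    ``selection_metric``; ties broken by iteration order) and a results table
    with one row per evaluated combination. Combinations whose pooling chain
    shrinks the sequence below the convolution width are skipped and logged.
    """
    from .evaluate import cross_validate  # deferred: circular import

    cfg = cfg or TrainConfig()
    base = base_arch or ArchitectureSpec()
    rows = []
    best_score, best_arch = -np.inf, None
    for combo in grid.combinations():
        arch = ArchitectureSpec(**{**asdict(base), **combo})
        try:
            report = cross_validate(ds, scheme, arch=arch, cfg=cfg, k=k, seed=seed)
        except ShapeError as err:
            logger.warning("skipping combination %s: %s", combo, err)
            continue
        row = dict(combo)
        row.update(mcc=report.mcc, acc=report.acc, sn=report.sn,
                   sp=report.sp, auc=report.auc)
        rows.append(row)
        score = row[selection_metric]
        if score > best_score:
            best_score, best_arch = score, arch
    if best_arch is None:
        raise ValueError("no grid combination could be evaluated")
    return best_arch, pd.DataFrame(rows)
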