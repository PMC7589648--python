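"""The two window classifiers, as scikit-learn style estimators.

:class:`CNN3DClassifier` consumes raw normalized frame windows of shape
``(T, 24, 32)`` and learns spatio-temporal filters directly:

    conv3d(32 filters, 5x5x5) -> ReLU -> maxpool3d(3x3x3)
    -> dense(128) -> ReLU -> dropout(0.5) -> dense(8) -> softmax

:class:`LSTMClassifier` consumes the 6-feature time series (``T`` steps of
6 dimensions): a 128-unit LSTM followed by a dense layer to the 8 classes
and softmax.

Both train with softmax cross-entropy and Adam at learning rate 0.001 for
up to 100 epochs (all configurable); dropout is active only during
training, so inference is a pure function.  Probability vectors always
follow the canonical class order of :data:`thermofall.io.MOTION_LABELS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import LABEL_TO_INDEX, MOTION_LABELS, FrameWindow
from . import nn

N_CLASSES = len(MOTION_LABELS)


@dataclass
class TrainConfig:
    """Training hyperparameters shared by both classifiers."""

    learning_rate: float = 0.001
    max_epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"


def normalize_window(
    w: FrameWindow, clip_low_c: float = 0.0, clip_high_c: float = 5.0
) -> FrameWindow:
    """Map a °C-above-background window onto [0, 1] grayscale.

    Values are clipped to ``[clip_low_c, clip_high_c]`` (a human's
    above-background temperature spread stays within ~5 °C) and scaled
    linearly.  Re-normalizing an already normalized window is refused.
    """
    if w.units == "normalized":
        raise ValueError("window is already normalized")
    if clip_high_c <= clip_low_c:
        raise ValueError("clip_high_c must exceed clip_low_c")
    vals = np.clip(w.values, clip_low_c, clip_high_c)
    vals = (vals - clip_low_c) / (clip_high_c - clip_low_c)
    return FrameWindow(vals, label=w.label, units="normalized", subject_id=w.subject_id)


def _encode_labels(y) -> np.ndarray:
    idx = np.array([LABEL_TO_INDEX[str(lab)] for lab in y], dtype=np.int64)
    if np.unique(idx).size < 2:
        raise ValueError("training data must span at least two classes")
    return idx


class _NetClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing over a :class:`thermofall.nn.Sequential`."""

    def _build(self, rng: np.random.Generator) -> nn.Sequential:  # pragma: no cover
        raise NotImplementedError

    def _check_X(self, X: np.ndarray, fitted: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y):
        X = self._check_X(np.asarray(X, dtype=np.float32), fitted=False)
        y_idx = _encode_labels(y)
        rng = np.random.default_rng(self.seed)
        self.net_ = self._build(rng)
        self.loss_curve_ = nn.train_network(
            self.net_,
            X,
            y_idx,
            rng,
            lr=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
        )
        self.classes_ = np.array(MOTION_LABELS)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._check_X(np.asarray(X, dtype=np.float32), fitted=True)
        logits = self.net_.forward(X, train=False)
        return nn.softmax(logits)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # np.argmax takes the first maximum: ties break to the lowest
        # canonical class index
        return self.classes_[np.argmax(proba, axis=1)]

    def n_parameters(self) -> int:
        check_is_fitted(self, "net_")
        return self.net_.n_params()


class CNN3DClassifier(_NetClassifierBase):
    """3D convolutional classifier on raw ``(T, 24, 32)`` windows.

    Parameters follow the fixed architecture: 32 conv filters with a
    5x5x5 kernel (valid, stride 1), 3x3x3 max pooling (stride 3), a
    128-unit dense layer with ReLU and 50% dropout, and an 8-way softmax
    head.  ``window_shape`` fixes the expected input geometry at fit time.
    """

    def __init__(
        self,
        n_filters: int = 32,
        conv_kernel: int = 5,
        pool_kernel: int = 3,
        fc1: int = 128,
        dropout: float = 0.5,
        learning_rate: float = 0.001,
        max_epochs: int = 100,
        batch_size: int = 32,
        seed: int = 0,
        optimizer: str = "adam",
    ):
        self.n_filters = n_filters
        self.conv_kernel = conv_kernel
        self.pool_kernel = pool_kernel
        self.fc1 = fc1
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.seed = seed
        self.optimizer = optimizer

    def _check_X(self, X: np.ndarray, fitted: bool) -> np.ndarray:
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, T, rows, cols)")
        if X.shape[0] == 0:
            raise ValueError("empty dataset")
        if fitted and X.shape[1:] != self.window_shape_:
            raise ValueError(
                f"window shape {X.shape[1:]} != fitted shape {self.window_shape_}"
            )
        if not fitted:
            self.window_shape_ = X.shape[1:]
        return X

    def _flat_dim(self) -> int:
        T, H, W = self.window_shape_
        k, p = self.conv_kernel, self.pool_kernel
        co = (T - k + 1, H - k + 1, W - k + 1)
        po = tuple(c // p for c in co)
        if min(po) < 1:
            raise ValueError(f"window shape {self.window_shape_} too small for the architecture")
        return int(np.prod(po)) * self.n_filters

    def _build(self, rng: np.random.Generator) -> nn.Sequential:
        return nn.Sequential(
            [
                nn.Conv3D(rng, self.n_filters, self.conv_kernel, input_layer=True),
                nn.ReLU(),
                nn.MaxPool3D(self.pool_kernel),
                nn.Flatten(),
                nn.Dense(rng, self._flat_dim(), self.fc1),
                nn.ReLU(),
                nn.Dropout(rng, self.dropout),
                nn.Dense(rng, self.fc1, N_CLASSES),
            ]
        )


class LSTMClassifier(_NetClassifierBase):
    """LSTM classifier on ``(T, 6)`` feature-matrix sequences.

    Accepts either ``(n, T, 6)`` step-major sequences or ``(n, 6, T)``
    feature matrices (transposed automatically).  128 hidden units, dense
    8-way softmax head.
    """

    def __init__(
        self,
        hidden: int = 128,
        n_features: int = 6,
        learning_rate: float = 0.001,
        max_epochs: int = 100,
        batch_size: int = 32,
        seed: int = 0,
        optimizer: str = "adam",
        standardize: bool = True,
    ):
        self.hidden = hidden
        self.n_features = n_features
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.seed = seed
        self.optimizer = optimizer
        self.standardize = standardize

    def _check_X(self, X: np.ndarray, fitted: bool) -> np.ndarray:
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, T, n_features) or (n_samples, n_features, T)")
        if X.shape[2] != self.n_features:
            if X.shape[1] == self.n_features:
                X = X.transpose(0, 2, 1)  # feature-matrix layout -> step-major
            else:
                raise ValueError(
                    f"neither trailing nor middle axis has {self.n_features} features"
                )
        if X.shape[0] == 0:
            raise ValueError("empty dataset")
        if fitted:
            X = (X - self.feat_mean_) / self.feat_scale_
        else:
            # per-feature standardization: the six features live on very
            # different scales (px, px^2 counts, ratios, °C)
            if self.standardize:
                self.feat_mean_ = X.mean(axis=(0, 1), keepdims=True)
                self.feat_scale_ = X.std(axis=(0, 1), keepdims=True)
                self.feat_scale_[self.feat_scale_ < 1e-8] = 1.0
            else:
                self.feat_mean_ = np.zeros((1, 1, X.shape[2]), dtype=np.float32)
                self.feat_scale_ = np.ones((1, 1, X.shape[2]), dtype=np.float32)
            X = (X - self.feat_mean_) / self.feat_scale_
        return X.astype(np.float32)

    def _build(self, rng: np.random.Generator) -> nn.Sequential:
        return nn.Sequential(
            [
                nn.LSTM(rng, self.n_features, self.hidden),
                nn.Dense(rng, self.hidden, N_CLASSES),
            ]
        )
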