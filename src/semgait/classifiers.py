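"""Uniform classifier adapters over analysis windows.

Every adapter implements ``fit(windows, labels, val_windows=None,
val_labels=None)`` and ``predict(windows) -> labels``, so the evaluation
drivers can swap the CNN and the feature-based baselines freely.  Any
data-dependent state (image normalization scale, feature standardization,
SVM hyperparameters) is fitted on the training windows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baselines, cnn, semg_image
from .core import AnalysisWindow


class CNNClassifier:
    """sEMG-image CNN behind the common fit/predict interface."""

    def __init__(self, train_config: cnn.TrainConfig | None = None,
                 per_channel_scale: bool = True):
        self.train_config = train_config or cnn.TrainConfig()
        self.per_channel_scale = per_channel_scale
        self.scale: semg_image.NormalizationScale | None = None
        self.params: cnn.CNNParams | None = None
        self.loss_trace: np.ndarray | None = None

    def fit(self, windows, labels, val_windows=None, val_labels=None):
        self.scale = semg_image.fit_scale(list(windows), per_channel=self.per_channel_scale)
        x, _ = semg_image.images_from_windows(list(windows), self.scale)
        self.params, self.loss_trace = cnn.train(x, np.asarray(labels), self.train_config)
        return self

    def predict(self, windows) -> np.ndarray:
        x, _ = semg_image.images_from_windows(list(windows), self.scale)
        return cnn.predict(x, self.params)


class SVMClassifier:
    """iEMG/RMS features + RBF SVM with cross-validated grid search."""

    def __init__(self, cv_folds: int = 5,
                 c_grid=baselines.DEFAULT_C_GRID, gamma_grid=baselines.DEFAULT_GAMMA_GRID):
        self.cv_folds = cv_folds
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.model = None

    def fit(self, windows, labels, val_windows=None, val_labels=None):
        X = baselines.features_matrix(list(windows))
        self.model = baselines.train_svm(X, np.asarray(labels), self.cv_folds,
                                         self.c_grid, self.gamma_grid)
        return self

    def predict(self, windows) -> np.ndarray:
        X = baselines.features_matrix(list(windows))
        return np.asarray(self.model.predict(X), dtype=int)


class BPNNClassifier:
    """iEMG/RMS features + three-layer BPNN (20 hidden nodes)."""

    def __init__(self, hidden: int = 20, output_head: str = "onehot",
                 seed: int = 0, max_iter: int = 2000):
        self.hidden = hidden
        self.output_head = output_head
        self.seed = seed
        self.max_iter = max_iter
        self.model: baselines.BPNNModel | None = None
        self._scaler_mean = None
        self._scaler_sd = None

    def fit(self, windows, labels, val_windows=None, val_labels=None):
        X = baselines.features_matrix(list(windows))
        self._scaler_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._scaler_sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._scaler_mean) / self._scaler_sd
        self.model = baselines.train_bpnn(Xs, np.asarray(labels), self.hidden,
                                          self.output_head, self.seed, self.max_iter)
        return self

    def predict(self, windows) -> np.ndarray:
        X = baselines.features_matrix(list(windows))
        Xs = (X - self._scaler_mean) / self._scaler_sd
        return self.model.predict(Xs)


@dataclass
class ConstantClassifier:
    """Degenerate stub: always predicts one phase (for harness tests)."""

    phase: int = 0

    def fit(self, windows, labels, val_windows=None, val_labels=None):
        return self

    def predict(self, windows) -> np.ndarray:
        return np.full(len(list(windows)), self.phase, dtype=int)


class OracleClassifier:
    """Perfect stub: reads each window's true label (for harness tests)."""

    def fit(self, windows, labels, val_windows=None, val_labels=None):
        return self

    def predict(self, windows) -> np.ndarray:
        return np.array([w.label for w in windows], dtype=int)


def make_classifier(name: str, seed: int = 0,
                    cnn_iterations: int = 10_000) -> object:
    """Factory by name: 'cnn', 'svm' or 'bpnn'.

    The CNN uses the experiment-driver settings (cross-entropy loss, ψ = 5,
    phase-balanced mini-batches of 30, single precision) selected once on
    validation data; the library-level ``TrainConfig`` defaults stay at the
    architecture's canonical full-batch MSE configuration.
    """
    if name == "cnn":
        return CNNClassifier(cnn.TrainConfig(
            iterations=cnn_iterations, psi=5.0, loss="cross_entropy",
            batch_size=30, balanced_batches=True, dtype="float32", seed=seed,
        ))
    if name == "svm":
        return SVMClassifier()
    if name == "bpnn":
        return BPNNClassifier(seed=seed)
    raise ValueError(f"unknown classifier '{name}'")
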