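"""Hand-crafted feature pipeline (iEMG, RMS) with SVM-RBF and BPNN classifiers.

Per 30 ms window and channel two time-domain amplitude features are taken:

* iEMG = (1/N) Σ |V_k| — the mean absolute value (the 1/N factor is kept as
  defined here; the classical integrated-EMG definition omits it, which is
  scale-equivalent at fixed N = 60),
* RMS  = sqrt((1/N) Σ V_k²),

giving an 8-feature vector (RMS, iEMG per channel) per window.  The SVM uses
a Gaussian RBF kernel with (C, γ) chosen by cross-validated grid search; the
BPNN is a three-layer perceptron with 20 hidden nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import AnalysisWindow, ConfigurationError, N_CHANNELS, N_PHASES

DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)


def iemg(samples: np.ndarray) -> float:
    """Mean absolute value of one channel's window, µV."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ConfigurationError("iEMG of an empty window is undefined")
    return float(np.mean(np.abs(x)))


def rms(samples: np.ndarray) -> float:
    """Root-mean-square amplitude of one channel's window, µV."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ConfigurationError("RMS of an empty window is undefined")
    return float(np.sqrt(np.mean(x * x)))


def build_features(window: AnalysisWindow) -> np.ndarray:
    """The 8-feature vector [RMS_1, iEMG_1, …, RMS_4, iEMG_4] of a window."""
    out = np.empty(2 * N_CHANNELS)
    for ch in range(N_CHANNELS):
        out[2 * ch] = rms(window.samples[ch])
        out[2 * ch + 1] = iemg(window.samples[ch])
    return out


def features_matrix(windows: list[AnalysisWindow]) -> np.ndarray:
    return np.stack([build_features(w) for w in windows])


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
) -> GridSearchCV:
    """RBF-kernel SVM with (C, γ) grid search by k-fold cross-validation.

    Features are standardized inside the pipeline (fit on the training split
    only).  Multiclass decisions use the SVM's native one-vs-one scheme.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ConfigurationError("SVM training needs at least two classes")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", decision_function_shape="ovo")),
    ])
    folds = min(cv_folds, np.bincount(labels.astype(int)).min()) if labels.size else cv_folds
    grid = GridSearchCV(
        pipe,
        {"svc__C": list(c_grid), "svc__gamma": list(gamma_grid)},
        cv=max(2, folds),
        n_jobs=1,
    )
    grid.fit(np.asarray(features, dtype=float), labels)
    return grid


@dataclass
class BPNNModel:
    """Predict-contract wrapper over either BPNN output head."""

    estimator: object
    output_head: str

    def predict(self, features: np.ndarray) -> np.ndarray:
        raw = self.estimator.predict(np.asarray(features, dtype=float))
        if self.output_head == "ordinal":
            return np.clip(np.rint(raw), 0, N_PHASES - 1).astype(int)
        return np.asarray(raw, dtype=int)


def train_bpnn(
    features: np.ndarray,
    labels: np.ndarray,
    hidden: int = 20,
    output_head: str = "onehot",
    seed: int = 0,
    max_iter: int = 2000,
) -> BPNNModel:
    """Three-layer BPNN, 8 → ``hidden`` → output, trained by backpropagation.

    The default head has 5 one-hot output units with an argmax decision; the
    ``"ordinal"`` head is the literal single-output variant that regresses
    the phase index and rounds.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 * N_CHANNELS:
        raise ConfigurationError(f"features must be (n, {2 * N_CHANNELS})")
    if output_head == "onehot":
        est = MLPClassifier(
            hidden_layer_sizes=(hidden,), activation="logistic",
            random_state=seed, max_iter=max_iter,
        )
    elif output_head == "ordinal":
        est = MLPRegressor(
            hidden_layer_sizes=(hidden,), activation="logistic",
            random_state=seed, max_iter=max_iter,
        )
    else:
        raise ConfigurationError("output_head must be 'onehot' or 'ordinal'")
    est.fit(X, np.asarray(labels))
    return BPNNModel(estimator=est, output_head=output_head)
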