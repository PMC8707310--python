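"""The sEMG-image CNN: L1 input → C2 spatial conv → C3 temporal conv →
F4 → O5, with manual backpropagation and layer-wise learning rates.

Architecture (fixed by design):

* L1: the 4 × 60 greyscale image ``H`` (4 channels × 60 sample points).
* C2: 7 spatial filters, kernel 4 × 1 — each output sample ``r`` of map
  ``m`` is ``f(Σ_i H[i, r]·K2[m, i] + b2[m])``; 7 maps of 1 × 60.
* C3: 6 temporal filters, kernel 1 × 6, applied *non-overlapping* with
  stride 6 to every C2 map: ``f(Σ_i P2[(r−1)·6 + i]·K3[j, i] + b3[j])``;
  7 × 6 = 42 maps of 1 × 10.
* F4: fully connected, 420 → 110, sigmoid.
* O5: fully connected, 110 → 5 (one unit per gait phase), sigmoid.

C2/C3 use the scaled hyperbolic tangent ``f(u) = α tanh(β u)`` with
α = 1.7159, β = 2/3; F4/O5 use the logistic sigmoid.  Training is plain
(full-batch by default) gradient descent for a fixed iteration budget, with
per-layer rates σ = 2ψ/(N_sh·√N_in) for the shared-weight convolutional
layers and σ = ψ/√N_in for the fully connected ones, where N_sh is the
number of neurons sharing a weight and N_in the fan-in of a neuron.
Weights initialize uniformly on [−1/√N_in, +1/√N_in].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit as sigmoid

from .core import ConfigurationError, DivergenceError

ALPHA: float = 1.7159
BETA: float = 2.0 / 3.0

N_SPATIAL: int = 7       # C2 maps
N_TEMPORAL: int = 6      # C3 filters per C2 map
KERNEL_SPATIAL: int = 4  # C2 kernel height (channels)
KERNEL_TEMPORAL: int = 6 # C3 kernel width (stride, non-overlapping)
C2_LEN: int = 60
C3_LEN: int = C2_LEN // KERNEL_TEMPORAL  # 10
N_C3_MAPS: int = N_SPATIAL * N_TEMPORAL  # 42
N_FLAT: int = N_C3_MAPS * C3_LEN         # 420
N_F4: int = 110
N_OUT: int = 5

#: (N_sh, N_in) per trainable layer: neurons sharing each weight, and fan-in.
LAYER_FANS: dict[str, tuple[int, int]] = {
    "C2": (C2_LEN, KERNEL_SPATIAL),
    "C3": (C3_LEN, KERNEL_TEMPORAL),
    "F4": (1, N_FLAT),
    "O5": (1, N_F4),
}


def scaled_tanh(u: np.ndarray) -> np.ndarray:
    return ALPHA * np.tanh(BETA * u)


def _scaled_tanh_deriv_from_output(a: np.ndarray) -> np.ndarray:
    # f' = αβ(1 − tanh²) = β(α − f²/α)
    return BETA * (ALPHA - a * a / ALPHA)


@dataclass
class CNNParams:
    """All trainable weights and biases plus the activation constants."""

    K2: np.ndarray  # (7, 4) spatial kernels
    b2: np.ndarray  # (7,)
    K3: np.ndarray  # (6, 6) temporal kernels
    b3: np.ndarray  # (6,)
    W4: np.ndarray  # (420, 110)
    b4: np.ndarray  # (110,)
    W5: np.ndarray  # (110, 5)
    b5: np.ndarray  # (5,)
    alpha: float = ALPHA
    beta: float = BETA

    def __post_init__(self) -> None:
        shapes = {
            "K2": (N_SPATIAL, KERNEL_SPATIAL), "b2": (N_SPATIAL,),
            "K3": (N_TEMPORAL, KERNEL_TEMPORAL), "b3": (N_TEMPORAL,),
            "W4": (N_FLAT, N_F4), "b4": (N_F4,),
            "W5": (N_F4, N_OUT), "b5": (N_OUT,),
        }
        for name, shape in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ConfigurationError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    TENSORS = ("K2", "b2", "K3", "b3", "W4", "b4", "W5", "b5")

    def copy(self) -> "CNNParams":
        return CNNParams(*(getattr(self, t).copy() for t in self.TENSORS),
                         alpha=self.alpha, beta=self.beta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CNNParams):
            return NotImplemented
        return all(np.array_equal(getattr(self, t), getattr(other, t)) for t in self.TENSORS)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``psi`` is the global learning-rate constant ψ of the layer-wise rate
    formulas; the iteration budget counts full-batch updates by default
    (``batch_size`` switches to mini-batch updates, one update = one
    iteration).  ``literal_fan_in`` selects the 1/N_in (rather than 1/√N_in)
    reading of the initialization range.
    """

    iterations: int = 10_000
    psi: float = 0.1
    loss: str = "mse"  # or "cross_entropy"
    batch_size: int | None = None
    balanced_batches: bool = False  # phase-stratified mini-batch sampling
    seed: int = 0
    literal_fan_in: bool = False
    dtype: str = "float64"
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.psi < 0:
            raise ConfigurationError("psi must be non-negative")
        if self.loss not in ("mse", "cross_entropy"):
            raise ConfigurationError("loss must be 'mse' or 'cross_entropy'")
        if self.dtype not in ("float64", "float32"):
            raise ConfigurationError("dtype must be 'float64' or 'float32'")


@dataclass(frozen=True)
class LearningRates:
    conv2: float
    conv3: float
    fc4: float
    fc5: float


def layer_learning_rates(config: TrainConfig) -> LearningRates:
    """σ = 2ψ/(N_sh·√N_in) for C2/C3, σ = ψ/√N_in for F4/O5."""
    psi = config.psi
    rates = {}
    for layer, (n_sh, n_in) in LAYER_FANS.items():
        if layer in ("C2", "C3"):
            rates[layer] = 2.0 * psi / (n_sh * np.sqrt(n_in))
        else:
            rates[layer] = psi / np.sqrt(n_in)
    return LearningRates(rates["C2"], rates["C3"], rates["F4"], rates["O5"])


def init_params(seed: int, literal_fan_in: bool = False) -> CNNParams:
    """Draw every weight and bias uniformly from ±1/√N_in (or ±1/N_in)."""
    rng = np.random.default_rng(seed)

    def bound(n_in: int) -> float:
        return 1.0 / n_in if literal_fan_in else 1.0 / np.sqrt(n_in)

    def u(shape, n_in):
        b = bound(n_in)
        return rng.uniform(-b, b, size=shape)

    return CNNParams(
        K2=u((N_SPATIAL, KERNEL_SPATIAL), KERNEL_SPATIAL),
        b2=u((N_SPATIAL,), KERNEL_SPATIAL),
        K3=u((N_TEMPORAL, KERNEL_TEMPORAL), KERNEL_TEMPORAL),
        b3=u((N_TEMPORAL,), KERNEL_TEMPORAL),
        W4=u((N_FLAT, N_F4), N_FLAT),
        b4=u((N_F4,), N_FLAT),
        W5=u((N_F4, N_OUT), N_F4),
        b5=u((N_OUT,), N_F4),
    )


def _as_batch(images: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(images, dtype=float)
    if x.ndim == 2:
        return x[None], True
    if x.ndim != 3:
        raise ConfigurationError("images must be (4, 60) or (n, 4, 60)")
    return x, False


def conv_spatial(image: np.ndarray, params: CNNParams) -> np.ndarray:
    """C2: 7 spatial filters over the 4 channels → (7, 60) feature maps."""
    x, single = _as_batch(image)
    if x.shape[1:] != (KERNEL_SPATIAL, C2_LEN):
        raise ConfigurationError(f"expected (4, {C2_LEN}) image, got {x.shape[1:]}")
    z = np.einsum("bcr,mc->bmr", x, params.K2) + params.b2[None, :, None]
    a = scaled_tanh(z)
    return a[0] if single else a


def conv_temporal(maps: np.ndarray, params: CNNParams) -> np.ndarray:
    """C3: 6 temporal filters, stride-6 non-overlapping → (42, 10) maps.

    Output is indexed (input map m, temporal filter j) flattened to 42 maps.
    """
    a2 = np.asarray(maps, dtype=float)
    single = a2.ndim == 2
    if single:
        a2 = a2[None]
    if a2.shape[1] != N_SPATIAL or a2.shape[2] % KERNEL_TEMPORAL != 0:
        raise ConfigurationError(
            f"expected {N_SPATIAL} maps of length divisible by {KERNEL_TEMPORAL}"
        )
    n_out = a2.shape[2] // KERNEL_TEMPORAL
    a2r = a2.reshape(a2.shape[0], N_SPATIAL, n_out, KERNEL_TEMPORAL)
    z = np.einsum("bmri,ji->bmjr", a2r, params.K3) + params.b3[None, None, :, None]
    a = scaled_tanh(z).reshape(a2.shape[0], N_SPATIAL * N_TEMPORAL, n_out)
    return a[0] if single else a


def _forward_full(x: np.ndarray, params: CNNParams) -> dict[str, np.ndarray]:
    """Batched forward pass keeping every intermediate for backprop."""
    a2 = conv_spatial(x, params)                       # (B, 7, 60)
    a3 = conv_temporal(a2, params)                     # (B, 42, 10)
    a3f = a3.reshape(x.shape[0], N_FLAT)               # (B, 420)
    a4 = sigmoid(a3f @ params.W4 + params.b4)          # (B, 110)
    a5 = sigmoid(a4 @ params.W5 + params.b5)           # (B, 5)
    assert a2.shape[1:] == (N_SPATIAL, C2_LEN)
    assert a3.shape[1:] == (N_C3_MAPS, C3_LEN)
    assert a4.shape[1] == N_F4 and a5.shape[1] == N_OUT
    return {"x": x, "a2": a2, "a3": a3, "a3f": a3f, "a4": a4, "a5": a5}


def forward(image: np.ndarray, params: CNNParams) -> np.ndarray:
    """Phase scores in (0, 1) for one image (→ (5,)) or a batch (→ (n, 5))."""
    x, single = _as_batch(image)
    a5 = _forward_full(x, params)["a5"]
    return a5[0] if single else a5


def predict(images: np.ndarray, params: CNNParams) -> np.ndarray:
    """Predicted phase labels (argmax of the scores; ties → lower index)."""
    x, single = _as_batch(images)
    labels = forward(x, params).argmax(axis=1)
    return labels[0] if single else labels


def one_hot(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    y = np.zeros((labels.shape[0], N_OUT))
    y[np.arange(labels.shape[0]), labels] = 1.0
    return y


def loss_and_gradients(
    x: np.ndarray, y: np.ndarray, params: CNNParams, loss: str = "mse"
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients for a batch of images ``x`` and one-hot ``y``.

    MSE loss is ``0.5·mean_b Σ_k (a5 − y)²``; cross-entropy is the per-unit
    Bernoulli likelihood matching the sigmoid output head.
    """
    B = x.shape[0]
    f = _forward_full(x, params)
    a2, a3, a3f, a4, a5 = f["a2"], f["a3"], f["a3f"], f["a4"], f["a5"]

    if loss == "mse":
        value = 0.5 * np.mean(np.sum((a5 - y) ** 2, axis=1))
        d5 = (a5 - y) * a5 * (1.0 - a5) / B             # dL/dz5
    else:
        eps = 1e-12
        value = -np.mean(np.sum(y * np.log(a5 + eps) + (1 - y) * np.log(1 - a5 + eps), axis=1))
        d5 = (a5 - y) / B

    grads: dict[str, np.ndarray] = {}
    grads["W5"] = a4.T @ d5
    grads["b5"] = d5.sum(axis=0)

    d4 = (d5 @ params.W5.T) * a4 * (1.0 - a4)
    grads["W4"] = a3f.T @ d4
    grads["b4"] = d4.sum(axis=0)

    d3 = (d4 @ params.W4.T).reshape(B, N_SPATIAL, N_TEMPORAL, C3_LEN)
    d3 = d3 * _scaled_tanh_deriv_from_output(a3.reshape(B, N_SPATIAL, N_TEMPORAL, C3_LEN))
    a2r = a2.reshape(B, N_SPATIAL, C3_LEN, KERNEL_TEMPORAL)
    grads["K3"] = np.einsum("bmjr,bmri->ji", d3, a2r)
    grads["b3"] = d3.sum(axis=(0, 1, 3))

    da2 = np.einsum("bmjr,ji->bmri", d3, params.K3).reshape(B, N_SPATIAL, C2_LEN)
    d2 = da2 * _scaled_tanh_deriv_from_output(a2)
    grads["K2"] = np.einsum("bmr,bcr->mc", d2, f["x"])
    grads["b2"] = d2.sum(axis=(0, 2))

    return float(value), grads


_RATE_OF = {"K2": "conv2", "b2": "conv2", "K3": "conv3", "b3": "conv3",
            "W4": "fc4", "b4": "fc4", "W5": "fc5", "b5": "fc5"}


def train(
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    params: CNNParams | None = None,
) -> tuple[CNNParams, np.ndarray]:
    """Gradient-descent training; returns trained params and the loss trace.

    Deterministic given ``config.seed`` (initialization and, in mini-batch
    mode, the batch shuffling both derive from it).
    """
    config = config or TrainConfig()
    x, _ = _as_batch(images)
    if x.shape[0] < 1:
        raise ConfigurationError("need at least one labelled image")
    y = one_hot(labels)
    if y.shape[0] != x.shape[0]:
        raise ConfigurationError("labels must match images")

    params = params.copy() if params is not None else init_params(
        config.seed, config.literal_fan_in
    )
    dt = np.dtype(config.dtype)
    if dt != np.float64:
        x, y = x.astype(dt), y.astype(dt)
        for tensor in CNNParams.TENSORS:
            setattr(params, tensor, getattr(params, tensor).astype(dt))
    rates = layer_learning_rates(config)
    rng = np.random.default_rng(config.seed + 1)
    by_class = [np.flatnonzero(np.asarray(labels) == k) for k in range(N_OUT)]
    by_class = [b for b in by_class if b.size]

    trace = np.empty(config.iterations)
    n = x.shape[0]
    for it in range(config.iterations):
        if config.batch_size is None or config.batch_size >= n:
            xb, yb = x, y
        elif config.balanced_batches:
            per = max(1, config.batch_size // len(by_class))
            idx = np.concatenate(
                [rng.choice(b, per, replace=b.size < per) for b in by_class]
            )
            xb, yb = x[idx], y[idx]
        else:
            idx = rng.choice(n, size=config.batch_size, replace=False)
            xb, yb = x[idx], y[idx]
        value, grads = loss_and_gradients(xb, yb, params, config.loss)
        if not np.isfinite(value):
            raise DivergenceError(it)
        trace[it] = value
        for tensor, grad in grads.items():
            arr = getattr(params, tensor)
            arr -= float(getattr(rates, _RATE_OF[tensor])) * grad
    return params, trace


# ---------------------------------------------------------------------------
# Persistence: JSON header + CSV-style weight blocks (exact round-trip)


def save_params(params: CNNParams, path: str | Path, config: TrainConfig | None = None) -> Path:
    """Serialize params (and optionally the training config) as JSON text.

    Floats are stored via ``repr`` (hex-exact for IEEE doubles under json),
    so load → save round-trips bit-for-bit.
    """
    path = Path(path)
    blob = {
        "format": "semgait-cnn-1",
        "alpha": params.alpha,
        "beta": params.beta,
        "tensors": {t: getattr(params, t).tolist() for t in CNNParams.TENSORS},
    }
    if config is not None:
        blob["train_config"] = {
            "iterations": config.iterations, "psi": config.psi, "loss": config.loss,
            "batch_size": config.batch_size, "seed": config.seed,
            "literal_fan_in": config.literal_fan_in,
        }
    path.write_text(json.dumps(blob, sort_keys=True))
    return path


def load_params(path: str | Path) -> CNNParams:
    blob = json.loads(Path(path).read_text())
    if blob.get("format") != "semgait-cnn-1":
        raise ConfigurationError("unrecognized model file format")
    tensors = {t: np.asarray(blob["tensors"][t], dtype=float) for t in CNNParams.TENSORS}
    return CNNParams(**tensors, alpha=blob["alpha"], beta=blob["beta"])
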