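"""sEMG-image formation: 30 ms windows → 4 × 60 greyscale matrices.

Each analysis window is rearranged into a channels × samples image whose
pixels are affinely rescaled to [0, 1] with per-channel (min, max) bounds
fitted on the *training* windows only.  Test-set pixels may clip at 0/1 but
never leave the range; a degenerate channel (max = min) maps to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnalysisWindow, ConfigurationError, N_CHANNELS, NotFittedError


@dataclass
class SEMGImage:
    """A 4 × 60 greyscale image with its gait-phase label."""

    pixels: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (4, 60):
            raise ConfigurationError("sEMG image must be 4 x 60")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ConfigurationError("pixels must lie in [0, 1]")


@dataclass
class NormalizationScale:
    """Per-channel affine bounds mapping raw µV to greyscale [0, 1]."""

    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    per_channel: bool = True
    quantize_8bit: bool = False

    @property
    def fitted(self) -> bool:
        return self.lo is not None and self.hi is not None


def fit_scale(
    training_windows: list[AnalysisWindow],
    per_channel: bool = True,
    quantize_8bit: bool = False,
) -> NormalizationScale:
    """Fit (lo, hi) = per-channel (min, max) over the training windows.

    With ``per_channel=False`` a single global (min, max) is shared by all
    channels, preserving inter-channel amplitude ratios.
    """
    if not training_windows:
        raise ConfigurationError("need at least one training window to fit a scale")
    stack = np.stack([w.samples for w in training_windows])  # (n, 4, 60)
    if per_channel:
        lo = stack.min(axis=(0, 2))
        hi = stack.max(axis=(0, 2))
    else:
        lo = np.full(N_CHANNELS, stack.min())
        hi = np.full(N_CHANNELS, stack.max())
    return NormalizationScale(lo=lo, hi=hi, per_channel=per_channel,
                              quantize_8bit=quantize_8bit)


def to_image(window: AnalysisWindow, scale: NormalizationScale) -> SEMGImage:
    """Map one window to a greyscale image: pixel = (v − lo) / (hi − lo), clipped."""
    if not scale.fitted:
        raise NotFittedError("normalization scale has not been fitted")
    lo = scale.lo[:, None]
    hi = scale.hi[:, None]
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        pix = np.where(span > 0, (window.samples - lo) / np.where(span > 0, span, 1.0), 0.5)
    pix = np.clip(pix, 0.0, 1.0)
    if scale.quantize_8bit:
        pix = np.round(pix * 255.0) / 255.0
    return SEMGImage(pixels=pix, label=window.label)


def images_from_windows(
    windows: list[AnalysisWindow], scale: NormalizationScale
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, 4, 60) pixel and (n,) label arrays."""
    imgs = [to_image(w, scale) for w in windows]
    return np.stack([im.pixels for im in imgs]), np.array([im.label for im in imgs])
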