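"""Shared containers and constants for the gait-sEMG pipeline.

The study design is fixed: four thigh muscles recorded at 2000 Hz while a
subject walks at one of three treadmill speeds carrying a load (20% of body
weight) in one of three styles — backpack (BP), cross-shoulder single strap
(CS), or straight-shoulder single strap (SS).  Each gait cycle is subdivided
into five subphases delimited by heel-strike / toe-off events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLE_RATE_HZ: int = 2000

#: Recording montage, ipsilateral (right) thigh.  The tensor fasciae latae and
#: semitendinosus are stance-phase muscles; the adductor longus and vastus
#: medialis mainly shape the swing phase.
MUSCLES: tuple[str, ...] = (
    "tensor_fasciae_latae",
    "semitendinosus",
    "adductor_longus",
    "vastus_medialis",
)
N_CHANNELS: int = 4

PHASES: tuple[str, ...] = (
    "initial_stance",
    "midstance",
    "terminal_stance",
    "initial_swing",
    "terminal_swing",
)
N_PHASES: int = 5
UNLABELLED: int = -1

SPEEDS_KMH: tuple[int, ...] = (3, 5, 7)
LOAD_STYLES: tuple[str, ...] = ("BP", "CS", "SS")

#: Hardware saturation of the acquisition chain, µV.
MAX_AMPLITUDE_UV: float = 1600.0

WINDOW_MS: float = 30.0
OVERLAP_MS: float = 10.0


class ConfigurationError(ValueError):
    """Invalid pipeline or generator configuration."""


class InvalidAnnotationError(ValueError):
    """Gait-event annotations are non-monotone or overlapping."""


class TooShortSignalError(ValueError):
    """Signal too short for the requested filter."""


class NotFittedError(RuntimeError):
    """A data-dependent transform was used before being fitted."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite loss at iteration {iteration}")


@dataclass(frozen=True)
class TrialCondition:
    """One treadmill trial: speed, load style and load size."""

    speed_kmh: int
    load_style: str
    load_fraction: float = 0.20
    n_cycles: int = 50

    def __post_init__(self) -> None:
        if self.speed_kmh not in SPEEDS_KMH:
            raise ConfigurationError(f"speed must be one of {SPEEDS_KMH} km/h")
        if self.load_style not in LOAD_STYLES:
            raise ConfigurationError(f"load style must be one of {LOAD_STYLES}")
        if not 0.0 <= self.load_fraction <= 1.0:
            raise ConfigurationError("load_fraction must lie in [0, 1]")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be a positive integer")


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and per-muscle baseline sEMG amplitude of one subject."""

    subject_id: str
    body_weight_kg: float
    baseline_uv: np.ndarray  # shape (4,), µV at full activation
    subject_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline_uv", np.asarray(self.baseline_uv, dtype=float))
        if self.body_weight_kg <= 0:
            raise ConfigurationError("body weight must be positive")
        if self.baseline_uv.shape != (N_CHANNELS,) or np.any(self.baseline_uv <= 0):
            raise ConfigurationError("baseline amplitudes must be 4 positive values")


@dataclass(frozen=True)
class GaitEventTable:
    """Per-cycle subphase boundaries derived from heel-strike / toe-off events.

    ``boundaries`` has shape (n_cycles, 6): column 0 is the ipsilateral heel
    strike opening the cycle, column 3 the ipsilateral toe off (stance→swing),
    column 5 the heel strike closing the cycle.  Columns 1, 2 and 4 are the
    remaining subphase demarcations, so each row yields five contiguous,
    half-open subphase intervals ``[b_k, b_{k+1})`` in seconds.
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float).reshape(-1, 6)
        object.__setattr__(self, "boundaries", b)
        if b.size and (np.diff(b, axis=1) <= 0).any():
            raise InvalidAnnotationError("subphase boundaries must be strictly increasing")
        if b.shape[0] > 1 and (b[1:, 0] < b[:-1, 5] - 1e-12).any():
            raise InvalidAnnotationError("gait cycles must not overlap")

    @property
    def n_cycles(self) -> int:
        return self.boundaries.shape[0]

    @property
    def heel_strikes(self) -> np.ndarray:
        """Ipsilateral heel-strike times (cycle starts), seconds."""
        return self.boundaries[:, 0]

    @property
    def toe_offs(self) -> np.ndarray:
        """Ipsilateral toe-off times (stance→swing demarcation), seconds."""
        return self.boundaries[:, 3]

    @property
    def total_duration_s(self) -> float:
        return float(self.boundaries[-1, 5]) if self.n_cycles else 0.0

    def phase_intervals(self) -> np.ndarray:
        """All subphase intervals as an array of (start_s, end_s, phase)."""
        if not self.n_cycles:
            return np.empty((0, 3))
        starts = self.boundaries[:, :5].ravel()
        ends = self.boundaries[:, 1:].ravel()
        phases = np.tile(np.arange(N_PHASES, dtype=float), self.n_cycles)
        return np.column_stack([starts, ends, phases])


@dataclass
class GaitRecording:
    """One trial's 4-channel sEMG with its annotations and condition."""

    signal: np.ndarray  # (4, L), µV
    events: GaitEventTable
    condition: TrialCondition
    subject_id: str
    trial_id: str = ""
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != N_CHANNELS or self.signal.shape[1] < 1:
            raise ConfigurationError("signal must have shape (4, L) with L >= 1")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ConfigurationError(f"sample rate is fixed at {SAMPLE_RATE_HZ} Hz")
        if np.nanmax(np.abs(self.signal), initial=0.0) > MAX_AMPLITUDE_UV + 1e-9:
            raise ConfigurationError(f"|signal| must not exceed {MAX_AMPLITUDE_UV} µV")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class AnalysisWindow:
    """One 30 ms analysis window (4 channels × 60 samples) with its phase label."""

    samples: np.ndarray  # (4, 60), µV
    label: int
    trial_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = int(round(WINDOW_MS * SAMPLE_RATE_HZ / 1000.0))
        if self.samples.shape != (N_CHANNELS, expected):
            raise ConfigurationError(f"window must have shape (4, {expected})")
        if not 0 <= self.label < N_PHASES:
            raise ConfigurationError("label must be one of the 5 gait phases")

    @property
    def n_samples_total(self) -> int:
        return int(self.samples.size)
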