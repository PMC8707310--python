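"""Synthetic gait-sEMG generator.

Emulates the study design: 15 subjects walking on a treadmill at 3/5/7 km/h
under three load styles (backpack BP, cross-shoulder CS, straight-shoulder
SS), 50 gait cycles per trial, 9 trials per subject, 4-channel sEMG sampled
at 2000 Hz.

The signal model is the standard amplitude-modulated EMG model: a smooth,
phase-locked activation envelope multiplies a band-limited (20–400 Hz)
Gaussian carrier, plus additive baseline noise and 50 Hz line interference.
Load styles act on the envelope through three knobs — an amplitude scale, an
asymmetry factor on designated channels (unilateral loading), and a
variance-inflation factor on cycle-to-cycle gain variability.  With the
defaults, single-strap styles (CS worst, then SS) are noisier and more
asymmetric than the backpack, which is what degrades cross-style classifier
generalization downstream.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence``; identical seeds give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .core import (
    LOAD_STYLES,
    MAX_AMPLITUDE_UV,
    MUSCLES,
    N_CHANNELS,
    N_PHASES,
    SAMPLE_RATE_HZ,
    SPEEDS_KMH,
    ConfigurationError,
    GaitEventTable,
    GaitRecording,
    SubjectProfile,
    TrialCondition,
)

#: Fractional positions of the five subphase boundaries inside a gait cycle
#: (initial stance / midstance / terminal stance / initial swing / terminal
#: swing).  Stance ends at the 62% toe-off, per standard gait-phase timing.
DEFAULT_PHASE_FRACTIONS: tuple[float, ...] = (0.0, 0.12, 0.31, 0.62, 0.81, 1.0)

#: Mean gait-cycle duration (s) per treadmill speed (km/h).
DEFAULT_CYCLE_MEAN_S: dict[int, float] = {3: 1.30, 5: 1.05, 7: 0.85}

# Mean activation level in [0, 1] per (phase, muscle); columns follow MUSCLES.
# Stance muscles (TFL, ST) peak in a stance subphase, swing muscles (AL, VM)
# in a swing subphase.
DEFAULT_PHASE_ACTIVATION = np.array(
    [
        #  TFL    ST    AL    VM
        [0.90, 0.60, 0.10, 0.25],  # initial stance
        [0.55, 0.35, 0.05, 0.10],  # midstance
        [0.35, 0.80, 0.15, 0.10],  # terminal stance
        [0.10, 0.15, 0.85, 0.40],  # initial swing
        [0.15, 0.25, 0.30, 0.90],  # terminal swing
    ]
)


@dataclass(frozen=True)
class StyleEffect:
    """How one load style perturbs the activation envelope."""

    amplitude_scale: float = 1.0
    asymmetry: float = 1.0       # multiplies the designated (loaded-side) channels
    variance_inflation: float = 1.0  # scales cycle-to-cycle gain variance, >= 1

    def __post_init__(self) -> None:
        if self.variance_inflation < 1.0:
            raise ConfigurationError("variance inflation must be >= 1")


@dataclass(frozen=True)
class SpeedEffect:
    """How one treadmill speed sets cycle timing and overall drive."""

    cycle_mean_s: float
    jitter_frac: float = 0.03    # SD of cycle duration, as a fraction of the mean
    amplitude_scale: float = 1.0


def _default_style_effects() -> dict[str, StyleEffect]:
    # Backpack is the symmetric, most repeatable style; single-strap styles
    # drive the loaded-side muscles harder, are lateralized, and markedly
    # more variable (CS worst), so classifier separability orders BP > SS > CS
    # and cross-style generalization degrades.
    return {
        "BP": StyleEffect(1.00, 1.00, 1.0),
        "SS": StyleEffect(1.25, 1.30, 1.4),
        "CS": StyleEffect(1.50, 1.60, 2.0),
    }


def _default_speed_effects() -> dict[int, SpeedEffect]:
    return {
        3: SpeedEffect(DEFAULT_CYCLE_MEAN_S[3], 0.03, 0.85),
        5: SpeedEffect(DEFAULT_CYCLE_MEAN_S[5], 0.03, 1.00),
        7: SpeedEffect(DEFAULT_CYCLE_MEAN_S[7], 0.03, 1.20),
    }


@dataclass
class ActivationModel:
    """Phase-locked activation model with style and speed modifiers."""

    phase_activation: np.ndarray = field(
        default_factory=lambda: DEFAULT_PHASE_ACTIVATION.copy()
    )
    style_effects: dict[str, StyleEffect] = field(default_factory=_default_style_effects)
    speed_effects: dict[int, SpeedEffect] = field(default_factory=_default_speed_effects)
    phase_fractions: tuple[float, ...] = DEFAULT_PHASE_FRACTIONS
    boundary_jitter_frac: float = 0.01   # SD of interior boundary fractions
    cycle_gain_sd: float = 0.12          # baseline SD of per-cycle gain (× sqrt(inflation))
    transition_s: float = 0.03           # raised-cosine transition half-width; 0 disables

    def __post_init__(self) -> None:
        a = np.asarray(self.phase_activation, dtype=float)
        if a.shape != (N_PHASES, N_CHANNELS):
            raise ConfigurationError("phase_activation must be 5 phases x 4 muscles")
        if a.min() < 0.0 or a.max() > 1.0:
            raise ConfigurationError("phase activation levels must lie in [0, 1]")
        # Stance muscles peak in stance subphases, swing muscles in swing ones.
        peaks = a.argmax(axis=0)
        if not (peaks[0] <= 2 and peaks[1] <= 2 and peaks[2] >= 3 and peaks[3] >= 3):
            raise ConfigurationError(
                "stance muscles must peak in a stance subphase and "
                "swing muscles in a swing subphase"
            )
        vi = {s: self.style_effects[s].variance_inflation for s in self.style_effects}
        if not vi["CS"] >= vi["SS"] >= vi["BP"]:
            raise ConfigurationError("variance inflation must satisfy CS >= SS >= BP")
        self.phase_activation = a

    #: Channels multiplied by the style asymmetry factor (loaded-side hip
    #: abductor and hamstring).  The strap side is not identified in the
    #: montage, so this is a free parameter.
    asymmetric_channels: tuple[int, ...] = (0, 1)


@dataclass(frozen=True)
class NoiseConfig:
    """Carrier band and additive noise of the synthetic acquisition chain."""

    carrier_band_hz: tuple[float, float] = (20.0, 400.0)
    baseline_noise_uv: float = 3.0   # SD of additive wideband noise
    hum_amplitude_uv: float = 20.0   # 50 Hz line interference
    hum_freq_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.baseline_noise_uv < 0:
            raise ConfigurationError("baseline noise SD must be non-negative")
        if self.hum_amplitude_uv < 0:
            raise ConfigurationError("hum amplitude must be non-negative")


def generate_gait_events(
    condition: TrialCondition,
    seed: int,
    model: ActivationModel | None = None,
) -> GaitEventTable:
    """Draw gait cycles and subphase boundaries for one trial.

    Cycle durations are normal around the speed's mean with a small relative
    jitter; interior subphase boundaries sit at the configured fractional
    offsets, each perturbed and re-sorted so every cycle tiles into exactly
    five strictly increasing intervals.  Cycles are contiguous.
    """
    if condition.n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    model = model or ActivationModel()
    speed = model.speed_effects[condition.speed_kmh]
    rng = np.random.default_rng(seed)

    durations = speed.cycle_mean_s * (
        1.0 + speed.jitter_frac * rng.standard_normal(condition.n_cycles)
    )
    durations = np.clip(durations, 0.25 * speed.cycle_mean_s, None)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])

    base = np.asarray(model.phase_fractions)
    interior = np.tile(base[1:-1], (condition.n_cycles, 1))
    if model.boundary_jitter_frac > 0:
        interior = interior + model.boundary_jitter_frac * rng.standard_normal(interior.shape)
        interior = np.sort(np.clip(interior, 0.02, 0.98), axis=1)
    fracs = np.column_stack(
        [np.zeros(condition.n_cycles), interior, np.ones(condition.n_cycles)]
    )
    boundaries = starts[:, None] + fracs * durations[:, None]
    return GaitEventTable(boundaries)


def generate_envelope(
    events: GaitEventTable,
    model: ActivationModel,
    profile: SubjectProfile,
    condition: TrialCondition,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Build the per-channel activation envelope (µV) sampled at 2000 Hz.

    Within each subphase the envelope approaches
    ``phase_activation × style amplitude × speed amplitude × subject baseline``
    times a per-cycle multiplicative gain whose SD is inflated by the style's
    variance-inflation factor.  Boundaries are smoothed by a raised-cosine
    (Hann) kernel of width ``2 × transition_s``; ``transition_s = 0`` keeps
    the piecewise-constant (indicator) limit.
    """
    if events.n_cycles == 0:
        raise ConfigurationError("events table is empty")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng if rng is not None else profile.subject_seed)

    style = model.style_effects[condition.load_style]
    speed = model.speed_effects[condition.speed_kmh]

    n = int(np.ceil(events.total_duration_s * SAMPLE_RATE_HZ))
    env = np.zeros((N_CHANNELS, n))

    chan_scale = profile.baseline_uv * style.amplitude_scale * speed.amplitude_scale
    asym = np.ones(N_CHANNELS)
    asym[list(model.asymmetric_channels)] = style.asymmetry
    chan_scale = chan_scale * asym

    gain_sd = model.cycle_gain_sd * np.sqrt(style.variance_inflation)
    gains = 1.0 + gain_sd * rng.standard_normal((events.n_cycles, N_CHANNELS))
    gains = np.clip(gains, 0.0, None)

    b = events.boundaries
    for c in range(events.n_cycles):
        for p in range(N_PHASES):
            i0 = int(np.ceil(b[c, p] * SAMPLE_RATE_HZ))
            i1 = int(np.ceil(b[c, p + 1] * SAMPLE_RATE_HZ))
            i0, i1 = max(i0, 0), min(i1, n)
            if i1 <= i0:
                continue
            level = model.phase_activation[p] * chan_scale * gains[c]
            env[:, i0:i1] = level[:, None]

    if model.transition_s > 0:
        half = int(round(model.transition_s * SAMPLE_RATE_HZ))
        if half >= 1:
            kernel = np.hanning(2 * half + 1)
            kernel /= kernel.sum()
            for ch in range(N_CHANNELS):
                env[ch] = np.convolve(env[ch], kernel, mode="same")
    return np.clip(env, 0.0, None)


def _bandlimited_carrier(
    n: int, band: tuple[float, float], rng: np.random.Generator, channels: int
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz), per channel."""
    lo, hi = band
    nyq = SAMPLE_RATE_HZ / 2.0
    sos = sps.butter(4, [lo / nyq, min(hi / nyq, 0.999)], btype="bandpass", output="sos")
    white = rng.standard_normal((channels, n))
    carrier = sps.sosfiltfilt(sos, white, axis=1)
    sd = carrier.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return carrier / sd


def synthesize_semg(
    envelope: np.ndarray,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Modulate the envelope into a raw 4-channel sEMG trace (µV, 2000 Hz).

    signal = envelope × band-limited unit-variance Gaussian carrier
             + additive Gaussian baseline noise + 50 Hz hum,
    clipped to the ±1600 µV acquisition range.
    """
    noise_cfg = noise_cfg or NoiseConfig()
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    rng = np.random.default_rng(seed)
    n = env.shape[1]

    out = np.zeros_like(env)
    if env.any():
        carrier = _bandlimited_carrier(n, noise_cfg.carrier_band_hz, rng, env.shape[0])
        out = env * carrier
    if noise_cfg.baseline_noise_uv > 0:
        out = out + noise_cfg.baseline_noise_uv * rng.standard_normal(env.shape)
    if noise_cfg.hum_amplitude_uv > 0:
        t = np.arange(n) / SAMPLE_RATE_HZ
        phases = rng.uniform(0, 2 * np.pi, size=env.shape[0])
        out = out + noise_cfg.hum_amplitude_uv * np.sin(
            2 * np.pi * noise_cfg.hum_freq_hz * t[None, :] + phases[:, None]
        )
    return np.clip(out, -MAX_AMPLITUDE_UV, MAX_AMPLITUDE_UV)


# ---------------------------------------------------------------------------
# Study-level generation


@dataclass
class StudyConfig:
    """Full study design: who walks, how, and with what signal model."""

    n_subjects: int = 15
    n_cycles: int = 50
    speeds_kmh: tuple[int, ...] = SPEEDS_KMH
    load_styles: tuple[str, ...] = ("BP", "SS", "CS")  # trial order within a speed
    load_fraction: float = 0.20
    body_weight_mean_kg: float = 64.1
    body_weight_sd_kg: float = 4.2
    baseline_mean_uv: tuple[float, ...] = (300.0, 260.0, 240.0, 310.0)
    baseline_rel_sd: float = 0.10
    model: ActivationModel = field(default_factory=ActivationModel)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_cycles < 1:
            raise ConfigurationError("n_subjects and n_cycles must be positive")
        for s in self.speeds_kmh:
            if s not in SPEEDS_KMH:
                raise ConfigurationError(f"unknown speed {s}")
        for st in self.load_styles:
            if st not in LOAD_STYLES:
                raise ConfigurationError(f"unknown load style {st}")


def sample_profiles(cfg: StudyConfig, master_seed: int) -> list[SubjectProfile]:
    """Draw subject profiles from the population defaults.

    Subject seeds are spawned from ``SeedSequence(master_seed)`` in subject
    order, so each subject's trials are independently reproducible.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(cfg.n_subjects)
    profiles = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        weight = max(40.0, cfg.body_weight_mean_kg + cfg.body_weight_sd_kg * rng.standard_normal())
        base = np.asarray(cfg.baseline_mean_uv) * (
            1.0 + cfg.baseline_rel_sd * rng.standard_normal(N_CHANNELS)
        )
        base = np.clip(base, 20.0, None)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                body_weight_kg=weight,
                baseline_uv=base,
                subject_seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return profiles


def generate_recording(
    profile: SubjectProfile,
    condition: TrialCondition,
    model: ActivationModel,
    noise_cfg: NoiseConfig,
    seed: int,
    trial_id: str = "",
) -> GaitRecording:
    """Generate one labelled trial recording from a single trial seed."""
    ss = np.random.SeedSequence(seed)
    s_events, s_env, s_noise = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    events = generate_gait_events(condition, s_events, model)
    env = generate_envelope(events, model, profile, condition, rng=s_env)
    sig = synthesize_semg(env, noise_cfg, seed=s_noise)
    return GaitRecording(
        signal=sig,
        events=events,
        condition=condition,
        subject_id=profile.subject_id,
        trial_id=trial_id or f"{profile.subject_id}_V{condition.speed_kmh}_{condition.load_style}",
    )


@dataclass
class Dataset:
    """Generated trial recordings plus a manifest of the study design."""

    recordings: list[GaitRecording]
    manifest: list[dict]

    @property
    def n_trials(self) -> int:
        return len(self.manifest)

    @property
    def n_cycles_total(self) -> int:
        return int(sum(m["n_cycles"] for m in self.manifest))


def generate_dataset(
    cfg: StudyConfig,
    master_seed: int,
    events_only: bool = False,
    profiles: list[SubjectProfile] | None = None,
) -> Dataset:
    """Generate the full study: one recording per (subject, speed, style).

    Trials are ordered per subject as speed-major (V3, V5, V7) with styles in
    ``cfg.load_styles`` order, nine trials per subject at full design.  With
    ``events_only=True`` only gait events are drawn (signals skipped), which
    is enough to build the manifest of the full study design quickly.
    """
    profiles = profiles if profiles is not None else sample_profiles(cfg, master_seed)
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate subject ids in study")

    ss = np.random.SeedSequence((master_seed, 1))
    n_trials = len(profiles) * len(cfg.speeds_kmh) * len(cfg.load_styles)
    trial_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_trials)]

    recordings: list[GaitRecording] = []
    manifest: list[dict] = []
    k = 0
    for profile in profiles:
        trial_no = 0
        for speed in cfg.speeds_kmh:
            for style in cfg.load_styles:
                trial_no += 1
                cond = TrialCondition(
                    speed_kmh=speed,
                    load_style=style,
                    load_fraction=cfg.load_fraction,
                    n_cycles=cfg.n_cycles,
                )
                seed = trial_seeds[k]
                k += 1
                trial_id = f"{profile.subject_id}_V{speed}_{style}"
                entry = {
                    "trial_id": trial_id,
                    "subject_id": profile.subject_id,
                    "trial_no": trial_no,
                    "speed_kmh": speed,
                    "load_style": style,
                    "load_kg": round(cfg.load_fraction * profile.body_weight_kg, 3),
                    "n_cycles": cfg.n_cycles,
                    "seed": seed,
                    "sample_rate_hz": SAMPLE_RATE_HZ,
                }
                if events_only:
                    events = generate_gait_events(
                        cond, int(np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31)), cfg.model
                    )
                    entry["n_samples"] = int(np.ceil(events.total_duration_s * SAMPLE_RATE_HZ))
                else:
                    rec = generate_recording(profile, cond, cfg.model, cfg.noise, seed, trial_id)
                    recordings.append(rec)
                    entry["n_samples"] = rec.n_samples
                manifest.append(entry)
    return Dataset(recordings=recordings, manifest=manifest)


# ---------------------------------------------------------------------------
# CSV + JSON exchange format


def save_recording(rec: GaitRecording, out_dir: str | Path) -> Path:
    """Write one trial as ``<trial_id>.csv`` plus a ``<trial_id>.json`` sidecar.

    CSV columns: time_s, ch1..ch4 (µV), phase_label (0–4, -1 outside cycles).
    """
    from .preprocessing import label_phases  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = label_phases(rec)
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    table = np.column_stack([t, rec.signal.T, labels])
    csv_path = out_dir / f"{rec.trial_id}.csv"
    header = "time_s,ch1,ch2,ch3,ch4,phase_label"
    np.savetxt(csv_path, table, delimiter=",", header=header, comments="",
               fmt=["%.6f"] + ["%.4f"] * N_CHANNELS + ["%d"])
    sidecar = {
        "trial_id": rec.trial_id,
        "subject_id": rec.subject_id,
        "speed_kmh": rec.condition.speed_kmh,
        "load_style": rec.condition.load_style,
        "load_fraction": rec.condition.load_fraction,
        "n_cycles": rec.events.n_cycles,
        "sample_rate_hz": rec.sample_rate_hz,
        "event_boundaries_s": rec.events.boundaries.tolist(),
        "muscles": list(MUSCLES),
    }
    (out_dir / f"{rec.trial_id}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path


def load_recording(out_dir: str | Path, trial_id: str) -> GaitRecording:
    """Read a trial written by :func:`save_recording`."""
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{trial_id}.json").read_text())
    table = np.loadtxt(out_dir / f"{trial_id}.csv", delimiter=",", skiprows=1)
    cond = TrialCondition(
        speed_kmh=int(meta["speed_kmh"]),
        load_style=meta["load_style"],
        load_fraction=float(meta["load_fraction"]),
        n_cycles=int(meta["n_cycles"]),
    )
    return GaitRecording(
        signal=table[:, 1 : 1 + N_CHANNELS].T,
        events=GaitEventTable(np.asarray(meta["event_boundaries_s"])),
        condition=cond,
        subject_id=meta["subject_id"],
        trial_id=meta["trial_id"],
    )


def save_manifest(dataset: Dataset, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(dataset.manifest, indent=1, sort_keys=True))
    return path
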