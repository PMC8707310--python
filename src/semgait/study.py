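"""High-level drivers tying generation, preprocessing and evaluation together.

These helpers run the replication workflow at a configurable scale: generate
a synthetic study, filter and window every trial, group windows by load
style at one speed, and drive the per-condition / cross-style / mixed-style
experiments over a chosen classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classifiers, evaluation, preprocessing, synthetic_data
from .core import AnalysisWindow, LOAD_STYLES


@dataclass(frozen=True)
class ScalePreset:
    """A named problem size for the replication pipeline."""

    n_subjects: int
    n_cycles: int
    speeds_kmh: tuple[int, ...]
    cnn_iterations: int
    max_windows_per_style: int | None = None


SCALES: dict[str, ScalePreset] = {
    # desk-scale run: one speed, small pools, short CNN budget
    "tiny": ScalePreset(2, 10, (5,), 4000, 600),
    # moderate single-machine run
    "default": ScalePreset(5, 20, (3, 5, 7), 8000, 2000),
    # full study design
    "full": ScalePreset(15, 50, (3, 5, 7), 10_000, None),
}


def windows_for_trials(
    dataset: synthetic_data.Dataset,
) -> dict[str, list[AnalysisWindow]]:
    """Filter, label and window every recording; keyed by trial id."""
    out: dict[str, list[AnalysisWindow]] = {}
    for rec in dataset.recordings:
        filtered = preprocessing.bandpass_notch(rec)
        labels = preprocessing.label_phases(filtered)
        out[rec.trial_id] = preprocessing.segment_windows(filtered, labels)
    return out


def style_windows_at_speed(
    dataset: synthetic_data.Dataset,
    speed_kmh: int,
    max_per_style: int | None = None,
    seed: int = 0,
) -> dict[str, list[AnalysisWindow]]:
    """Pool every subject's windows per load style at one speed.

    ``max_per_style`` optionally subsamples each style's pool (phase-
    stratified via a seeded shuffle) to bound experiment cost.
    """
    by_trial = windows_for_trials(dataset)
    pools: dict[str, list[AnalysisWindow]] = {s: [] for s in LOAD_STYLES}
    for rec in dataset.recordings:
        if rec.condition.speed_kmh == speed_kmh:
            pools[rec.condition.load_style].extend(by_trial[rec.trial_id])
    pools = {s: w for s, w in pools.items() if w}
    if max_per_style is not None:
        rng = np.random.default_rng(seed)
        for s, ws in pools.items():
            if len(ws) > max_per_style:
                idx = np.sort(rng.choice(len(ws), size=max_per_style, replace=False))
                pools[s] = [ws[i] for i in idx]
    return pools


def run_style_experiments(
    study_cfg: synthetic_data.StudyConfig,
    speed_kmh: int,
    classifier_name: str,
    master_seed: int,
    cnn_iterations: int = 4000,
    max_per_style: int | None = 600,
) -> tuple[evaluation.CrossStyleMatrix, evaluation.MixedStyleTable]:
    """One seed's cross-style matrix and mixed-style table at one speed."""
    dataset = synthetic_data.generate_dataset(study_cfg, master_seed)
    pools = style_windows_at_speed(dataset, speed_kmh, max_per_style, master_seed)

    def factory():
        return classifiers.make_classifier(classifier_name, seed=master_seed,
                                           cnn_iterations=cnn_iterations)

    cross = evaluation.cross_style_experiment(factory, pools, seed=master_seed,
                                              speed_kmh=speed_kmh)
    mixed = evaluation.mixed_style_experiment(factory, pools, seed=master_seed,
                                              speed_kmh=speed_kmh)
    return cross, mixed


def tiny_study_config(n_subjects: int = 2, n_cycles: int = 10,
                      speeds: tuple[int, ...] = (5,)) -> synthetic_data.StudyConfig:
    """Desk-scale study: all three load styles at one speed."""
    return synthetic_data.StudyConfig(
        n_subjects=n_subjects, n_cycles=n_cycles, speeds_kmh=speeds
    )


#: Phase-activation table for the separability sanity check: each subphase
#: drives a distinct, non-proportional channel pattern (stance muscles still
#: peak in stance subphases, swing muscles in swing subphases).
SEPARABLE_PHASE_ACTIVATION = np.array(
    [
        [0.95, 0.10, 0.05, 0.05],
        [0.45, 0.45, 0.05, 0.05],
        [0.10, 0.95, 0.05, 0.05],
        [0.05, 0.05, 0.95, 0.10],
        [0.05, 0.05, 0.10, 0.95],
    ]
)


def separable_study_config(n_subjects: int = 2, n_cycles: int = 12) -> synthetic_data.StudyConfig:
    """A low-noise study whose phases are cleanly separable by construction:
    orthogonal per-phase channel patterns, small cycle-to-cycle gain noise,
    sharp subphase transitions, little additive noise."""
    model = synthetic_data.ActivationModel(
        phase_activation=SEPARABLE_PHASE_ACTIVATION.copy(),
        cycle_gain_sd=0.04,
        transition_s=0.01,
    )
    noise = synthetic_data.NoiseConfig(baseline_noise_uv=1.0, hum_amplitude_uv=5.0)
    return synthetic_data.StudyConfig(
        n_subjects=n_subjects, n_cycles=n_cycles, speeds_kmh=(5,),
        model=model, noise=noise,
    )


def pure_phase_windows(dataset: synthetic_data.Dataset,
                       load_style: str = "BP") -> list[AnalysisWindow]:
    """Windows whose 60 samples all carry the same subphase label.

    Used by the separability sanity check to exclude windows that straddle a
    subphase boundary (whose majority label is intrinsically ambiguous).
    """
    out: list[AnalysisWindow] = []
    for rec in dataset.recordings:
        if rec.condition.load_style != load_style:
            continue
        filtered = preprocessing.bandpass_notch(rec)
        labels = preprocessing.label_phases(filtered)
        for w in preprocessing.segment_windows(filtered, labels):
            seg = labels[w.start_index : w.start_index + w.samples.shape[1]]
            if np.all(seg == seg[0]):
                out.append(w)
    return out
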