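import numpy as np
import pytest

from semgait import preprocessing, study, synthetic_data
from semgait.core import GaitEventTable, GaitRecording, SubjectProfile, TrialCondition


@pytest.fixture(scope="session")
def profile() -> SubjectProfile:
    return SubjectProfile(
        subject_id="S01",
        body_weight_kg=64.1,
        baseline_uv=np.array([300.0, 260.0, 240.0, 310.0]),
        subject_seed=7,
    )


@pytest.fixture(scope="session")
def condition() -> TrialCondition:
    return TrialCondition(speed_kmh=5, load_style="BP", n_cycles=5)


@pytest.fixture(scope="session")
def tiny_recording(profile, condition) -> GaitRecording:
    """One small generated trial (5 cycles at V5, backpack)."""
    model = synthetic_data.ActivationModel()
    return synthetic_data.generate_recording(
        profile, condition, model, synthetic_data.NoiseConfig(), seed=11
    )


@pytest.fixture(scope="session")
def tiny_windows(tiny_recording):
    filtered = preprocessing.bandpass_notch(tiny_recording)
    labels = preprocessing.label_phases(filtered)
    return preprocessing.segment_windows(filtered, labels)


def uniform_label_recording(n_samples: int, label_phase_bounds=None) -> GaitRecording:
    """Recording with a single gait cycle covering the whole signal."""
    dur = n_samples / 2000.0
    bounds = label_phase_bounds or [0.0, 0.2 * dur, 0.4 * dur, 0.6 * dur, 0.8 * dur, dur + 1e-9]
    rng = np.random.default_rng(0)
    return GaitRecording(
        signal=rng.normal(0, 50, size=(4, n_samples)),
        events=GaitEventTable(np.asarray(bounds)),
        condition=TrialCondition(speed_kmh=5, load_style="BP", n_cycles=1),
        subject_id="S00",
        trial_id="T0",
    )
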