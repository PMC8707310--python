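"""Filtering, gait-phase labelling, and overlapped windowing.

The acquisition chain band-passes sEMG to 10–400 Hz and notches out 50 Hz
line interference; here that is reproduced digitally as a zero-phase 4th
order Butterworth bandpass followed by an IIR notch.  Labelled signal is
then cut into 30 ms analysis windows overlapped by 10 ms (step 20 ms =
40 samples at 2000 Hz), 60 samples per channel per window.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .core import (
    N_PHASES,
    OVERLAP_MS,
    SAMPLE_RATE_HZ,
    UNLABELLED,
    WINDOW_MS,
    AnalysisWindow,
    ConfigurationError,
    GaitRecording,
    InvalidAnnotationError,
    TooShortSignalError,
)

BANDPASS_HZ: tuple[float, float] = (10.0, 400.0)
NOTCH_HZ: float = 50.0
NOTCH_Q: float = 30.0
FILTER_ORDER: int = 4


def filter_signal(
    x: np.ndarray,
    band_hz: tuple[float, float] = BANDPASS_HZ,
    notch_hz: float = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass + 50 Hz notch, per channel.

    Forward-backward filtering keeps the output aligned with the gait-event
    annotations (no group delay).  Output length equals input length.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nyq = SAMPLE_RATE_HZ / 2.0
    sos = sps.butter(order, [band_hz[0] / nyq, min(band_hz[1] / nyq, 0.999)],
                     btype="bandpass", output="sos")
    b_n, a_n = sps.iirnotch(notch_hz, notch_q, fs=SAMPLE_RATE_HZ)
    padlen = max(3 * (2 * sos.shape[0] + 1), 3 * max(len(b_n), len(a_n)))
    if x.shape[1] <= padlen:
        raise TooShortSignalError(
            f"signal length {x.shape[1]} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    y = sps.sosfiltfilt(sos, x, axis=1)
    y = sps.filtfilt(b_n, a_n, y, axis=1)
    return y


def bandpass_notch(recording: GaitRecording, **kwargs) -> GaitRecording:
    """Return a filtered copy of ``recording`` (10–400 Hz bandpass + 50 Hz notch)."""
    filtered = filter_signal(recording.signal, **kwargs)
    # the zero-phase cascade cannot exceed the input range by much; clip to
    # keep the container invariant
    filtered = np.clip(filtered, -1600.0, 1600.0)
    return dataclasses.replace(recording, signal=filtered)


def label_phases(recording: GaitRecording) -> np.ndarray:
    """Per-sample gait-phase labels 0–4; samples outside any cycle get -1.

    Sample ``n`` (time ``n / fs``) takes the label of the half-open subphase
    interval ``[start, end)`` containing it, so a sample exactly on a
    boundary belongs to the later interval.
    """
    events = recording.events
    labels = np.full(recording.n_samples, UNLABELLED, dtype=int)
    if events.n_cycles == 0:
        return labels
    b = events.boundaries  # validated strictly increasing / non-overlapping
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    for c in range(events.n_cycles):
        idx = np.searchsorted(b[c], t, side="right") - 1
        inside = (idx >= 0) & (idx < N_PHASES)
        labels[inside] = idx[inside]
    return labels


def window_count(segment_length: int, window: int = 60, step: int = 40) -> int:
    """Number of windows in a contiguous labelled segment of given length."""
    if segment_length < window:
        return 0
    return (segment_length - window) // step + 1


def segment_windows(
    recording: GaitRecording,
    labels: np.ndarray,
    window_ms: float = WINDOW_MS,
    overlap_ms: float = OVERLAP_MS,
) -> list[AnalysisWindow]:
    """Cut overlapped analysis windows from the labelled signal.

    Windows start every ``window_ms − overlap_ms`` (default 20 ms = 40
    samples) within each contiguous labelled segment; a window spanning a
    subphase boundary takes the majority per-sample label, ties broken
    toward the earlier phase.  Windows touching unlabelled samples are
    dropped (equivalently: windowing restarts at each labelled segment).
    """
    if not 0 <= overlap_ms < window_ms:
        raise ConfigurationError("require window_ms > overlap_ms >= 0")
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != recording.n_samples:
        raise ConfigurationError("labels length must match the recording")

    fs = recording.sample_rate_hz
    win = int(round(window_ms * fs / 1000.0))
    step = int(round((window_ms - overlap_ms) * fs / 1000.0))

    windows: list[AnalysisWindow] = []
    labelled = labels != UNLABELLED
    # contiguous labelled segments
    edges = np.flatnonzero(np.diff(np.concatenate([[0], labelled.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        for start in range(s, e - win + 1, step):
            seg = labels[start : start + win]
            counts = np.bincount(seg, minlength=N_PHASES)
            windows.append(
                AnalysisWindow(
                    samples=recording.signal[:, start : start + win],
                    label=int(counts.argmax()),
                    trial_id=recording.trial_id,
                    start_index=start,
                )
            )
    return windows
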