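"""Generator contracts: timing structure, envelope semantics, signal model."""

import numpy as np
import pytest
from scipy import signal as sps

from semgait import preprocessing, synthetic_data as sd
from semgait.core import ConfigurationError, SAMPLE_RATE_HZ, TrialCondition


class TestGaitEvents:
    def test_zero_jitter_yields_exact_configured_timing(self):
        model = sd.ActivationModel(boundary_jitter_frac=0.0)
        model.speed_effects[5] = sd.SpeedEffect(1.05, jitter_frac=0.0)
        cond = TrialCondition(speed_kmh=5, load_style="BP", n_cycles=1)
        events = sd.generate_gait_events(cond, seed=0, model=model)
        assert events.n_cycles == 1
        np.testing.assert_allclose(
            events.boundaries[0], 1.05 * np.asarray(sd.DEFAULT_PHASE_FRACTIONS)
        )

    def test_default_config_boundaries_strictly_increasing(self):
        cond = TrialCondition(speed_kmh=3, load_style="CS", n_cycles=50)
        events = sd.generate_gait_events(cond, seed=3)
        assert events.n_cycles == 50
        # brute-force monotonicity scan over every boundary in time order
        flat = events.boundaries.reshape(-1)
        seq = [flat[0]]
        for c in range(50):
            for k in range(1, 6):
                assert events.boundaries[c, k] > events.boundaries[c, k - 1]
        assert events.phase_intervals().shape[0] == 250

    def test_cycles_tile_contiguously(self):
        cond = TrialCondition(speed_kmh=7, load_style="SS", n_cycles=20)
        events = sd.generate_gait_events(cond, seed=1)
        np.testing.assert_allclose(events.boundaries[1:, 0], events.boundaries[:-1, 5])

    def test_rejects_nonpositive_cycle_count(self):
        with pytest.raises(ConfigurationError):
            TrialCondition(speed_kmh=5, load_style="BP", n_cycles=0)

    def test_same_seed_reproduces_events(self):
        cond = TrialCondition(speed_kmh=5, load_style="BP", n_cycles=10)
        a = sd.generate_gait_events(cond, seed=42)
        b = sd.generate_gait_events(cond, seed=42)
        np.testing.assert_array_equal(a.boundaries, b.boundaries)


class TestEnvelope:
    def test_zero_activation_gives_zero_envelope(self, profile, condition):
        model = sd.ActivationModel()
        model.phase_activation = np.zeros((5, 4))
        events = sd.generate_gait_events(condition, seed=0, model=model)
        env = sd.generate_envelope(events, model, profile, condition, rng=0)
        assert not env.any()

    def test_indicator_limit_single_phase_single_muscle(self, profile):
        # one muscle active only in midstance, transitions disabled, no gain noise
        act = np.zeros((5, 4))
        act[1, 0] = 1.0   # TFL peaks in midstance (a stance subphase)
        act[3, 2] = 0.0
        # keep the swing muscles' (zero) peaks formally in swing via tiny values
        act[3, 2] = 1e-6
        act[3, 3] = 1e-6
        act[4, 1] = 0.0
        act[2, 1] = 1e-6
        model = sd.ActivationModel(
            phase_activation=act, transition_s=0.0, cycle_gain_sd=0.0,
            boundary_jitter_frac=0.0,
        )
        model.speed_effects[5] = sd.SpeedEffect(1.0, jitter_frac=0.0, amplitude_scale=1.0)
        cond = TrialCondition(speed_kmh=5, load_style="BP", n_cycles=1)
        events = sd.generate_gait_events(cond, seed=0, model=model)
        env = sd.generate_envelope(events, model, profile, cond, rng=0)
        t = np.arange(env.shape[1]) / SAMPLE_RATE_HZ
        inside = (t >= events.boundaries[0, 1]) & (t < events.boundaries[0, 2])
        np.testing.assert_allclose(env[0, inside], profile.baseline_uv[0])
        assert np.all(env[0, ~inside] == 0)

    def test_variance_inflation_ordering_cs_over_bp(self, profile):
        # cycle-peak variance ratio across many cycles tracks the configured
        # variance-inflation ratio (amplitude scaling only increases it)
        model = sd.ActivationModel(transition_s=0.0, boundary_jitter_frac=0.0)
        peaks = {}
        for style in ("BP", "CS"):
            cond = TrialCondition(speed_kmh=5, load_style=style, n_cycles=200)
            events = sd.generate_gait_events(cond, seed=5, model=model)
            env = sd.generate_envelope(events, model, profile, cond, rng=9)
            # per-cycle mean level of channel 0 during initial stance
            vals = []
            for c in range(events.n_cycles):
                i0 = int(np.ceil(events.boundaries[c, 0] * SAMPLE_RATE_HZ))
                i1 = int(np.ceil(events.boundaries[c, 1] * SAMPLE_RATE_HZ))
                vals.append(env[0, i0:i1].mean())
            # normalize away the amplitude scale to isolate variability
            vals = np.asarray(vals)
            peaks[style] = np.var(vals / vals.mean())
        configured = (
            model.style_effects["CS"].variance_inflation
            / model.style_effects["BP"].variance_inflation
        )
        assert peaks["CS"] / peaks["BP"] >= 0.9 * configured

    def test_asymmetry_scales_designated_channels_only(self, profile):
        model = sd.ActivationModel(transition_s=0.0, cycle_gain_sd=0.0,
                                   boundary_jitter_frac=0.0)
        envs = {}
        for style in ("BP", "CS"):
            cond = TrialCondition(speed_kmh=5, load_style=style, n_cycles=2)
            events = sd.generate_gait_events(cond, seed=2, model=model)
            envs[style] = sd.generate_envelope(events, model, profile, cond, rng=3)
        eff = model.style_effects["CS"]
        ratio = envs["CS"].max(axis=1) / envs["BP"].max(axis=1)
        np.testing.assert_allclose(ratio[:2], eff.amplitude_scale * eff.asymmetry, rtol=1e-9)
        np.testing.assert_allclose(ratio[2:], eff.amplitude_scale, rtol=1e-9)


class TestSynthesize:
    def test_zero_everything_gives_zero_signal(self):
        env = np.zeros((4, 2000))
        cfg = sd.NoiseConfig(baseline_noise_uv=0.0, hum_amplitude_uv=0.0)
        out = sd.synthesize_semg(env, cfg, seed=0)
        assert not out.any()

    def test_constant_envelope_sets_signal_rms(self):
        # law of large numbers: RMS of envelope x unit-variance carrier -> envelope
        env = np.full((4, 20 * SAMPLE_RATE_HZ), 100.0)
        cfg = sd.NoiseConfig(baseline_noise_uv=0.0, hum_amplitude_uv=0.0)
        out = sd.synthesize_semg(env, cfg, seed=1)
        rms = np.sqrt(np.mean(out**2, axis=1))
        np.testing.assert_allclose(rms, 100.0, rtol=0.05)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.NoiseConfig(baseline_noise_uv=-1.0)

    def test_carrier_power_concentrated_in_band(self):
        env = np.full((4, 20 * SAMPLE_RATE_HZ), 100.0)
        cfg = sd.NoiseConfig(baseline_noise_uv=0.0, hum_amplitude_uv=0.0)
        out = sd.synthesize_semg(env, cfg, seed=2)
        f, pxx = sps.periodogram(out[0], fs=SAMPLE_RATE_HZ)
        in_band = (f >= 20) & (f <= 400)
        assert pxx[~in_band].sum() < 0.05 * pxx.sum()

    def test_hum_peak_removed_by_bandpass_notch(self, profile, condition):
        model = sd.ActivationModel()
        events = sd.generate_gait_events(condition, seed=0, model=model)
        env = sd.generate_envelope(events, model, profile, condition, rng=1)
        cfg = sd.NoiseConfig(hum_amplitude_uv=50.0)
        raw = sd.synthesize_semg(env, cfg, seed=3)
        f, p_raw = sps.periodogram(raw[0], fs=SAMPLE_RATE_HZ)
        k50 = np.argmin(np.abs(f - 50.0))
        assert p_raw[k50] == p_raw[(f > 40) & (f < 60)].max()  # dominant line at 50 Hz
        filt = preprocessing.filter_signal(raw)
        _, p_filt = sps.periodogram(filt[0], fs=SAMPLE_RATE_HZ)
        assert 10 * np.log10(p_raw[k50] / p_filt[k50]) >= 20.0


class TestDataset:
    def test_minimal_study_counts(self):
        cfg = sd.StudyConfig(n_subjects=1, n_cycles=2, speeds_kmh=(5,), load_styles=("BP",))
        ds = sd.generate_dataset(cfg, master_seed=0)
        assert ds.n_trials == 1 and len(ds.recordings) == 1
        rec = ds.recordings[0]
        assert rec.events.n_cycles == 2
        assert rec.events.phase_intervals().shape[0] == 10

    def test_full_scale_manifest_counts(self):
        cfg = sd.StudyConfig(n_subjects=15, n_cycles=50)
        ds = sd.generate_dataset(cfg, master_seed=0, events_only=True)
        assert ds.n_trials == 15 * 9 == 135
        assert ds.n_cycles_total == 6750
        per_subject = {}
        for m in ds.manifest:
            per_subject.setdefault(m["subject_id"], []).append(m["trial_no"])
        assert all(sorted(v) == list(range(1, 10)) for v in per_subject.values())

    def test_same_master_seed_is_bit_identical(self):
        cfg = sd.StudyConfig(n_subjects=1, n_cycles=2, speeds_kmh=(5,))
        a = sd.generate_dataset(cfg, master_seed=9)
        b = sd.generate_dataset(cfg, master_seed=9)
        assert a.manifest == b.manifest
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.signal, rb.signal)
            np.testing.assert_array_equal(ra.events.boundaries, rb.events.boundaries)

    def test_duplicate_subject_ids_rejected(self, profile):
        cfg = sd.StudyConfig(n_subjects=2, n_cycles=2, speeds_kmh=(5,))
        with pytest.raises(ConfigurationError):
            sd.generate_dataset(cfg, 0, profiles=[profile, profile])

    def test_recording_roundtrip_through_csv_json(self, tmp_path, tiny_recording):
        sd.save_recording(tiny_recording, tmp_path)
        back = sd.load_recording(tmp_path, tiny_recording.trial_id)
        assert back.subject_id == tiny_recording.subject_id
        assert back.condition == tiny_recording.condition
        np.testing.assert_array_equal(back.events.boundaries, tiny_recording.events.boundaries)
        np.testing.assert_allclose(back.signal, tiny_recording.signal, atol=1e-3)


class TestStyleVarianceOrdering:
    def test_window_feature_variance_orders_cs_ss_bp(self):
        """Window-level RMS variability follows the configured CS >= SS >= BP."""
        from semgait import baselines, study

        cfg = study.tiny_study_config(n_subjects=2, n_cycles=10)
        ds = sd.generate_dataset(cfg, master_seed=4)
        pools = study.style_windows_at_speed(ds, 5)
        spread = {}
        for style, ws in pools.items():
            assert len(ws) >= 1000
            feats = baselines.features_matrix(ws)
            labels = np.array([w.label for w in ws])
            # within-phase relative dispersion of every window feature,
            # averaged over phases and channels: isolates cycle-to-cycle
            # gain variability from the (style-invariant) phase structure
            # and the carrier's window-sampling noise floor
            vals = []
            for p in range(5):
                sel = feats[labels == p]
                vals.extend(np.var(sel / sel.mean(axis=0), axis=0))
            spread[style] = float(np.mean(vals))
        assert spread["CS"] >= spread["SS"] >= spread["BP"]
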