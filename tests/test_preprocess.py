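"""Preprocessing chain: filtering, channel/epoch exclusion, normalization, balance."""

import numpy as np
import pytest
from scipy import signal as sps

from errp import (ERRP, NONERRP, EpochSet, balance_classes, bandpass_filter,
                  detect_bad_channels, extract_epochs, normalize_epochs,
                  preprocess_session, reject_artifact_epochs)
from errp.preprocess import PreprocessConfig, design_bandpass
from errp.simulate import FEEDBACK_CORRECT, FEEDBACK_ERROR, Recording

from conftest import FS, SMALL_MONTAGE


def _recording(signal, fs=FS, events=None, labels=None):
    n_ch = signal.shape[0]
    labels = labels or [f"C{i}" for i in range(n_ch)]
    return Recording(labels, fs, signal, events or [])


def _epochs(data, labels, fs=FS, window=(100.0, 500.0)):
    n_samp = int(round((window[1] - window[0]) / 1000 * fs))
    assert data.shape[2] == n_samp
    chans = [f"C{i}" for i in range(data.shape[1])]
    return EpochSet(np.asarray(data, float), labels, window, fs, chans)


class TestBandpass:
    def test_dc_removed(self):
        rec = _recording(np.full((2, 40000), 7.0))
        out = bandpass_filter(rec)
        rms = np.sqrt(np.mean(out.signal[:, 5000:-5000] ** 2))
        assert rms < 0.01 * 7.0

    def test_midband_sinusoid_unit_gain_zero_lag(self):
        # the 0.05 Hz edge has a ~20 s time constant, so use a long record
        # and measure far from both ends
        fs, f = 1200.0, 5.0
        t = np.arange(int(fs * 240)) / fs
        x = np.sin(2 * np.pi * f * t)
        out = bandpass_filter(_recording(x[None, :], fs=fs)).signal[0]
        mid = slice(int(100 * fs), int(140 * fs))
        amp = np.max(np.abs(out[mid]))
        assert amp == pytest.approx(1.0, rel=0.01)
        # zero-phase: cross-correlation with the input peaks at lag 0
        seg_in, seg_out = x[mid], out[mid]
        lags = np.arange(-20, 21)
        cc = [np.dot(seg_out, np.roll(seg_in, k)) for k in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_50hz_attenuated_at_least_40db(self):
        sos = design_bandpass((0.05, 10.0), 8, 1200.0)
        w, h = sps.sosfreqz(sos, worN=[50.0], fs=1200.0)
        # forward-backward application squares the magnitude
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db >= 40.0

    def test_linearity(self, rng):
        x = rng.standard_normal((1, 8000))
        y = rng.standard_normal((1, 8000))
        fa = bandpass_filter(_recording(3 * x + 2 * y)).signal
        fb = 3 * bandpass_filter(_recording(x)).signal + 2 * bandpass_filter(_recording(y)).signal
        np.testing.assert_allclose(fa, fb, atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 5000)))
        with pytest.raises(ValueError):
            bandpass_filter(rec, band_hz=(0.05, 150.0))

    def test_short_signal_rejected(self):
        rec = _recording(np.zeros((1, 30)))
        with pytest.raises(ValueError):
            bandpass_filter(rec)

    def test_events_unchanged(self, clean_session):
        out = bandpass_filter(clean_session)
        assert out.events == clean_session.events


class TestBadChannels:
    def test_identical_channels_none_flagged(self):
        rec = _recording(np.tile(np.sin(np.arange(4000) / 50.0), (5, 1)))
        assert detect_bad_channels(rec) == []

    def test_inflated_channel_flagged(self, rng):
        sig = rng.standard_normal((37, 4000))
        sig[17] *= 50.0
        rec = _recording(sig)
        # hand-computed bound on the mean-|x| statistics
        stats = np.mean(np.abs(sig), axis=1)
        assert stats[17] > stats.mean() + 3 * stats.std()
        assert detect_bad_channels(rec) == ["C17"]

    def test_fewer_than_three_channels_rejected(self):
        with pytest.raises(ValueError):
            detect_bad_channels(_recording(np.zeros((2, 100))))

    def test_single_outlier_unflaggable_below_eleven_channels(self, rng):
        # among n channels a lone outlier's z-score cannot exceed (n-1)/sqrt(n),
        # which stays below 3 for n <= 10: the 3-SD rule needs a large montage
        sig = np.abs(rng.standard_normal((9, 2000)))
        sig[4] *= 1e6
        assert detect_bad_channels(_recording(sig)) == []

    def test_simulator_bad_channel_detected_across_seeds(self):
        """On the full 37-channel montage an inflated channel is flagged >= 95% of seeds."""
        from errp import ErpTemplateParams, make_session_schedule, synthesize_recording
        from errp.montage import default_montage
        from conftest import clean_profile
        montage = default_montage()
        sched = make_session_schedule(1, 0.5, seed=0)
        profile = clean_profile(noise_rms_uV=6.0, bad_channel_rate=0.03)
        sessions_with_bad = hits = 0
        for seed in range(60):
            rec = synthesize_recording(sched, ErpTemplateParams(), profile,
                                       montage, FS, seed=seed)
            # a 25x inflated channel has mean |x| far above the 6 uV noise RMS
            inflated = {montage[i] for i in range(len(montage))
                        if np.mean(np.abs(rec.signal[i])) > 5 * 6.0}
            if not inflated:
                continue
            sessions_with_bad += 1
            hits += inflated <= set(detect_bad_channels(bandpass_filter(rec)))
        assert sessions_with_bad >= 20
        assert hits / sessions_with_bad >= 0.95


class TestEpochExtraction:
    def test_sample_count_at_1200hz(self):
        fs = 1200.0
        sig = np.zeros((3, int(fs * 4)))
        rec = _recording(sig, fs=fs, events=[(int(fs * 1), FEEDBACK_CORRECT)])
        ep = extract_epochs(rec)
        assert ep.data.shape == (1, 3, 480)

    def test_counts_and_labels(self, noisy_session):
        ep = extract_epochs(bandpass_filter(noisy_session))
        assert ep.n_epochs == 100
        assert int(np.sum(ep.labels == ERRP)) == 30

    def test_truncated_event_dropped(self):
        sig = np.zeros((2, 200))
        events = [(50, FEEDBACK_ERROR), (180, FEEDBACK_CORRECT)]  # 2nd lacks room
        ep = extract_epochs(_recording(sig, events=events))
        assert ep.n_epochs == 1 and ep.labels[0] == ERRP

    def test_bad_channels_excluded_from_axis(self, clean_session):
        ep = extract_epochs(clean_session, exclude_channels=["FCz"])
        assert "FCz" not in ep.channel_labels
        assert ep.n_channels == len(SMALL_MONTAGE) - 1


class TestRejection:
    def test_strictly_exceeding_threshold(self):
        data = np.zeros((3, 1, 80))
        data[0, 0, 10] = 149.0
        data[1, 0, 10] = 150.0
        data[2, 0, 10] = -151.0
        ep = _epochs(data, [0, 1, 0])
        out = reject_artifact_epochs(ep, 150.0)
        assert out.n_epochs == 2
        assert list(out.trial_indices) == [0, 1]

    def test_all_zero_retained(self):
        ep = _epochs(np.zeros((4, 2, 80)), [0, 1, 0, 1])
        assert reject_artifact_epochs(ep, 150.0).n_epochs == 4

    def test_simulated_rejection_rate_in_binomial_ci(self):
        """Rejected counts track the configured artifact rate (95% CI)."""
        from errp import ErpTemplateParams, make_session_schedule, synthesize_recording
        from conftest import clean_profile
        rate, n = 0.18, 400
        lo = rate * n - 1.96 * np.sqrt(n * rate * (1 - rate))
        hi = rate * n + 1.96 * np.sqrt(n * rate * (1 - rate))
        sched = make_session_schedule(100, 0.70, seed=1)
        profile = clean_profile(noise_rms_uV=6.0, artifact_epoch_rate=rate,
                                artifact_amp_uV=300.0)
        rec = synthesize_recording(sched, ErpTemplateParams(), profile,
                                   SMALL_MONTAGE, FS, seed=21)
        ep = extract_epochs(bandpass_filter(rec))
        kept = reject_artifact_epochs(ep, 150.0)
        assert lo <= ep.n_epochs - kept.n_epochs <= hi


class TestNormalize:
    def test_constant_epoch_becomes_zero(self):
        ep = _epochs(np.full((2, 3, 80), 42.0), [0, 1])
        assert not np.any(normalize_epochs(ep).data)

    def test_zero_mean_and_idempotent(self, noisy_epochs):
        out = normalize_epochs(noisy_epochs)
        np.testing.assert_allclose(out.data.mean(axis=2), 0.0, atol=1e-12)
        np.testing.assert_allclose(normalize_epochs(out).data, out.data, atol=1e-12)


class TestBalance:
    def test_subsamples_majority_to_minority(self, rng):
        data = rng.standard_normal((40, 2, 80))
        labels = np.array([ERRP] * 12 + [NONERRP] * 28)
        out = balance_classes(_epochs(data, labels), seed=5)
        assert out.class_counts() == {"NonErrP": 12, "ErrP": 12}
        # all minority epochs kept
        assert set(np.flatnonzero(labels == ERRP)) <= set(out.trial_indices)

    def test_already_balanced_is_identity_up_to_order(self, rng):
        data = rng.standard_normal((10, 1, 80))
        labels = np.array([ERRP, NONERRP] * 5)
        out = balance_classes(_epochs(data, labels), seed=0)
        assert sorted(out.trial_indices) == list(range(10))

    def test_deterministic(self, rng):
        ep = _epochs(rng.standard_normal((30, 1, 80)), [ERRP] * 10 + [NONERRP] * 20)
        a = balance_classes(ep, seed=3)
        b = balance_classes(ep, seed=3)
        np.testing.assert_array_equal(a.trial_indices, b.trial_indices)

    def test_single_class_rejected(self, rng):
        ep = _epochs(rng.standard_normal((5, 1, 80)), [ERRP] * 5)
        with pytest.raises(ValueError):
            balance_classes(ep, seed=0)


class TestPipelineComposition:
    def test_count_conservation_and_purity(self, noisy_session):
        ep, log = preprocess_session(noisy_session, seed=9)
        assert log.n_trials - log.n_rejected == log.n_errp + log.n_nonerrp
        assert log.n_after_balance == 2 * min(log.n_errp, log.n_nonerrp)
        assert ep.n_epochs == log.n_after_balance
        ep2, _ = preprocess_session(noisy_session, seed=9)
        np.testing.assert_array_equal(ep.data, ep2.data)
        np.testing.assert_array_equal(ep.trial_indices, ep2.trial_indices)

    def test_provenance_maps_to_original_trials(self, noisy_session):
        ep, _ = preprocess_session(noisy_session, seed=9)
        fb = bandpass_filter(noisy_session).feedback_events()
        for row, orig in zip(ep.labels, ep.trial_indices):
            code = fb[orig][1]
            assert row == (ERRP if code == FEEDBACK_ERROR else NONERRP)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(band_hz=(10.0, 0.05))
        with pytest.raises(ValueError):
            PreprocessConfig(filter_order=7)
        with pytest.raises(ValueError):
            PreprocessConfig(reject_amp_uV=0.0)
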