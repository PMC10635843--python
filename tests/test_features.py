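"""Feature pipeline: segmentation, peak finding, filtering, envelopes."""

import numpy as np
import pytest
from scipy import stats as sstats

from gammadbs.features import (
    NoPeakError,
    RecordingEpoch,
    bandpass,
    envelope_pdf,
    extract_features,
    find_gamma_peak,
    hilbert_envelope,
    segment_epochs,
    select_epoch,
    welch_psd,
)

RATE = 250.0


def tone(freq, duration, amp=1.0, rate=RATE, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


def noisy_tone_epoch(freq, duration=40.0, amp=1.0, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = tone(freq, duration, amp) + noise * rng.standard_normal(
        int(duration * RATE))
    return RecordingEpoch(rate=RATE, samples=x)


class TestSegmentEpochs:
    def test_single_long_stream(self):
        eps = segment_epochs(np.zeros(25000), RATE, 30.0)
        assert len(eps) == 1 and eps[0].duration == pytest.approx(100.0)

    def test_below_minimum_returns_empty(self):
        assert segment_epochs(np.zeros(int(29 * RATE)), RATE, 30.0) == []

    def test_gap_splits_stream(self):
        x = np.concatenate([np.zeros(int(40 * RATE)), [np.nan] * 10,
                            np.zeros(int(35 * RATE))])
        eps = segment_epochs(x, RATE, 30.0)
        assert len(eps) == 2
        assert eps[0].duration == pytest.approx(40.0)
        assert eps[1].t_start > 40.0


class TestFindGammaPeak:
    def test_planted_tone_is_found(self):
        pk = find_gamma_peak(noisy_tone_epoch(75.0, noise=1.0))
        assert pk.found and abs(pk.frequency - 75.0) <= 1.0

    def test_white_noise_has_no_peak(self):
        rng = np.random.default_rng(7)
        ep = RecordingEpoch(rate=RATE,
                            samples=rng.standard_normal(int(60 * RATE)))
        assert not find_gamma_peak(ep).found

    def test_larger_of_two_tones_wins(self):
        x = tone(70, 40, 1.0) + tone(80, 40, np.sqrt(2.0)) \
            + 0.5 * np.random.default_rng(1).standard_normal(int(40 * RATE))
        pk = find_gamma_peak(RecordingEpoch(rate=RATE, samples=x))
        assert abs(pk.frequency - 80.0) <= 1.0


class TestSelectEpoch:
    def test_picks_most_prominent_within_band(self):
        eps = [noisy_tone_epoch(74, amp=0.8, seed=1),
               noisy_tone_epoch(76, amp=1.5, seed=2),
               noisy_tone_epoch(90, amp=3.0, seed=3)]
        chosen = select_epoch(eps, 75.0)
        assert chosen is eps[1]  # 90 Hz excluded despite largest peak

    def test_single_qualifying_epoch(self):
        ep = noisy_tone_epoch(75)
        assert select_epoch([ep], 75.0) is ep

    def test_tie_breaks_to_earlier_start(self):
        a = noisy_tone_epoch(75, seed=5)
        b = noisy_tone_epoch(75, seed=5)
        a.t_start, b.t_start = 100.0, 0.0
        assert select_epoch([a, b], 75.0) is b

    def test_no_epoch_in_band_raises(self):
        with pytest.raises(NoPeakError, match="75"):
            select_epoch([noisy_tone_epoch(85)], 75.0)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        # amplitude read from the envelope: at 250 Hz the samples of a
        # 75 Hz tone never hit the crest exactly
        y = bandpass(tone(75, 30), RATE, 75.0)
        env = hilbert_envelope(y)[int(5 * RATE): int(25 * RATE)]
        assert env.mean() == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuated(self):
        y = bandpass(tone(60, 30), RATE, 75.0)
        assert np.abs(y[int(5 * RATE): int(25 * RATE)]).max() <= 0.1

    def test_dc_removed(self):
        y = bandpass(np.ones(int(30 * RATE)), RATE, 75.0)
        assert abs(y.mean()) < 1e-6

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(tone(75, 5), RATE, 124.0)


class TestHilbertEnvelope:
    def test_constant_tone_envelope(self):
        env = hilbert_envelope(tone(75, 30, amp=0.7))
        interior = env[int(RATE): -int(RATE)]
        assert np.allclose(interior, 0.7, atol=0.01)

    def test_zero_signal(self):
        assert np.all(hilbert_envelope(np.zeros(1000)) == 0)

    def test_am_modulator_recovered(self):
        t = np.arange(int(30 * RATE)) / RATE
        mod = 1 + 0.5 * np.sin(2 * np.pi * 2 * t)
        env = hilbert_envelope(mod * np.sin(2 * np.pi * 75 * t))
        sl = slice(int(RATE), -int(RATE))
        assert np.corrcoef(env[sl], mod[sl])[0, 1] > 0.99


class TestWelchPSD:
    def test_parseval_for_white_noise(self):
        x = 2.0 * np.random.default_rng(0).standard_normal(int(60 * RATE))
        f, p = welch_psd(x, RATE)
        assert np.sum(p) * (f[1] - f[0]) == pytest.approx(4.0, rel=0.05)

    def test_tone_power_scales_quadratically(self):
        f, p1 = welch_psd(tone(75, 30), RATE)
        f, p2 = welch_psd(tone(75, 30, amp=2.0), RATE)
        assert p2[np.argmax(p1)] == pytest.approx(4 * p1.max(), rel=1e-6)
        assert f[np.argmax(p1)] == 75.0

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), RATE, window_length=1.0)


class TestEnvelopePDF:
    def test_constant_envelope_single_bin(self):
        centres, dens = envelope_pdf(np.full(1000, 3.0))
        width = centres[1] - centres[0]
        assert np.sum(dens > 0) == 1
        assert np.sum(dens) * width == pytest.approx(1.0, abs=1e-6)

    def test_rayleigh_samples_match_density(self):
        env = sstats.rayleigh.rvs(scale=1.0, size=7500,
                                  random_state=np.random.default_rng(4))
        centres, dens = envelope_pdf(env)
        width = centres[1] - centres[0]
        cdf_emp = np.cumsum(dens) * width
        cdf_true = sstats.rayleigh.cdf(centres + width / 2)
        assert np.abs(cdf_emp - cdf_true).max() < 0.05

    def test_integral_is_one(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            c, d = envelope_pdf(rng.gamma(2.0, size=2000))
            assert np.sum(d) * (c[1] - c[0]) == pytest.approx(1.0, abs=1e-6)


class TestExtractFeatures:
    def test_planted_rhythm_pipeline(self):
        fs = extract_features(noisy_tone_epoch(75, duration=40, noise=0.5))
        assert abs(fs.peak_frequency - 75.0) <= 1.0
        assert fs.band == (fs.peak_frequency - 3, fs.peak_frequency + 3)
        width = fs.env_pdf_bins[1] - fs.env_pdf_bins[0]
        assert np.sum(fs.env_pdf) * width == pytest.approx(1.0, abs=1e-6)

    def test_deterministic(self):
        a = extract_features(noisy_tone_epoch(75, seed=2))
        b = extract_features(noisy_tone_epoch(75, seed=2))
        assert np.array_equal(a.psd, b.psd)
        assert np.array_equal(a.env_pdf, b.env_pdf)

    def test_gain_invariance(self):
        ep = noisy_tone_epoch(75, seed=3)
        scaled = RecordingEpoch(rate=RATE, samples=ep.samples * 37.0)
        a, b = extract_features(ep), extract_features(scaled)
        assert np.allclose(a.psd, b.psd)
        assert np.allclose(a.env_psd, b.env_psd)
        assert np.allclose(a.env_pdf, b.env_pdf)
        assert b.zscore_params["gain"] == pytest.approx(
            37.0 * a.zscore_params["gain"], rel=1e-6)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="30"):
            extract_features(noisy_tone_epoch(75, duration=20))
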