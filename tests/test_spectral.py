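"""Multitaper estimators: spectrogram, coherence, SFC, band power, crosscorr."""

import numpy as np
import pytest

from painlfp.signal_ops import BandDef, CANONICAL_BANDS
from painlfp.spectral import (
    SpectralError,
    TaperSpec,
    band_power,
    coherence_bias_floor,
    lfp_crosscorr,
    mt_coherence,
    mt_psd,
    mt_spectrogram,
    spike_field_coherence,
    zscore_spectrogram,
)

FS = 1000.0


def tone(freq, dur=10.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t)


class TestTapers:
    def test_tw5_gives_9_tapers(self):
        assert TaperSpec(tw=5.0).k == 9

    def test_tw3_gives_5_tapers(self):
        assert TaperSpec(tw=3.0).k == 5

    def test_taper_orthogonality(self):
        tapers = TaperSpec(tw=5.0).tapers(500)
        gram = tapers @ tapers.T
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-10)


class TestSpectrogram:
    def test_sinusoid_peak_tracks_frequency(self):
        spec = mt_spectrogram(tone(6.0), FS,
                              TaperSpec(tw=5.0, window_len=1.0, step=0.25))
        resolution = 2 * 5.0 / 1.0
        for col in spec.power.T:
            assert abs(spec.freqs[np.argmax(col)] - 6.0) <= resolution

    def test_white_noise_parseval(self, rng):
        sigma = 2.0
        x = rng.standard_normal(int(20 * FS)) * sigma
        freqs, psd = mt_psd(x, FS, tw=5)
        total = psd.sum() * (freqs[1] - freqs[0])
        assert abs(total - sigma**2) / sigma**2 < 0.1

    def test_window_longer_than_signal(self):
        with pytest.raises(SpectralError, match="longer"):
            mt_spectrogram(np.zeros(100), FS, TaperSpec(window_len=0.5))

    def test_power_nonnegative(self, rng):
        spec = mt_spectrogram(rng.standard_normal(4000), FS,
                              TaperSpec(window_len=0.5, step=0.1))
        assert (spec.power >= 0).all()


class TestZscoreSpectrogram:
    def make(self, rng, burst=False):
        x = rng.standard_normal(int(10 * FS))
        if burst:
            t = np.arange(int(10 * FS)) / FS
            x += 4.0 * np.cos(2 * np.pi * 45.0 * t) * ((t > 5.5) & (t < 8.0))
        spec = mt_spectrogram(x, FS, TaperSpec(window_len=0.5, step=0.1), t0=-5.0)
        return zscore_spectrogram(spec, baseline=(-5.0, 0.0))

    def test_baseline_mean_near_zero(self, rng):
        z = self.make(rng)
        cols = (z.times >= -5) & (z.times < 0)
        assert np.abs(z.zscore[:, cols].mean(axis=1)).max() < 0.2

    def test_gamma_burst_z_above_2(self, rng):
        z = self.make(rng, burst=True)
        rows = (z.freqs >= 30) & (z.freqs <= 80)
        cols = (z.times > 0.6) & (z.times < 2.9)  # burst at 5.5-8 s, t0 = -5
        assert z.zscore[np.ix_(rows, cols)].max() > 2.0

    def test_stationary_signal_mostly_within_2sd(self, rng):
        z = self.make(rng)
        frac = np.mean(np.abs(z.zscore) <= 2.0)
        assert frac >= 0.9


class TestCoherence:
    def test_identical_signals_coherence_one(self, rng):
        x = rng.standard_normal(2000)
        _, coh, _ = mt_coherence(x, x, FS, TaperSpec(tw=5.0, window_len=2.0))
        np.testing.assert_allclose(coh, 1.0, atol=1e-6)

    def test_independent_noise_below_bias_floor(self, rng):
        n_trials, k = 20, 9
        xs = rng.standard_normal((n_trials, 2000))
        ys = rng.standard_normal((n_trials, 2000))
        freqs, coh, se = mt_coherence(xs, ys, FS, TaperSpec(tw=5.0, window_len=2.0))
        floor = coherence_bias_floor(n_trials * k, 0.95)
        ok = coh <= floor + 2 * se
        assert ok.mean() >= 0.95

    def test_shared_oscillation_peaks_at_its_frequency(self, rng):
        shared = tone(6.0, dur=2.0, amp=1.0)
        xs = np.stack([shared + 0.5 * rng.standard_normal(2000) for _ in range(10)])
        ys = np.stack([shared + 0.5 * rng.standard_normal(2000) for _ in range(10)])
        freqs, coh, _ = mt_coherence(xs, ys, FS, TaperSpec(tw=5.0, window_len=2.0))
        sel = freqs <= 100
        assert abs(freqs[sel][np.argmax(coh[sel])] - 6.0) <= 5.0

    def test_single_taper_jackknife_rejected(self, rng):
        x = rng.standard_normal(1000)
        with pytest.raises(SpectralError, match="jackknife"):
            mt_coherence(x, x, FS, TaperSpec(tw=1.5, n_tapers=1, window_len=1.0))


def locked_spikes(rng, freq=6.0, kappa=4.0, rate=25.0, dur=20.0):
    """Inhomogeneous-Poisson spikes with von Mises phase preference."""
    t = np.arange(int(dur * FS)) / FS
    lam = rate * np.exp(kappa * np.cos(2 * np.pi * freq * t)) / np.i0(kappa)
    return t[rng.uniform(size=t.size) < lam / FS]


class TestSpikeFieldCoherence:
    def test_locked_spikes_peak_at_field_frequency(self, rng):
        dur = 20.0
        field = tone(6.0, dur=dur) + 0.5 * rng.standard_normal(int(dur * FS))
        spikes = locked_spikes(rng)
        freqs, sfc, _ = spike_field_coherence(spikes, field, FS,
                                              TaperSpec(tw=3.0, window_len=dur))
        sel = (freqs > 1) & (freqs <= 50)
        resolution = 2 * 3.0 / dur
        assert abs(freqs[sel][np.argmax(sfc[sel])] - 6.0) <= max(resolution, 0.5)
        assert np.all((sfc >= 0) & (sfc <= 1 + 1e-12))

    def test_homogeneous_spikes_below_bias_floor(self, rng):
        dur = 20.0
        field = rng.standard_normal(int(dur * FS))
        spikes = np.sort(rng.uniform(0, dur, 500))
        freqs, sfc, se = spike_field_coherence(spikes, field, FS,
                                               TaperSpec(tw=3.0, window_len=dur))
        floor = coherence_bias_floor(5, 0.95)
        assert (sfc <= floor + 2 * se).mean() >= 0.9

    def test_locking_strength_monotone(self):
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            dur = 20.0
            field = tone(6.0, dur=dur) + 0.5 * r.standard_normal(int(dur * FS))
            f, s4, _ = spike_field_coherence(locked_spikes(r, kappa=4.0), field, FS,
                                             TaperSpec(tw=3.0, window_len=dur))
            f, s0, _ = spike_field_coherence(locked_spikes(r, kappa=1e-6), field, FS,
                                             TaperSpec(tw=3.0, window_len=dur))
            theta = (f >= 4) & (f <= 8)
            wins += s4[theta].mean() > s0[theta].mean()
        assert wins == 10

    def test_empty_train_rejected(self):
        with pytest.raises(SpectralError, match="empty"):
            spike_field_coherence(np.array([]), np.zeros(2000), FS)


class TestBandPower:
    def test_theta_tone_dominates(self):
        bp = band_power(tone(6.0), FS)
        assert bp["theta"] - bp["beta"] >= 20.0

    def test_additivity_over_contiguous_bands(self, rng):
        x = rng.standard_normal(int(10 * FS))
        bp = band_power(x, FS)
        total_parts = sum(10 ** (bp[b.name] / 10) for b in CANONICAL_BANDS)
        whole = band_power(x, FS, bands=(BandDef("all", 4.0, 80.0),))["all"]
        assert abs(total_parts - 10 ** (whole / 10)) / 10 ** (whole / 10) < 0.01

    def test_doubling_amplitude_adds_6db(self):
        b1 = band_power(tone(6.0, amp=1.0), FS)["theta"]
        b2 = band_power(tone(6.0, amp=2.0), FS)["theta"]
        assert b2 - b1 == pytest.approx(6.02, abs=0.1)

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(SpectralError, match="Nyquist"):
            band_power(np.zeros(1000), FS, bands=(BandDef("bad", 400.0, 600.0),))


class TestCrossCorr:
    def test_self_correlation_peaks_at_zero(self, rng):
        x = rng.standard_normal(int(10 * FS))
        lags, cc = lfp_crosscorr(x, x, FS)
        assert lags[np.argmax(cc)] == 0.0
        assert cc.max() == pytest.approx(1.0, abs=0.01)

    def test_delay_shifts_the_peak(self, rng):
        x = rng.standard_normal(int(10 * FS))
        y = np.roll(x, int(0.2 * FS))
        lags, cc = lfp_crosscorr(x, y, FS, max_lag=0.4)
        assert lags[np.argmax(cc)] == pytest.approx(0.2, abs=0.01)

    def test_two_theta_oscillators_rhythmic_correlogram(self, rng):
        t = np.arange(int(20 * FS)) / FS
        x = np.cos(2 * np.pi * 6.0 * t) + 0.3 * rng.standard_normal(t.size)
        y = np.cos(2 * np.pi * 6.0 * t + 1.0) + 0.3 * rng.standard_normal(t.size)
        lags, cc = lfp_crosscorr(x, y, FS, max_lag=0.5)
        # peaks separated by ~1/6 s
        peaks = lags[np.flatnonzero((cc[1:-1] > cc[:-2]) & (cc[1:-1] > cc[2:])) + 1]
        spacing = np.diff(peaks)
        assert np.abs(spacing - 1 / 6.0).min() < 0.02

    def test_excessive_lag_rejected(self):
        with pytest.raises(SpectralError):
            lfp_crosscorr(np.zeros(1000), np.zeros(1000), FS, max_lag=2.0)
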