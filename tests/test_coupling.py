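import numpy as np
import pytest
from scipy.signal import coherence as scipy_coherence

from laminarfp.coupling import (
    coherence_with_significance,
    crosscorr_lagged,
    mean_frequency_autocorr,
    phase_randomize,
    windowed_pearson_histogram,
)
from laminarfp.deconv import pulse_template
from laminarfp.preprocess import exclude_large_events


class TestCrossCorrelation:
    def test_identity_peaks_at_zero_lag(self):
        t = np.arange(10000) / 1000.0
        x = np.sin(2 * np.pi * 7 * t)
        r = crosscorr_lagged(x, x, 1000.0, max_lag=0.05)
        assert r.cc_max == pytest.approx(1.0, abs=1e-6)
        assert r.tau_max == 0.0

    def test_delay_convention_positive_when_y_trails_x(self, rng):
        fs = 1000.0
        x = rng.standard_normal(20000)
        y = np.roll(x, 10)  # y is x delayed by 10 ms
        r = crosscorr_lagged(x, y, fs, max_lag=0.05)
        assert r.tau_max == pytest.approx(0.010)

    def test_independent_noise_cc_small(self, rng):
        fs = 250.0
        small = 0
        for _ in range(20):
            r = crosscorr_lagged(rng.standard_normal(15000),
                                 rng.standard_normal(15000), fs, max_lag=0.2)
            small += abs(r.cc_max) < 0.05
        assert small >= 19

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            crosscorr_lagged(np.zeros(1000), np.ones(1000), 100.0, 0.1)

    def test_swap_symmetry(self, rng):
        x, y = rng.standard_normal(5000), rng.standard_normal(5000)
        a = crosscorr_lagged(x, y, 1000.0, 0.02)
        b = crosscorr_lagged(y, x, 1000.0, 0.02)
        assert np.allclose(a.R, b.R[::-1], atol=1e-12)

    def test_surrogate_significance_level(self, rng):
        x, y = rng.standard_normal(8000), rng.standard_normal(8000)
        r = crosscorr_lagged(x, y, 1000.0, 0.05, n_surrogates=50, seed=0)
        assert 0 < r.significance < 0.2


class TestPhaseRandomize:
    def test_sine_keeps_frequency_and_amplitude(self):
        t = np.arange(4096) / 1000.0
        x = np.sin(2 * np.pi * 25 * t)
        s = phase_randomize(x, seed=1)
        fx, fs_ = np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(s))
        assert np.allclose(fx, fs_, rtol=1e-10, atol=1e-8)

    def test_spectrum_preserved_for_noise(self, rng):
        x = rng.standard_normal(5001)  # odd length: no Nyquist bin
        s = phase_randomize(x, seed=2)
        assert np.allclose(np.abs(np.fft.rfft(x)), np.abs(np.fft.rfft(s)),
                           rtol=1e-10, atol=1e-10)
        assert s.mean() == pytest.approx(x.mean(), abs=1e-10)

    def test_surrogate_decorrelated_from_original(self, rng):
        ok = 0
        for i in range(20):
            x = rng.standard_normal(15000)
            s = phase_randomize(x, seed=i)
            ok += abs(np.corrcoef(x, s)[0, 1]) < 0.05
        assert ok >= 19


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(15000)
        r = coherence_with_significance(x, x, 250.0, n_surrogates=0)
        assert (r.coherence >= 0.99).all()

    def test_matches_scipy_welch(self, rng):
        x, y = rng.standard_normal(15000), rng.standard_normal(15000)
        r = coherence_with_significance(x, y, 250.0, n_surrogates=0)
        f, C = scipy_coherence(x, y, fs=250.0, window="hann", nperseg=250,
                               noverlap=125)
        assert np.allclose(r.freqs, f)
        assert np.allclose(r.coherence, C, atol=1e-3)

    def test_half_coherence_for_equal_band_power_noise(self, rng):
        from laminarfp.preprocess import filter_signal
        fs, n = 250.0, 30000
        x = filter_signal(rng.standard_normal(n), "bandpass", (5, 20), fs=fs)
        m = filter_signal(rng.standard_normal(n), "bandpass", (5, 20), fs=fs)
        y = x + m * (x.std() / m.std())
        r = coherence_with_significance(x, y, fs, n_surrogates=0)
        band = (r.freqs >= 7) & (r.freqs <= 18)
        assert r.coherence[band].mean() == pytest.approx(0.5, abs=0.05)

    def test_single_segment_rejected(self, rng):
        with pytest.raises(ValueError, match="segment"):
            coherence_with_significance(rng.standard_normal(300),
                                        rng.standard_normal(300), 250.0)

    def test_threshold_decreases_with_more_segments(self, rng):
        fs = 250.0
        thr = []
        for dur in (20, 120):
            x = rng.standard_normal(int(dur * fs))
            y = rng.standard_normal(int(dur * fs))
            r = coherence_with_significance(x, y, fs, n_surrogates=200, seed=0)
            thr.append(r.threshold[5:-5].mean())
        assert thr[1] < thr[0]

    def test_masked_segments_excluded(self, rng):
        fs = 250.0
        x = rng.standard_normal(15000)
        y = rng.standard_normal(15000)
        x2 = x.copy()
        x2[5000:5100] += 50.0  # large transient
        masked = exclude_large_events(x2, fs, k=5.0, pad=0.05)
        r = coherence_with_significance(x2, y, fs, n_surrogates=0,
                                        mask=masked.mask)
        r_clean = coherence_with_significance(x, y, fs, n_surrogates=0)
        # masking removes the transient's broadband leakage
        assert r.n_segments < r_clean.n_segments
        assert r.coherence.max() < 0.5


class TestWindowedPearson:
    def test_identity_and_sign_flip(self, rng):
        x = rng.standard_normal(40000)
        w = windowed_pearson_histogram(x, x, 4000.0, 0.01)
        assert w.mean == pytest.approx(1.0) and w.sd == pytest.approx(0.0)
        w = windowed_pearson_histogram(x, -x, 4000.0, 0.01)
        assert w.mean == pytest.approx(-1.0)

    def test_null_moments_at_10ms_windows(self, rng):
        n = 400000  # 100 s at 4 kHz -> 10^4 windows
        w = windowed_pearson_histogram(rng.standard_normal(n),
                                       rng.standard_normal(n), 4000.0, 0.01)
        assert w.mean == pytest.approx(0.0, abs=0.01)
        assert w.sd == pytest.approx(1 / np.sqrt(39), abs=0.01)

    def test_zero_variance_window_recorded_missing(self, rng):
        fs, dt = 1000.0, 0.1
        x = rng.standard_normal(20000)
        y = rng.standard_normal(20000)
        x[:100] = 3.14  # first window constant
        w = windowed_pearson_histogram(x, y, fs, dt)
        assert np.isnan(w.r[0])
        assert w.n_valid == w.n_windows - 1

    def test_density_integrates_to_one(self, rng):
        w = windowed_pearson_histogram(rng.standard_normal(40000),
                                       rng.standard_normal(40000), 4000.0, 0.01)
        assert np.sum(w.density * np.diff(w.edges)) == pytest.approx(1.0)

    def test_histograms_flatten_as_windows_shrink(self, rng):
        n = 400000
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        sds = [windowed_pearson_histogram(x, y, 4000.0, dt).sd
               for dt in (1.0, 0.1, 0.01)]
        assert sds[0] < sds[1] < sds[2]


class TestMeanFrequency:
    def test_pure_40hz_sine(self, rng):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 40 * t) + 0.05 * rng.standard_normal(t.size)
        f = mean_frequency_autocorr(x, fs)
        assert f == pytest.approx(40.0, abs=fs / (fs / 40) ** 2 + 1.7)

    def test_pulse_train_28ms_interval(self, rng):
        # pulse-like waves every 28 ms on average -> ~35.7 Hz
        fs, dur = 1000.0, 30.0
        n = int(dur * fs)
        t = np.arange(n) / fs
        x = np.zeros(n)
        tau = 0.05
        while tau < dur - 0.1:
            a = int(tau * fs)
            b = min(n, a + 40)
            x[a:b] -= pulse_template(t[a:b] - tau, 0.005)
            tau += 0.028 + 0.002 * rng.standard_normal()
        f = mean_frequency_autocorr(x, fs)
        assert f == pytest.approx(35.7, abs=2.0)

    def test_bandpassed_noise_stays_in_band(self, rng):
        f = mean_frequency_autocorr(rng.standard_normal(60000), 1000.0)
        assert 30.0 <= f <= 100.0

    def test_too_short_input_rejected(self, rng):
        with pytest.raises(ValueError, match="100 cycles"):
            mean_frequency_autocorr(rng.standard_normal(1000), 1000.0)
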