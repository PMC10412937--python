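import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from laminarfp.deconv import (
    BaselineQualityWarning,
    DeconvConfig,
    PulseDeconvolver,
    PulseEvent,
    amplitude_covariation,
    deconvolve_events,
    overlap_fraction,
    pair_events,
    pulse_template,
)


class TestTemplate:
    def test_zero_for_nonpositive_time(self):
        assert pulse_template(0.0, 0.01) == 0.0
        assert pulse_template(-1.0, 0.01) == 0.0

    def test_peak_at_delta(self):
        d = 0.005
        assert pulse_template(d, d) == pytest.approx(np.exp(-0.5) / d)
        t = np.linspace(0, 6 * d, 10000)
        assert abs(t[np.argmax(pulse_template(t, d))] - d) < 2 * 6 * d / 10000

    @given(st.floats(1e-3, 0.1))
    @settings(max_examples=20, deadline=None)
    def test_unit_area_for_any_delta(self, d):
        area, _ = quad(lambda t: pulse_template(t, d), 0, 20 * d)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_rejects_nonpositive_delta(self):
        with pytest.raises(ValueError):
            pulse_template(0.1, 0.0)


class TestDeconvolution:
    def test_single_noiseless_pulse_recovered(self):
        fs = 1000.0
        t = np.arange(int(0.4 * fs)) / fs
        s = 2.0 * pulse_template(t - 0.1, 0.005)
        events, resid = deconvolve_events(s, fs)
        assert len(events) == 1
        e = events[0]
        assert abs(e.tau - 0.1) <= 0.002
        assert abs(e.w - 2.0) / 2.0 <= 0.05
        assert abs(e.delta - 0.005) / 0.005 <= 0.10

    def test_two_separated_pulses(self):
        fs = 1000.0
        t = np.arange(int(0.4 * fs)) / fs
        s = 2.0 * pulse_template(t - 0.1, 0.005) \
            + 1.5 * pulse_template(t - 0.15, 0.005)
        events, _ = deconvolve_events(s, fs)
        assert len(events) == 2
        assert events[0].tau == pytest.approx(0.1, abs=0.002)
        assert events[1].tau == pytest.approx(0.15, abs=0.002)

    def test_white_noise_yields_no_events(self, rng):
        s = 0.1 * rng.standard_normal(10000)
        events, _ = deconvolve_events(s, 1000.0)
        assert events == []

    def test_fluctuating_baseline_warns(self, rng):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        s = np.sin(2 * np.pi * 1.0 * t) + 0.01 * rng.standard_normal(t.size)
        with pytest.warns(BaselineQualityWarning):
            deconvolve_events(s, fs, DeconvConfig(max_events=2))

    def test_residual_decreases_monotonically(self, rng):
        fs = 1000.0
        t = np.arange(int(5 * fs)) / fs
        s = np.zeros(t.size)
        for tau in (0.5, 1.2, 2.0, 3.1, 4.0):
            s -= pulse_template(t - tau, 0.005)
        s += 0.02 * rng.standard_normal(t.size)
        norms = []
        for k in (1, 2, 3, 4, 5):
            _, resid = deconvolve_events(
                s, fs, DeconvConfig(max_events=k, polarity="negative",
                                    refine=False)
            )
            norms.append(np.sum(resid**2))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_estimator_wrapper_reconstructs(self):
        fs = 1000.0
        t = np.arange(int(1.0 * fs)) / fs
        s = 3.0 * pulse_template(t - 0.3, 0.01)
        est = PulseDeconvolver(fs=fs).fit(s)
        assert len(est.events_) == 1
        model = est.predict()
        assert np.allclose(model, s, atol=1e-3 * np.abs(s).max())


def _ev(tau_ms, dur_ms, w=1.0):
    return PulseEvent(w=w, tau=tau_ms / 1000.0, delta=dur_ms / 3.0 / 1000.0)


class TestPairing:
    def test_seventy_percent_boundary_paired(self):
        # supports [100,130] and [106,136] ms: overlap 24/30 = 0.8
        L, R = [_ev(100, 30)], [_ev(106, 30)]
        assert overlap_fraction(L[0], R[0]) == pytest.approx(0.8)
        assert len(pair_events(L, R).pairs) == 1

    def test_low_overlap_unpaired(self):
        # supports [100,130] and [125,155] ms: overlap 5/30 ~ 0.17
        L, R = [_ev(100, 30)], [_ev(125, 30)]
        assert overlap_fraction(L[0], R[0]) == pytest.approx(5 / 30)
        res = pair_events(L, R)
        assert res.pairs == []
        assert res.unpaired_left == [0] and res.unpaired_right == [0]

    def test_symmetry(self, rng):
        L = [_ev(1000 * rng.uniform(0, 1), rng.uniform(20, 40)) for _ in range(6)]
        R = [_ev(1000 * rng.uniform(0, 1), rng.uniform(20, 40)) for _ in range(5)]
        a = pair_events(L, R)
        b = pair_events(R, L)
        assert sorted((i, j) for i, j, _ in a.pairs) == \
            sorted((j, i) for i, j, _ in b.pairs)

    def test_matches_brute_force_on_small_lists(self, rng):
        for trial in range(50):
            nl, nr = rng.integers(1, 6), rng.integers(1, 6)
            L = [_ev(1000 * rng.uniform(0, 0.3), rng.uniform(15, 45))
                 for _ in range(nl)]
            R = [_ev(1000 * rng.uniform(0, 0.3), rng.uniform(15, 45))
                 for _ in range(nr)]
            got = pair_events(L, R)
            best = _brute_force_total(L, R)
            total = sum(f for _, _, f in got.pairs)
            assert total == pytest.approx(best, abs=1e-9)


def _brute_force_total(L, R, min_overlap=0.7):
    """Maximum total overlap over all one-to-one matchings."""
    nl, nr = len(L), len(R)
    best = 0.0
    k = min(nl, nr)
    for size in range(k + 1):
        for li in itertools.combinations(range(nl), size):
            for rj in itertools.permutations(range(nr), size):
                fracs = [overlap_fraction(L[i], R[j]) for i, j in zip(li, rj)]
                if all(f >= min_overlap for f in fracs):
                    best = max(best, sum(fracs))
    return best


class TestAmplitudeCovariation:
    def _pairs(self, n):
        return type("P", (), {"pairs": [(i, i, 1.0) for i in range(n)]})()

    def test_identical_amplitudes_on_diagonal(self):
        L = [_ev(i * 100, 30, w=1 + i) for i in range(5)]
        res = amplitude_covariation(L, list(L), self._pairs(5))
        assert res.r == pytest.approx(1.0)
        assert res.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_independent_amplitudes_uncorrelated(self, rng):
        small = 0
        for _ in range(10):
            L = [_ev(i * 100, 30, w=rng.uniform(0.5, 2)) for i in range(100)]
            R = [_ev(i * 100, 30, w=rng.uniform(0.5, 2)) for i in range(100)]
            res = amplitude_covariation(L, R, self._pairs(100))
            small += abs(res.r) < 0.2
        assert small >= 9

    def test_common_amplitude_with_small_noise(self, rng):
        w = rng.uniform(0.5, 2, 100)
        L = [_ev(i * 100, 30, w=wi) for i, wi in enumerate(w)]
        R = [_ev(i * 100, 30, w=wi * (1 + 0.05 * rng.standard_normal()))
             for i, wi in enumerate(w)]
        res = amplitude_covariation(L, R, self._pairs(100))
        assert res.r >= 0.95

    def test_requires_three_pairs(self):
        L = [_ev(0, 30), _ev(100, 30)]
        with pytest.raises(ValueError):
            amplitude_covariation(L, list(L), self._pairs(2))
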