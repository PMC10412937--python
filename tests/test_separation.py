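import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from laminarfp.separation import (
    GeneratorSet,
    LaminarICA,
    epoch_stability_length,
    match_profiles,
    pca_reduce,
    profile_similarity,
    relative_variance_filter,
    run_ica,
)


def _align(true_mix, est_mix):
    """Best one-to-one assignment of estimated to true generators."""
    n, m = true_mix.shape[1], est_mix.shape[1]
    C = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            C[i, j] = abs(profile_similarity(true_mix[:, i], est_mix[:, j]))
    ri, ci = linear_sum_assignment(-C)
    return ri, ci, C[ri, ci]


class TestPCAReduce:
    def test_exact_rank_two(self, rng):
        base = rng.standard_normal((2, 5000))
        data = rng.standard_normal((8, 2)) @ base
        red = pca_reduce(data, 2)
        assert red.explained_variance_ratio.sum() > 0.9999
        back = red.back_project()
        assert np.allclose(back, data, atol=1e-8)

    def test_white_noise_variance_share(self, rng):
        data = rng.standard_normal((32, 20000))
        red = pca_reduce(data, 0.9)
        # eigenvalues of white-noise covariance are nearly equal
        assert 24 <= red.scores.shape[0] <= 31

    def test_retain_beyond_channel_count(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            pca_reduce(rng.standard_normal((32, 100)), 64)

    def test_retain_beyond_rank(self, rng):
        base = rng.standard_normal((2, 500))
        data = rng.standard_normal((8, 2)) @ base
        with pytest.raises(ValueError, match="rank"):
            pca_reduce(data, 5)


class TestLaminarICA:
    def test_identity_mixing_laplacian_sources(self, rng):
        S = rng.laplace(size=(2, 20000))
        gs = run_ica(S, n_components=2, fs=1000.0, seed=0)
        _, _, sims = _align(np.eye(2), gs.mixing)
        assert (sims >= 0.99).all()

    def test_random_mixing_recovery(self, rng):
        S = rng.laplace(size=(4, 60000))
        A = rng.standard_normal((4, 4))
        gs = run_ica(A @ S, n_components=4, fs=1000.0, seed=1)
        ri, ci, sims = _align(A / np.linalg.norm(A, axis=0), gs.mixing)
        assert (sims >= 0.95).all()
        tc_r = [
            abs(np.corrcoef(S[i], gs.timecourses[j])[0, 1])
            for i, j in zip(ri, ci)
        ]
        assert min(tc_r) >= 0.9

    def test_gaussian_sources_warn_nonidentifiable(self, rng):
        S = rng.standard_normal((2, 20000))
        with pytest.warns(UserWarning, match="Gaussian"):
            run_ica(S, n_components=2, fs=1000.0, seed=2)

    def test_too_short_input_rejected(self, rng):
        with pytest.raises(ValueError, match="50x"):
            LaminarICA(n_components=4).fit(rng.standard_normal((100, 4)))

    def test_deterministic_given_seed(self, rng):
        X = rng.laplace(size=(3, 30000))
        a = run_ica(X, n_components=3, fs=1000.0, seed=5)
        b = run_ica(X, n_components=3, fs=1000.0, seed=5)
        assert np.array_equal(a.mixing, b.mixing)

    def test_channel_permutation_invariance(self, rng):
        # relabelling channels permutes profile rows but nothing else
        S = rng.laplace(size=(3, 30000))
        A = rng.standard_normal((6, 3))
        perm = rng.permutation(6)
        a = run_ica(A @ S, n_components=3, fs=1000.0, seed=3)
        b = run_ica((A @ S)[perm], n_components=3, fs=1000.0, seed=3)
        _, _, sims = _align(a.mixing[perm], b.mixing)
        assert (sims >= 0.999).all()

    def test_canonical_form(self, rng):
        S = rng.laplace(size=(3, 30000))
        gs = run_ica(rng.standard_normal((8, 3)) @ S, n_components=3,
                     fs=1000.0, seed=4)
        norms = np.linalg.norm(gs.mixing, axis=0)
        assert np.allclose(norms, 1.0)
        peaks = gs.mixing[np.argmax(np.abs(gs.mixing), axis=0), np.arange(3)]
        assert (peaks > 0).all()
        assert (np.diff(gs.variance_fraction) <= 1e-12).all()

    def test_reconstruction_bound(self, rng):
        S = rng.laplace(size=(3, 30000))
        data = rng.standard_normal((8, 3)) @ S + 0.01 * rng.standard_normal((8, 30000))
        gs = run_ica(data, n_components=3, fs=1000.0, seed=6)
        resid = data - gs.reconstruct()
        lhs = np.sum(resid**2) / np.sum((data - data.mean(1, keepdims=True))**2)
        assert lhs <= 1 - gs.variance_fraction.sum() + 0.01


class TestVarianceFilter:
    def test_single_source_has_fraction_one(self, rng):
        s = rng.laplace(size=(1, 20000))
        V = np.ones((4, 1)) / 2.0
        gs = GeneratorSet(mixing=V, timecourses=s, fs=1000.0,
                          variance_fraction=np.array([0.0]))
        out = relative_variance_filter(gs, V @ s)
        assert out.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_equal_orthogonal_sources_split_half(self, rng):
        s = rng.standard_normal((2, 20000))
        V = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        gs = GeneratorSet(mixing=V, timecourses=s, fs=1000.0,
                          variance_fraction=np.zeros(2))
        out = relative_variance_filter(gs, V @ s)
        assert np.allclose(out.variance_fraction, 0.5, atol=0.02)

    def test_weak_source_removed_at_one_percent(self, rng):
        s = np.vstack([rng.standard_normal(20000),
                       np.sqrt(0.005) * rng.standard_normal(20000)])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        gs = GeneratorSet(mixing=V, timecourses=s, fs=1000.0,
                          variance_fraction=np.zeros(2))
        out = relative_variance_filter(gs, V @ s, min_fraction=0.01)
        assert out.n_generators == 1


class TestMatchProfiles:
    def test_identical_sets_fully_matched(self, rng):
        P = rng.standard_normal((16, 3))
        m = match_profiles(P, P)
        assert len(m.pairs) == 3
        assert all(d == pytest.approx(0.0, abs=1e-12) for _, _, d in m.pairs)

    def test_correlation_085_matches_at_distance_015(self):
        a = np.sin(np.linspace(0, np.pi, 32))
        rng = np.random.default_rng(3)
        # add noise until correlation is ~0.85
        for scale in np.linspace(0, 1.0, 201):
            b = a + scale * rng.standard_normal(32)
            if np.corrcoef(a, b)[0, 1] < 0.851:
                break
        m = match_profiles(a[:, None], b[:, None])
        assert len(m.pairs) == 1
        assert m.pairs[0][2] == pytest.approx(1 - np.corrcoef(a, b)[0, 1],
                                              abs=1e-12)
        assert m.pairs[0][2] < 0.2

    def test_orthogonal_profiles_unmatched(self):
        m = np.arange(32)
        a = np.sin(2 * np.pi * m / 32)
        b = np.cos(2 * np.pi * m / 32)
        res = match_profiles(a[:, None], b[:, None])
        assert res.pairs == []
        assert res.unmatched_a == [0] and res.unmatched_b == [0]


class TestEpochStability:
    def test_identical_signals_stable_at_first_step(self, rng):
        x = rng.standard_normal(60000)
        res = epoch_stability_length(x, x, fs=1000.0, step=5.0)
        assert res.converged and res.length_s == 5.0
        assert np.allclose(res.cc, 1.0)

    def test_stationary_coupled_pair_converges(self, rng):
        n = 120000
        c = rng.standard_normal(n)
        x = np.sqrt(0.7) * c + np.sqrt(0.3) * rng.standard_normal(n)
        y = np.sqrt(0.7) * c + np.sqrt(0.3) * rng.standard_normal(n)
        res = epoch_stability_length(x, y, fs=1000.0, step=5.0)
        assert res.converged
        long_run = np.corrcoef(x, y)[0, 1]
        i = np.argmin(np.abs(res.lengths_s - res.length_s))
        assert abs(res.cc[i] - long_run) <= 0.03 * abs(long_run)

    def test_coupling_switch_detected(self, rng):
        n = 120000
        c = rng.standard_normal(n)
        x = 0.9 * c + 0.45 * rng.standard_normal(n)
        y = x.copy()
        y[n // 2:] = rng.standard_normal(n // 2)  # coupling off halfway
        res = epoch_stability_length(x, y, fs=1000.0, step=5.0)
        assert (not res.converged) or res.length_s > 60.0


class TestSerialization:
    def test_generator_set_hdf5_round_trip(self, tmp_path, rng):
        from laminarfp.separation import load_generator_set, save_generator_set

        gs = run_ica(rng.laplace(size=(3, 30000)), n_components=3,
                     fs=1000.0, seed=0)
        gs.labels = ["a", "b", "c"]
        path = tmp_path / "gs.h5"
        save_generator_set(gs, path)
        back = load_generator_set(path)
        assert np.array_equal(back.mixing, gs.mixing)
        assert np.array_equal(back.timecourses, gs.timecourses)
        assert back.labels == gs.labels
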