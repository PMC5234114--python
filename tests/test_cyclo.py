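import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from osasev import (
    ActivationMatrix,
    AudioSignal,
    RunningCSDMean,
    ValidationError,
    cyclic_spectral_density,
    fit_shared_basis,
    load_basis,
    otsu_mask,
    project_activations,
    save_basis,
    subject_running_mean,
    summarize_statistics,
    update_running_mean,
)
from osasev.config import CsdConfig
from osasev.cyclo import nmf_decompose

RATE = 8000


def _grid(mat):
    mat = np.asarray(mat, dtype=float)
    from osasev import CSDGrid

    return CSDGrid(
        magnitudes=mat,
        f_grid=np.arange(mat.shape[0], dtype=float),
        alpha_grid=np.arange(mat.shape[1], dtype=float),
    )


class TestCyclicSpectralDensity:
    def test_zero_window_gives_zero_grid(self):
        g = cyclic_spectral_density(AudioSignal(np.zeros(RATE * 60), RATE))
        assert g.magnitudes.shape == (54, 889)
        assert np.all(g.magnitudes == 0)

    def test_stationary_noise_has_no_cyclic_mass(self):
        # mean magnitude off the alpha=0 column stays far below the column itself
        ratios = []
        for seed in range(3):
            x = 0.1 * np.random.default_rng(seed).standard_normal(RATE * 60)
            g = cyclic_spectral_density(AudioSignal(x, RATE))
            a0 = g.magnitudes[:, g.alpha_grid == 0].mean()
            ratios.append(g.magnitudes[:, g.alpha_grid != 0].mean() / a0)
        assert np.mean(ratios) <= 0.1

    def test_am_noise_peaks_at_modulation_rate(self):
        t = np.arange(RATE * 60) / RATE
        rng = np.random.default_rng(5)
        x = (1 + np.cos(2 * np.pi * t / 4.0)) * rng.standard_normal(len(t))
        g = cyclic_spectral_density(AudioSignal(x / np.abs(x).max(), RATE))
        marginal = g.magnitudes.sum(axis=0)
        pos = g.alpha_grid > 0
        peak_alpha = g.alpha_grid[pos][np.argmax(marginal[pos])]
        nearest_bin = g.alpha_grid[pos][np.argmin(np.abs(g.alpha_grid[pos] - 0.25))]
        assert peak_alpha == pytest.approx(nearest_bin)

    def test_time_reversal_leaves_magnitudes_unchanged(self):
        # |S| of a real signal is reversal-invariant; the discrete estimator
        # realigns its averaging blocks under reversal, so agreement is close
        # but not bitwise — compare at the estimator's own resolution
        rng = np.random.default_rng(6)
        t = np.arange(RATE * 60) / RATE
        x = (1 + 0.8 * np.cos(2 * np.pi * t / 3.0)) * rng.standard_normal(len(t)) * 0.2
        g_fwd = cyclic_spectral_density(AudioSignal(x, RATE))
        g_rev = cyclic_spectral_density(AudioSignal(x[::-1].copy(), RATE))
        m_f, m_r = g_fwd.magnitudes, g_rev.magnitudes
        # stationary-power column agrees closely
        a0 = g_fwd.alpha_grid == 0
        np.testing.assert_allclose(m_f[:, a0], m_r[:, a0], rtol=0.02)
        # the cyclic peak sits in the same alpha bin
        pos = g_fwd.alpha_grid > 0
        marg_f, marg_r = m_f[:, pos].sum(axis=0), m_r[:, pos].sum(axis=0)
        assert np.argmax(marg_f) == np.argmax(marg_r)
        # overall structure matches up to the noise floor re-randomizing
        assert np.corrcoef(m_f.ravel(), m_r.ravel())[0, 1] >= 0.95

    def test_window_too_short_rejected(self):
        with pytest.raises(ValidationError):
            cyclic_spectral_density(AudioSignal(np.zeros(500), RATE))

    def test_custom_grid_shape(self):
        cfg = CsdConfig(window_s=10.0, n_f=20, n_alpha=100)
        g = cyclic_spectral_density(AudioSignal(np.zeros(RATE * 10), RATE), cfg)
        assert g.magnitudes.shape == (20, 100)


class TestRunningMean:
    def test_first_window(self):
        state = RunningCSDMean(rms=np.zeros(0), k=0)
        out = update_running_mean(state, _grid(np.full((3, 4), 2.0)))
        assert out.k == 1
        np.testing.assert_array_equal(out.rms, np.full((3, 4), 2.0))

    def test_constant_fixed_point(self):
        state = RunningCSDMean(rms=np.zeros(0), k=0)
        g = _grid(np.full((2, 2), 5.0))
        for _ in range(4):
            state = update_running_mean(state, g)
        np.testing.assert_allclose(state.rms, 5.0)

    def test_two_window_arithmetic(self):
        state = RunningCSDMean(rms=np.zeros(0), k=0)
        state = update_running_mean(state, _grid(np.zeros((2, 2))))
        state = update_running_mean(state, _grid(np.full((2, 2), 2.0)))
        np.testing.assert_allclose(state.rms, 1.0)

    def test_shape_mismatch_rejected(self):
        state = update_running_mean(RunningCSDMean(rms=np.zeros(0), k=0), _grid(np.ones((2, 2))))
        with pytest.raises(ValidationError):
            update_running_mean(state, _grid(np.ones((3, 3))))

    @given(
        arrays(np.float64, (5, 3, 4), elements=st.floats(0, 1e3, allow_nan=False))
    )
    @settings(max_examples=50, deadline=None)
    def test_running_equals_batch_mean(self, grids):
        state = RunningCSDMean(rms=np.zeros(0), k=0)
        for g in grids:
            state = update_running_mean(state, _grid(g))
        np.testing.assert_allclose(state.rms, grids.mean(axis=0), atol=1e-10)


class TestOtsuMask:
    def test_two_valued_matrix(self):
        m = np.zeros((30, 30))
        m.flat[:100] = 10.0
        res = otsu_mask(m)
        assert 0 < res.threshold <= 10
        assert (res.masked == 10).sum() == 100
        assert not res.degenerate

    def test_constant_matrix_degenerate(self):
        m = np.full((5, 5), 3.0)
        res = otsu_mask(m)
        assert res.degenerate
        np.testing.assert_array_equal(res.masked, m)

    def test_bimodal_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(1, 0.5, 800), rng.normal(8, 0.5, 200)]
        res = otsu_mask(np.abs(vals).reshape(40, 25))
        assert 1 < res.threshold < 8

    def test_is_a_between_class_variance_maximizer(self):
        # the objective can plateau across empty bins, so assert the returned
        # threshold achieves the exhaustive-search maximum exactly
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals = np.abs(np.r_[rng.normal(1, 1, 500), rng.normal(10, 2, 300)])
            res = otsu_mask(vals.reshape(40, 20))
            counts, edges = np.histogram(vals, bins=256)
            centers = (edges[:-1] + edges[1:]) / 2
            total = counts.sum()

            def variance_at(split):
                w0, w1 = counts[:split].sum(), counts[split:].sum()
                if w0 == 0 or w1 == 0:
                    return -np.inf
                m0 = (counts[:split] * centers[:split]).sum() / w0
                m1 = (counts[split:] * centers[split:]).sum() / w1
                return (w0 / total) * (w1 / total) * (m0 - m1) ** 2

            best = max(variance_at(s) for s in range(1, 256))
            split = int(np.clip(np.searchsorted(edges, res.threshold), 1, 255))
            assert variance_at(split) == pytest.approx(best, rel=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            otsu_mask(np.array([[-1.0, 2.0]]))


class TestNMF:
    def test_rank5_product_recovery(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0, 1, (40, 30 * 3))
        W0 = rng.uniform(0, 1, (40, 5))
        H0 = rng.uniform(0, 1, (5, 90))
        V = W0 @ H0
        basis = fit_shared_basis(
            [V[:, :30].T, V[:, 30:60].T, V[:, 60:].T],
            rank=5, seed=1, max_iter=3000, tol=1e-9,
        )
        assert basis.fit_residual <= 1e-2

    def test_rank1_outer_product_exact(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(0.1, 1, 20)
        v = rng.uniform(0.1, 1, 15)
        _, _, objs = nmf_decompose(np.outer(u, v), rank=1, seed=0, max_iter=2000, tol=0)
        assert objs[-1] / np.linalg.norm(np.outer(u, v)) <= 1e-6

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 1, (25, 18))
        _, _, objs = nmf_decompose(V, rank=4, seed=3, max_iter=100, tol=0)
        diffs = np.diff(objs)
        assert np.all(diffs <= 1e-10)

    def test_factors_nonnegative_and_reproducible(self):
        rng = np.random.default_rng(3)
        V = rng.uniform(0, 1, (20, 12))
        W1, H1, _ = nmf_decompose(V, rank=3, seed=7)
        W2, H2, _ = nmf_decompose(V, rank=3, seed=7)
        assert np.all(W1 >= 0) and np.all(H1 >= 0)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_residual_comparable_to_sklearn(self):
        # independent cross-check: same objective, different implementation
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(4)
        V = rng.uniform(0, 1, (30, 20))
        _, _, objs = nmf_decompose(V, rank=5, seed=0, max_iter=500)
        sk = NMF(n_components=5, init="random", random_state=0, max_iter=500,
                 solver="mu", beta_loss="frobenius", tol=1e-6)
        sk_res = np.linalg.norm(V - sk.fit_transform(V) @ sk.components_)
        assert objs[-1] <= 1.1 * sk_res

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            nmf_decompose(np.array([[-1.0, 1.0]]), rank=1, seed=0)
        with pytest.raises(ValidationError):
            nmf_decompose(np.ones((3, 3)), rank=4, seed=0)


class TestProjection:
    def test_known_product_recovered(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(0.1, 1, (30, 4))
        H0 = rng.uniform(0.1, 1, (4, 12))
        V = W @ H0
        from osasev import NMFBasis

        basis = NMFBasis(W=W, rank=4, seed=0, fit_residual=0.0)
        H = project_activations(basis, V.T, max_iter=5000, tol=0).H
        assert np.linalg.norm(V - W @ H) / np.linalg.norm(V) <= 1e-2

    def test_zero_input_gives_zero_activations(self):
        from osasev import NMFBasis

        basis = NMFBasis(W=np.ones((10, 2)), rank=2, seed=0, fit_residual=0.0)
        H = project_activations(basis, np.zeros((5, 10))).H
        np.testing.assert_allclose(H, 0.0, atol=1e-8)

    def test_incompatible_grid_rejected(self):
        from osasev import NMFBasis

        basis = NMFBasis(W=np.ones((10, 2)), rank=2, seed=0, fit_residual=0.0)
        with pytest.raises(ValidationError):
            project_activations(basis, np.zeros((5, 11)))


class TestSummaryStatistics:
    def test_693_features_from_45x54(self):
        rng = np.random.default_rng(6)
        feats = summarize_statistics(ActivationMatrix(H=rng.uniform(0, 1, (45, 54))))
        assert len(feats) == 693
        assert len(set(feats)) == 693

    def test_constant_matrix_degenerate_convention(self):
        feats = summarize_statistics(ActivationMatrix(H=np.full((45, 54), 3.0)))
        assert feats["c_alpha_f_max_1"] == 3.0
        assert feats["c_alpha_f_min_1"] == 3.0
        assert feats["c_alpha_f_median_1"] == 3.0
        assert feats["c_alpha_f_std_1"] == 0.0
        assert feats["c_f_alpha_var_10"] == 0.0
        assert feats["c_alpha_f_kurtosis_2"] == 0.0
        assert feats["c_f_alpha_skewness_3"] == 0.0

    def test_row_statistics_match_textbook_formulas(self):
        H = np.zeros((45, 54))
        x = np.arange(1.0, 55.0)
        H[0, :] = x
        feats = summarize_statistics(ActivationMatrix(H=np.abs(H)))
        n = len(x)
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        assert feats["c_alpha_f_max_1"] == 54.0
        assert feats["c_alpha_f_min_1"] == 1.0
        assert feats["c_alpha_f_median_1"] == pytest.approx(np.median(x))
        assert feats["c_alpha_f_std_1"] == pytest.approx(
            np.sqrt(((x - m) ** 2).sum() / (n - 1))
        )
        assert feats["c_alpha_f_var_1"] == pytest.approx(((x - m) ** 2).sum() / (n - 1))
        assert feats["c_alpha_f_skewness_1"] == pytest.approx(m3 / m2**1.5)
        assert feats["c_alpha_f_kurtosis_1"] == pytest.approx(m4 / m2**2)

    def test_optional_mean_statistic(self):
        rng = np.random.default_rng(7)
        feats = summarize_statistics(
            ActivationMatrix(H=rng.uniform(0, 1, (45, 54))), include_mean=True
        )
        assert len(feats) == (45 + 54) * 8
        assert "c_alpha_f_mean_1" in feats


class TestBasisPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        V = rng.uniform(0, 1, (20, 10))
        basis = fit_shared_basis([V.T], rank=3, seed=11)
        path = tmp_path / "basis.txt"
        save_basis(path, basis)
        back = load_basis(path)
        np.testing.assert_allclose(back.W, basis.W)
        assert back.rank == 3 and back.seed == 11
        assert back.fit_residual == pytest.approx(basis.fit_residual)


class TestPipelineDeterminism:
    def test_same_audio_same_seed_identical_features(self):
        rng = np.random.default_rng(9)
        t = np.arange(RATE * 120) / RATE
        x = (1 + np.cos(2 * np.pi * t / 4.0)) * rng.standard_normal(len(t)) * 0.1
        sig = AudioSignal(np.clip(x, -1, 1), RATE)

        def run():
            rms = subject_running_mean(sig)
            masked = otsu_mask(rms.rms).masked
            basis = fit_shared_basis([masked], rank=5, seed=3)
            H = project_activations(basis, masked)
            return summarize_statistics(H)

        f1, f2 = run(), run()
        assert list(f1) == list(f2)
        np.testing.assert_array_equal(
            np.array(list(f1.values())), np.array(list(f2.values()))
        )
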