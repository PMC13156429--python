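"""Masking, stepwise fit, and fit-quality metric."""

import numpy as np
import pytest
from scipy import ndimage

from mcdip.core_model import BValueScheme, GradientScheme, biexp_signal
from mcdip.ivim import (
    FitConfig,
    MaskError,
    brain_volume,
    compute_nrmse,
    fit_diffusion_step,
    fit_ivim_map,
    fit_perfusion_step,
    make_brain_mask,
)
from mcdip.phantom import synthesize_dwi


def grid_search_perfusion(signal, b, d_fixed, n_f=201, n_ds=201):
    """Brute-force oracle: dense (f, d_star) grid with closed-form S0.

    For each grid point the model is linear in S0, so the optimal S0 has a
    closed form; the best grid cell approximates the global optimum.
    """
    f_grid = np.linspace(0.0, 1.0, n_f)
    ds_grid = np.geomspace(max(d_fixed, 1e-4), 0.5, n_ds)
    e_d = np.exp(-b * d_fixed)
    best = (np.inf, None)
    for ds in ds_grid:
        e_star = np.exp(-b * ds)
        # decay shapes for all f at once: (n_f, n_b)
        shapes = f_grid[:, None] * e_star[None, :] + (1 - f_grid[:, None]) * e_d[None, :]
        s0 = (shapes * signal[None, :]).sum(axis=1) / (shapes**2).sum(axis=1)
        sse = ((s0[:, None] * shapes - signal[None, :]) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (sse[i], (s0[i], f_grid[i], ds))
    return best


class TestMakeBrainMask:
    def test_recovers_phantom_support(self, small_truth, scheme_2nd):
        dwi = synthesize_dwi(small_truth, scheme_2nd, noise_sigma=0.0, seed=0)
        mask = make_brain_mask(dwi.b0)
        np.testing.assert_array_equal(mask, small_truth.brain_mask)

    def test_all_zero_volume_errors(self):
        with pytest.raises(MaskError):
            make_brain_mask(np.zeros((8, 8, 8)))

    def test_largest_component_kept(self):
        # brute-force connected-component oracle on a toy grid: two blobs,
        # the bigger must survive
        vol = np.zeros((10, 10, 10))
        vol[1:5, 1:5, 1:5] = 100.0  # 64 voxels
        vol[7:9, 7:9, 7:9] = 100.0  # 8 voxels
        mask = make_brain_mask(vol)
        labels, n = ndimage.label(vol > 0)
        sizes = [(labels == i).sum() for i in range(1, n + 1)]
        expected = labels == (int(np.argmax(sizes)) + 1)
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 64


class TestBrainVolume:
    def test_voxel_count_times_volume(self):
        mask = np.zeros((20, 20, 10), dtype=bool)
        mask.flat[:1000] = True
        assert brain_volume(mask, (2.0, 2.0, 6.0)) == pytest.approx(24.0)

    def test_empty_mask(self):
        assert brain_volume(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)) == 0.0

    def test_phantom_volume_matches_truth(self, small_truth):
        assert brain_volume(
            small_truth.brain_mask, small_truth.voxel_dims
        ) == pytest.approx(small_truth.brain_volume_ml, rel=1e-12)


class TestDiffusionStep:
    def test_exact_on_monoexponential(self, scheme_2nd):
        b = scheme_2nd.b_array
        signal = 120.0 * np.exp(-b * 0.8e-3)
        d, s0_high = fit_diffusion_step(signal, scheme_2nd)
        assert d == pytest.approx(0.8e-3, rel=1e-10)
        assert s0_high == pytest.approx(120.0, rel=1e-10)

    def test_constant_signal_clamps_to_lower_bound(self, scheme_2nd):
        signal = np.full(scheme_2nd.n_b, 50.0)
        d, _ = fit_diffusion_step(signal, scheme_2nd)
        assert d == FitConfig().d_bounds[0]

    def test_biexponential_bias_within_five_percent(self, scheme_2nd):
        # residual perfusion at b >= 200 biases the one-pass D slightly high
        b = scheme_2nd.b_array
        signal = biexp_signal(100.0, 0.1, 10e-3, 0.8e-3, b)
        d, _ = fit_diffusion_step(signal, scheme_2nd)
        assert d > 0.8e-3
        assert d == pytest.approx(0.8e-3, rel=0.05)

    def test_nonpositive_signal_rejected(self, scheme_2nd):
        signal = np.full(scheme_2nd.n_b, 10.0)
        signal[-1] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_diffusion_step(signal, scheme_2nd)


class TestPerfusionStep:
    def test_noise_free_recovery_with_true_d(self, scheme_2nd):
        b = scheme_2nd.b_array
        truth = (150.0, 0.13, 12e-3, 0.75e-3)
        signal = biexp_signal(*truth, b)
        s0, f, d_star, q = fit_perfusion_step(signal, scheme_2nd, truth[3])
        assert q.converged
        assert s0 == pytest.approx(truth[0], rel=1e-6)
        assert f == pytest.approx(truth[1], rel=1e-6)
        assert d_star == pytest.approx(truth[2], rel=1e-6)
        assert q.nrmse == pytest.approx(0.0, abs=1e-9)

    def test_zero_perfusion_lands_on_bound(self, scheme_2nd):
        b = scheme_2nd.b_array
        signal = 90.0 * np.exp(-b * 0.9e-3)
        s0, f, d_star, q = fit_perfusion_step(signal, scheme_2nd, 0.9e-3)
        assert q.converged
        assert f == pytest.approx(0.0, abs=1e-8)
        assert f * d_star == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle_on_random_draws(self, scheme_2nd):
        # bounded trust-region solution equals the brute-force global
        # optimum on noise-free curves
        rng = np.random.default_rng(2024)
        b = scheme_2nd.b_array
        for _ in range(100):
            s0_t = rng.uniform(50, 200)
            f_t = rng.uniform(0.02, 0.3)
            ds_t = rng.uniform(4e-3, 40e-3)
            d_t = rng.uniform(0.4e-3, 1.5e-3)
            signal = biexp_signal(s0_t, f_t, ds_t, d_t, b)
            s0, f, d_star, q = fit_perfusion_step(signal, scheme_2nd, d_t)
            assert q.converged
            sse_fit = float(
                ((s0 * (f * np.exp(-b * d_star) + (1 - f) * np.exp(-b * d_t)) - signal) ** 2).sum()
            )
            sse_oracle, _ = grid_search_perfusion(signal, b, d_t, n_f=101, n_ds=101)
            assert sse_fit <= sse_oracle + 1e-12
            assert f == pytest.approx(f_t, rel=1e-5)
            assert d_star == pytest.approx(ds_t, rel=1e-5)

    def test_motion_attenuated_curve_inflates_fd_star(self, scheme_non):
        # uncompensated bulk motion adds exp(-b*g^2/2) decay which the fit
        # absorbs as extra pseudo-diffusion: FD* comes out above truth
        b = scheme_non.b_array
        truth = (100.0, 0.08, 10e-3, 0.7e-3)
        g = 0.06
        signal = biexp_signal(*truth, b) * np.exp(-b * g**2 / 2.0)
        d_est, _ = fit_diffusion_step(signal, scheme_non)
        s0, f, d_star, q = fit_perfusion_step(signal, scheme_non, d_est)
        assert q.converged
        assert f * d_star > truth[1] * truth[2]


class TestNRMSE:
    def test_perfect_fit_is_zero(self):
        x = np.array([5.0, 4.0, 3.0])
        assert compute_nrmse(x, x) == 0.0

    def test_direct_value(self):
        observed = np.full(4, 10.0)
        fitted = observed - 1.0
        assert compute_nrmse(observed, fitted) == pytest.approx(0.1)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.uniform(5, 50, 11)
        fit = obs + rng.normal(0, 1, 11)
        a = compute_nrmse(obs, fit)
        b = compute_nrmse(7.3 * obs, 7.3 * fit)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            compute_nrmse(np.zeros(3), np.zeros(3))


class TestFitIVIMMap:
    def test_empty_mask_returns_empty_map(self, small_truth, scheme_2nd, caplog):
        dwi = synthesize_dwi(small_truth, scheme_2nd, noise_sigma=0.0, seed=0)
        mask = np.zeros(small_truth.shape, dtype=bool)
        with caplog.at_level("WARNING"):
            params = fit_ivim_map(dwi, mask)
        assert params.mask.sum() == 0
        assert np.all(np.isnan(params.f))

    def test_noise_free_recovery_on_phantom(self, medium_truth, scheme_2nd):
        dwi = synthesize_dwi(medium_truth, scheme_2nd, noise_sigma=0.0, seed=0)
        mask = make_brain_mask(dwi.b0)
        params = fit_ivim_map(dwi, mask)
        ok = params.valid_mask
        assert ok.sum() >= 0.99 * mask.sum()
        for est, tru in (
            (params.d, medium_truth.true_d),
            (params.f, medium_truth.true_f),
            (params.d_star, medium_truth.true_d_star),
            (params.fd_star, medium_truth.true_fd_star),
        ):
            rel = np.abs(est[ok] - tru[ok]) / tru[ok]
            assert np.mean(rel < 0.01) >= 0.99

    def test_monoexponential_field_gives_zero_f(self, scheme_2nd):
        shape = (6, 6, 4)
        b = scheme_2nd.b_array
        signal = np.broadcast_to(
            80.0 * np.exp(-b * 1.0e-3), shape + (b.size,)
        ).copy()
        from mcdip.core_model import DWISeries

        dwi = DWISeries(signal=signal, scheme=scheme_2nd)
        params = fit_ivim_map(dwi, np.ones(shape, dtype=bool))
        ok = params.valid_mask
        assert np.all(params.f[ok] < 1e-6)
        np.testing.assert_allclose(params.d[ok], 1.0e-3, rtol=1e-6)

    def test_denoise_hook_shape_guard(self, small_truth, scheme_2nd):
        dwi = synthesize_dwi(small_truth, scheme_2nd, noise_sigma=0.0, seed=0)
        with pytest.raises(ValueError, match="shape"):
            fit_ivim_map(dwi, small_truth.brain_mask, denoise_hook=lambda s: s[..., :3])
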