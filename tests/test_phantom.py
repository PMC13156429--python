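"""Synthetic-data generator: determinism, motion model, construction inverses."""

import numpy as np
import pytest

from mcdip.asl import asl_rcbf, asl_scale_factor
from mcdip.core_model import ASLParams, BValueScheme, GradientScheme, VesselLabel
from mcdip.dip_calibration import SegmentationError, segment_lumen, vessel_flow
from mcdip.phantom import (
    MotionModel,
    PhantomConfig,
    make_phantom,
    motion_attenuation,
    synthesize_asl,
    synthesize_dwi,
    synthesize_pc,
)


class TestMakePhantom:
    def test_seeded_determinism(self):
        a = make_phantom((12, 12, 8), seed=5)
        b = make_phantom((12, 12, 8), seed=5)
        np.testing.assert_array_equal(a.true_f, b.true_f)
        np.testing.assert_array_equal(a.true_rcbf.values, b.true_rcbf.values)
        np.testing.assert_array_equal(a.motion.sigma_a, b.motion.sigma_a)
        assert a.vessel_true_flows == b.vessel_true_flows

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            make_phantom((4, 12, 8), seed=0)

    def test_brain_mean_rcbf_matches_configured_tcbf(self, small_truth):
        mean = small_truth.true_rcbf.values[small_truth.brain_mask].mean()
        assert mean == pytest.approx(small_truth.config.tcbf_normalized, rel=1e-9)

    def test_uniform_tissue_degenerate_case(self):
        cfg = PhantomConfig(uniform_tissue="gm", texture_rel_sd=0.0)
        t = make_phantom((12, 12, 8), seed=0, config=cfg)
        inside = t.brain_mask
        assert np.all(t.tissue_probs["gm"][inside] == 1.0)
        assert np.unique(t.true_f[inside]).size == 1
        assert np.unique(t.true_d[inside]).size == 1

    def test_tissue_ordering_and_positivity(self, small_truth):
        t = small_truth
        gm = t.tissue_probs["gm"] >= 0.9
        wm = t.tissue_probs["wm"] >= 0.9
        assert t.true_f[gm].mean() > t.true_f[wm].mean() > 0
        inside = t.brain_mask
        assert np.all(t.true_d[inside] > 0)
        assert np.all(t.true_d_star[inside] >= 2 * t.true_d[inside] - 1e-15)

    def test_vessel_flows_sum_to_tcbf(self, small_truth):
        total = sum(small_truth.vessel_true_flows.values())
        assert total == pytest.approx(small_truth.tcbf_ml_min, rel=1e-12)


class TestMotionAttenuation:
    def _model(self, sv=0.3, sa=2.0):
        return MotionModel(
            sigma_v=np.array([sv]), sigma_a=np.array([sa]), c1=0.1, c2=0.03
        )

    def test_second_order_weights_give_unity(self):
        assert motion_attenuation(800.0, self._model(), (0.0, 0.0)) == pytest.approx(1.0)

    def test_b0_gives_unity(self):
        assert motion_attenuation(0.0, self._model(), (1.0, 1.0)) == pytest.approx(1.0)

    def test_stated_formula_value(self):
        # sigma_phi = sqrt(100) * (c1*sigma_v + c2*sigma_a) arranged to be 0.5
        model = MotionModel(
            sigma_v=np.array([0.2]), sigma_a=np.array([1.0]), c1=0.1, c2=0.03
        )
        # sqrt(100)*(0.02+0.03) = 0.5 -> exp(-0.125)
        out = motion_attenuation(100.0, model, (1.0, 1.0))
        assert out[0] == pytest.approx(np.exp(-0.125), rel=1e-12)
        assert out[0] == pytest.approx(0.8825, abs=5e-4)

    def test_factor_in_unit_interval(self):
        model = self._model(sv=3.0, sa=30.0)
        for b in (0.0, 10.0, 1000.0):
            out = motion_attenuation(b, model, (1.0, 1.0))
            assert 0.0 < out[0] <= 1.0

    def test_monotone_in_dispersions_for_non_mc(self):
        weak = self._model(sv=0.1, sa=1.0)
        strong = self._model(sv=0.4, sa=3.0)
        assert motion_attenuation(500.0, strong, (1, 1))[0] < motion_attenuation(
            500.0, weak, (1, 1)
        )[0]


class TestSynthesizeDWI:
    def test_noise_free_second_order_equals_forward_model(self, small_truth, scheme_2nd):
        t = small_truth
        dwi = synthesize_dwi(t, scheme_2nd, noise_sigma=0.0, seed=0)
        b = scheme_2nd.b_array
        inside = t.brain_mask
        expected = t.true_s0[inside, None] * (
            t.true_f[inside, None] * np.exp(-b[None, :] * t.true_d_star[inside, None])
            + (1 - t.true_f[inside, None]) * np.exp(-b[None, :] * t.true_d[inside, None])
        )
        np.testing.assert_allclose(dwi.signal[inside], expected, rtol=1e-12)

    def test_motion_only_attenuates(self, small_truth, scheme_2nd, scheme_non):
        clean = synthesize_dwi(small_truth, scheme_2nd, noise_sigma=0.0, seed=0)
        moved = synthesize_dwi(small_truth, scheme_non, noise_sigma=0.0, seed=0)
        inside = small_truth.brain_mask
        assert np.all(moved.signal[inside] <= clean.signal[inside] + 1e-12)
        # strictly attenuated somewhere at b > 0
        assert np.any(moved.signal[inside][:, 1:] < clean.signal[inside][:, 1:])

    def test_scheme_ordering_of_total_deviation(self, small_truth):
        t = small_truth
        ref = synthesize_dwi(
            t, BValueScheme(scheme=GradientScheme.SECOND_ORDER_MC), 0.0, seed=0
        )
        dev = {}
        for scheme in GradientScheme:
            s = synthesize_dwi(t, BValueScheme(scheme=scheme), 0.0, seed=0)
            dev[scheme] = ((s.signal - ref.signal) ** 2).sum()
        assert dev[GradientScheme.SECOND_ORDER_MC] == 0.0
        assert dev[GradientScheme.NON_MC] > dev[GradientScheme.FIRST_ORDER_MC] > 0.0

    def test_seeded_determinism_with_noise(self, small_truth, scheme_2nd):
        a = synthesize_dwi(small_truth, scheme_2nd, noise_sigma=2.0, seed=9)
        b = synthesize_dwi(small_truth, scheme_2nd, noise_sigma=2.0, seed=9)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_rayleigh_floor_at_zero_signal(self, scheme_2nd):
        # outside the head the clean signal is 0; the magnitude mean must
        # approach the Rayleigh limit sigma*sqrt(pi/2)
        t = make_phantom((16, 16, 10), seed=3)
        sigma = 4.0
        dwi = synthesize_dwi(t, scheme_2nd, noise_sigma=sigma, nsa=1, seed=11)
        background = dwi.signal[~t.brain_mask]
        assert background.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)


class TestSynthesizePC:
    def test_noise_free_flow_roundtrip(self, small_truth):
        planes = synthesize_pc(small_truth, noise_sigma_v=0.0, seed=0)
        assert len(planes) == 4
        for plane in planes:
            roi = segment_lumen(plane.cine, plane.seed_point, vessel_label=plane.label)
            np.testing.assert_array_equal(roi.mask, plane.lumen_mask)
            q = vessel_flow(plane.cine, roi)
            assert q == pytest.approx(
                small_truth.vessel_true_flows[plane.label], rel=1e-9
            )

    def test_cycle_mean_independent_of_phase_count(self, small_truth):
        for n_phases in (4, 32):
            planes = synthesize_pc(small_truth, n_phases=n_phases, noise_sigma_v=0.0, seed=0)
            for plane in planes:
                roi = segment_lumen(plane.cine, plane.seed_point, vessel_label=plane.label)
                q = vessel_flow(plane.cine, roi)
                assert q == pytest.approx(
                    small_truth.vessel_true_flows[plane.label], rel=1e-9
                )

    def test_zero_pulsatility_breaks_segmentation(self):
        cfg = PhantomConfig(pulsatility=0.0)
        t = make_phantom((16, 16, 10), seed=0, config=cfg)
        planes = synthesize_pc(t, noise_sigma_v=0.0, seed=0)
        with pytest.raises(SegmentationError, match="pulsatility"):
            segment_lumen(planes[0].cine, planes[0].seed_point)

    def test_minimum_phase_count(self, small_truth):
        with pytest.raises(ValueError, match="n_phases"):
            synthesize_pc(small_truth, n_phases=2)

    def test_ica_velocity_near_physiologic_target(self, small_truth):
        planes = synthesize_pc(small_truth, noise_sigma_v=0.0, seed=0)
        ica = next(p for p in planes if p.label is VesselLabel.L_ICA)
        v_mean = ica.cine.velocity[ica.lumen_mask, :].mean()
        assert v_mean == pytest.approx(small_truth.config.ica_velocity_target, rel=0.05)


class TestSynthesizeASL:
    def test_noise_free_roundtrip(self, small_truth):
        control, label, pd = synthesize_asl(small_truth, noise_sigma=0.0, seed=0)
        rcbf = asl_rcbf(control, label, pd, mask=small_truth.brain_mask)
        inside = small_truth.brain_mask
        np.testing.assert_allclose(
            rcbf.values[inside], small_truth.true_rcbf.values[inside], rtol=1e-9
        )

    def test_zero_rcbf_voxel_means_control_equals_label(self):
        cfg = PhantomConfig(texture_rel_sd=0.0)
        t = make_phantom((16, 16, 10), seed=0, config=cfg)
        t.true_rcbf.values[t.brain_mask] = 0.0
        control, label, _ = synthesize_asl(t, noise_sigma=0.0, seed=0)
        np.testing.assert_allclose(control, label, atol=1e-12)

    def test_encoded_scale_factor_value(self, small_truth):
        # a voxel with dM/PD = 0.01 at the default constants encodes
        # K * 0.01 = 73.05 mL/100 g/min
        params = ASLParams()
        k = asl_scale_factor(params)
        assert 0.01 * k == pytest.approx(73.05, abs=0.01)
        control, label, pd = synthesize_asl(small_truth, params, noise_sigma=0.0, seed=0)
        inside = small_truth.brain_mask
        dm_over_pd = (control[inside] - label[inside]) / pd[inside]
        np.testing.assert_allclose(
            dm_over_pd * k, small_truth.true_rcbf.values[inside], rtol=1e-9
        )
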