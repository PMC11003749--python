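"""Stabilization, dF/F, bandpass and flash-response extraction."""

import numpy as np
import pytest

from vsdmask import preprocess as pre
from vsdmask import synth

MM = 8.0 / 128.0


def _bg_stack(gt_maps, motion=synth.NO_MOTION, seed=7):
    stim = synth.StimulusSpec(background_contrast=0.12,
                              background_orientation=30.0)
    return synth.render_trial_stack(stim, gt_maps, noise=synth.NO_NOISE,
                                    motion=motion, seed=seed)


class TestMotion:
    def test_static_stack_zero_motion(self):
        frames = np.ones((10, 32, 32)) * 7.0
        mt = pre.estimate_motion(synth.ImageStack(frames, onset_index=5))
        np.testing.assert_allclose(mt.v, 0.0)
        np.testing.assert_allclose(mt.alpha, 0.0)

    def test_planted_motion_recovered(self, gt_maps):
        mo = synth.MotionSpec(amplitude_px=0.5, frequency_hz=3.0)
        moved = _bg_stack(gt_maps, motion=mo)
        mt = pre.estimate_motion(moved)
        v_true = mo.trace(moved.n_frames, moved.frame_rate)
        err = (mt.v - mt.v.mean(0)) - (v_true - v_true.mean(0))
        assert np.sqrt(np.mean(err ** 2)) < 0.1

    def test_stabilization_removes_artifact_variance(self, gt_maps):
        mo = synth.MotionSpec(amplitude_px=0.5, frequency_hz=3.0)
        clean = _bg_stack(gt_maps)
        moved = _bg_stack(gt_maps, motion=mo)
        mt = pre.estimate_motion(moved)
        stab = pre.stabilize(moved, mt)
        amag = np.hypot(*mt.alpha)
        sel = amag > np.percentile(amag, 90)
        v_in = (moved.frames[:, sel] - clean.frames[:, sel]).var(axis=0).mean()
        v_out = (stab.frames[:, sel] - clean.frames[:, sel]).var(axis=0).mean()
        assert v_out < 0.1 * v_in

    def test_second_pass_explains_little(self, gt_maps):
        mo = synth.MotionSpec(amplitude_px=0.5, frequency_hz=3.0)
        moved = _bg_stack(gt_maps, motion=mo)
        mt = pre.estimate_motion(moved)
        stab = pre.stabilize(moved, mt)
        mt2 = pre.estimate_motion(stab)
        vc1 = mt.v - mt.v.mean(0)
        vc2 = mt2.v - mt2.v.mean(0)
        fit1 = np.square(np.einsum("tc,chw->thw", vc1, mt.alpha)).sum()
        fit2 = np.square(np.einsum("tc,chw->thw", vc2, mt2.alpha)).sum()
        assert fit2 < 0.05 * fit1

    def test_stabilize_validates_geometry(self, gt_maps):
        moved = _bg_stack(gt_maps, motion=synth.MotionSpec(amplitude_px=0.3))
        mt = pre.estimate_motion(moved)
        other = synth.ImageStack(np.ones((moved.n_frames, 16, 16)),
                                 onset_index=5)
        with pytest.raises(ValueError):
            pre.stabilize(other, mt)

    def test_zero_motion_identity(self):
        frames = np.random.default_rng(0).random((8, 16, 16))
        stack = synth.ImageStack(frames, onset_index=4)
        mt = pre.MotionTrace(v=np.zeros((8, 2)), alpha=np.zeros((2, 16, 16)),
                             v_mean=np.zeros(2))
        out = pre.stabilize(stack, mt)
        np.testing.assert_array_equal(out.frames, frames)


class TestDeltaFOverF:
    def test_constant_stack_all_zero(self):
        stack = synth.ImageStack(np.full((40, 8, 8), 500.0), onset_index=20)
        out = pre.delta_f_over_f(stack)
        np.testing.assert_allclose(out.frames, 0.0)
        assert out.is_dff

    def test_step_response(self):
        frames = np.full((40, 8, 8), 100.0)
        frames[20:] *= 1.01
        out = pre.delta_f_over_f(synth.ImageStack(frames, onset_index=20))
        np.testing.assert_allclose(out.frames[:20], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.frames[20:], 0.01, atol=1e-12)

    def test_closed_loop_peak_amplitude(self):
        # envelope centered exactly on a pixel so the peak dF/F is g*C there
        maps = synth.make_ground_truth(grid_shape=(64, 64),
                                       mm_per_pixel=0.125,
                                       envelope_center=(32.0, 32.0), seed=2)
        g, c = 0.01, 0.24
        stack = synth.render_trial_stack(
            synth.StimulusSpec(target_contrast=c), maps,
            response_gain=g, columnar_gain=0.0, noise=synth.NO_NOISE, seed=0)
        dff = pre.delta_f_over_f(stack)
        assert dff.frames[:, 32, 32].max() == pytest.approx(g * c, abs=1e-12)

    def test_nonpositive_baseline_rejected(self):
        frames = np.full((40, 4, 4), 10.0)
        frames[:, 2, 2] = 0.0
        with pytest.raises(ValueError, match="non-positive baseline"):
            pre.delta_f_over_f(synth.ImageStack(frames, onset_index=20))

    def test_dff_invariant_under_stabilization_when_motion_free(self, gt_maps):
        stack = _bg_stack(gt_maps)
        direct = pre.delta_f_over_f(stack)
        mt = pre.estimate_motion(stack)
        routed = pre.delta_f_over_f(pre.stabilize(stack, mt))
        assert np.max(np.abs(direct.frames - routed.frames)) < 1e-10


class TestBandpass:
    def test_constant_field_removed(self):
        out = pre.bandpass_columnar(np.full((64, 64), 3.0), mm_per_pixel=MM)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("freq,lo,hi", [(1.5, 0.95, 1.0001),
                                            (0.25, 0.0, 0.05),
                                            (5.0, 0.0, 0.05)])
    def test_sinusoid_gains(self, freq, lo, hi):
        # frequencies chosen on FFT bins (resolution 0.125 cyc/mm at n=128)
        n = 128
        x = np.arange(n) * MM
        field = np.cos(2 * np.pi * freq * x)[None, :] * np.ones((n, 1))
        out = pre.bandpass_columnar(field, mm_per_pixel=MM)
        gain = np.abs(out).max() / np.abs(field).max()
        assert lo <= gain <= hi

    def test_idempotent_on_in_band_content_and_linear(self):
        rng = np.random.default_rng(3)
        f1 = rng.standard_normal((64, 64))
        f2 = rng.standard_normal((64, 64))
        bp = lambda f: pre.bandpass_columnar(f, mm_per_pixel=MM)
        # content strictly inside the passband (clear of the cosine edges)
        # passes unchanged, so repeated filtering is exactly idempotent
        inner = pre.bandpass_columnar(f1, low=1.0, high=2.8, mm_per_pixel=MM,
                                      edge_width=0.0)
        once, twice = bp(inner), bp(bp(inner))
        assert np.sqrt(np.mean((once - twice) ** 2)) < 1e-10
        np.testing.assert_allclose(bp(f1 + 2 * f2), bp(f1) + 2 * bp(f2),
                                   atol=1e-10)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            pre.bandpass_columnar(np.zeros((32, 32)), low=3.0, high=0.8,
                                  mm_per_pixel=MM)
        with pytest.raises(ValueError):
            pre.bandpass_columnar(np.zeros((32, 32)), low=0.8, high=5.0,
                                  mm_per_pixel=0.125)


class TestFlashResponse:
    def _sine_stack(self, amp=0.02, freq=5.0, phase=0.0):
        t = np.arange(120) / 100.0
        sig = amp * np.sin(2 * np.pi * freq * (t - 0.15) + phase)
        frames = np.zeros((120, 4, 4))
        frames[:, 1, 2] = sig
        stack = synth.ImageStack(frames, onset_index=15, is_dff=True)
        return stack

    def test_sine_amplitude_identity(self):
        fmap = pre.extract_flash_response(self._sine_stack(amp=0.02), 5.0)
        assert fmap.amplitude[1, 2] == pytest.approx(0.02, rel=1e-9)
        assert fmap.amplitude[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_amplitude_phase_invariant(self):
        amps = [pre.extract_flash_response(self._sine_stack(phase=ph), 5.0)
                .amplitude[1, 2] for ph in (0.0, 1.1, 2.7)]
        assert np.ptp(amps) < 1e-9

    def test_unresolvable_frequency_rejected(self):
        with pytest.raises(ValueError, match="not resolvable"):
            pre.extract_flash_response(self._sine_stack(), 5.3)

    def test_fixation_amplitude_maps_envelope(self, gt_maps):
        stack = synth.render_trial_stack(
            synth.StimulusSpec(target_contrast=0.24), gt_maps,
            noise=synth.NO_NOISE, seed=0, onset_index=15, flash_hz=5.0)
        fmap = pre.extract_flash_response(pre.delta_f_over_f(stack), 5.0)
        r = np.corrcoef(fmap.amplitude.ravel(),
                        gt_maps.retinotopic_envelope.ravel())[0, 1]
        assert r > 0.95


class TestDownsample:
    def test_block_mean(self):
        frames = np.arange(2 * 8 * 8, dtype=float).reshape(2, 8, 8)
        out = pre.downsample(synth.ImageStack(frames, onset_index=1), 4)
        assert out.frames.shape == (2, 2, 2)
        assert out.frames[0, 0, 0] == frames[0, :4, :4].mean()
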