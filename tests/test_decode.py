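"""Template fitting, reliability weighting, and the three decoders."""

import numpy as np
import pytest

from vsdmask import decode as dec
from vsdmask import preprocess as pre
from vsdmask import synth
from vsdmask.utils import circular_orientation_correlation, gaussian_2d

MM = 8.0 / 128.0


def _fmap(arr, mm=MM):
    return pre.FlashResponseMap(amplitude=arr, phase=np.zeros_like(arr),
                                flash_frequency=5.0, mm_per_pixel=mm)


class TestRetinotopicTemplate:
    def test_exact_gaussian_recovered(self):
        img = gaussian_2d((64, 64), (30.0, 34.0), 6.0, amplitude=2.0,
                          offset=0.3)
        t = dec.fit_retinotopic_template(_fmap(img))
        assert t.center[0] == pytest.approx(30.0, abs=1e-5)
        assert t.center[1] == pytest.approx(34.0, abs=1e-5)
        assert t.sigma_major == pytest.approx(6.0, rel=1e-6)
        assert t.sigma_minor == pytest.approx(6.0, rel=1e-6)
        assert t.amplitude == pytest.approx(2.0, rel=1e-6)
        assert t.offset == pytest.approx(0.3, rel=1e-5)

    def test_offset_shift_leaves_shape(self):
        img = gaussian_2d((64, 64), (32.0, 32.0), 5.0, amplitude=1.0)
        t0 = dec.fit_retinotopic_template(_fmap(img))
        t1 = dec.fit_retinotopic_template(_fmap(img + 0.7))
        assert t1.offset - t0.offset == pytest.approx(0.7, abs=1e-6)
        assert t1.sigma_major == pytest.approx(t0.sigma_major, rel=1e-6)

    def test_flat_map_rejected(self):
        with pytest.raises(ValueError):
            dec.fit_retinotopic_template(_fmap(np.ones((32, 32))))

    def test_closed_loop_center_and_sigma(self, noiseless_templates, gt_maps):
        template, _ = noiseless_templates
        true_sigma_px = gt_maps.envelope_sigma_mm / gt_maps.mm_per_pixel
        assert abs(template.center[0] - 63.5) < 1.0
        assert abs(template.center[1] - 63.5) < 1.0
        assert template.sigma_major == pytest.approx(true_sigma_px, rel=0.05)
        assert template.sigma_minor == pytest.approx(true_sigma_px, rel=0.05)


class TestColumnarMap:
    def _template(self, shape=(64, 64)):
        img = gaussian_2d(shape, ((shape[0] - 1) / 2, (shape[1] - 1) / 2), 10.0)
        return dec.fit_retinotopic_template(_fmap(img))

    def test_single_orientation_pixel(self):
        t = self._template()
        resp0 = np.zeros((64, 64)); resp0[30, 30] = 1.0
        maps = {0.0: _fmap(resp0), 45.0: _fmap(np.zeros((64, 64))),
                90.0: _fmap(np.zeros((64, 64))), 135.0: _fmap(np.zeros((64, 64)))}
        cmap = dec.fit_columnar_map(maps, t, band=None)
        assert cmap.orientation[30, 30] == pytest.approx(0.0, abs=1e-9)

    def test_label_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        t = self._template()
        resp = {o: _fmap(rng.random((64, 64))) for o in (0.0, 45.0, 90.0, 135.0)}
        c1 = dec.fit_columnar_map(resp, t, band=None)
        shifted = {o + 30.0: m for o, m in resp.items()}
        c2 = dec.fit_columnar_map(shifted, t, band=None)
        d = (c2.orientation - c1.orientation - 30.0) % 180.0
        d = np.minimum(d, 180.0 - d)
        assert np.max(d) < 1e-6

    def test_too_few_orientations_rejected(self):
        t = self._template()
        with pytest.raises(ValueError):
            dec.fit_columnar_map({0.0: _fmap(np.ones((64, 64)))}, t)

    def test_noiseless_closed_loop_circular_correlation(
            self, noiseless_templates, gt_maps):
        template, cmap = noiseless_templates
        sel = template.ellipse_mask(2.0)
        cc = circular_orientation_correlation(
            cmap.orientation[sel], gt_maps.orientation_preference[sel])
        assert cc > 0.99


class TestPixelVariance:
    def _noise_stacks(self, n_trials, sd, seed=0, shape=(20, 64, 64)):
        rng = np.random.default_rng(seed)
        return [synth.ImageStack(sd * rng.standard_normal(shape),
                                 onset_index=5, is_dff=True)
                for _ in range(n_trials)]

    def test_identical_trials_floored_zero(self):
        frames = np.random.default_rng(1).random((10, 16, 16))
        stacks = [synth.ImageStack(frames.copy(), onset_index=5, is_dff=True)
                  for _ in range(2)]
        v = dec.estimate_pixel_variance(stacks, ["a", "a"], "retinotopic")
        assert (v.retinotopic > 0).all()          # floored, never exactly 0
        assert v.retinotopic.max() < 1e-10

    def test_planted_white_noise_recovered(self):
        sd = 2e-3
        stacks = self._noise_stacks(50, sd)
        v = dec.estimate_pixel_variance(stacks, ["c"] * 50, "retinotopic")
        assert v.retinotopic.mean() == pytest.approx(sd ** 2, rel=0.10)

    def test_variance_scales_quadratically(self):
        v1 = dec.estimate_pixel_variance(self._noise_stacks(30, 1e-3, seed=2),
                                         ["c"] * 30, "retinotopic")
        v2 = dec.estimate_pixel_variance(self._noise_stacks(30, 2e-3, seed=2),
                                         ["c"] * 30, "retinotopic")
        ratio = v2.retinotopic.mean() / v1.retinotopic.mean()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_all_singletons_rejected(self):
        stacks = self._noise_stacks(2, 1e-3)
        with pytest.raises(ValueError):
            dec.estimate_pixel_variance(stacks, ["a", "b"], "retinotopic")


class TestDecoders:
    @pytest.fixture()
    def setup(self):
        img = gaussian_2d((64, 64), (31.5, 31.5), 8.0)
        template = dec.fit_retinotopic_template(_fmap(img))
        var = dec.VarianceMaps(retinotopic=np.ones((64, 64)),
                               columnar=np.ones((64, 64)))
        return template, var

    def _stack(self, frames):
        return synth.ImageStack(np.asarray(frames, float), onset_index=0,
                                is_dff=True)

    def test_projection_identity(self, setup):
        template, var = setup
        s = self._stack(template.h_ret[None])
        out = dec.decode_retinotopic(s, template, var)
        assert out.values[0] == pytest.approx(np.linalg.norm(template.h_ret),
                                              rel=1e-9)

    def test_orthogonal_frame_decodes_zero(self, setup):
        template, var = setup
        h = template.h_ret
        orth = np.zeros_like(h)
        orth[0, 0], orth[0, 1] = h[0, 1], -h[0, 0]
        out = dec.decode_retinotopic(self._stack(orth[None]), template, var)
        assert abs(out.values[0]) < 1e-9 * np.linalg.norm(h)

    def test_linearity(self, setup):
        template, var = setup
        rng = np.random.default_rng(4)
        f1, f2 = rng.random((64, 64)), rng.random((64, 64))
        d = lambda f: dec.decode_retinotopic(self._stack(f[None]),
                                             template, var).values[0]
        assert d(f1 + 3 * f2) == pytest.approx(d(f1) + 3 * d(f2), rel=1e-10)

    def test_reliability_weighting_uniform_equals_unweighted(self, setup):
        template, _ = setup
        rng = np.random.default_rng(5)
        frame = rng.random((64, 64))
        v1 = dec.VarianceMaps(retinotopic=np.ones((64, 64)))
        v2 = dec.VarianceMaps(retinotopic=np.full((64, 64), 3.7))
        a = dec.decode_retinotopic(self._stack(frame[None]), template, v1)
        b = dec.decode_retinotopic(self._stack(frame[None]), template, v2)
        assert a.values[0] == pytest.approx(b.values[0], rel=1e-10)


class TestColumnarDecoders:
    def _render_bandpassed(self, gt_maps, ori):
        stim = synth.StimulusSpec(background_contrast=1.0,
                                  background_orientation=ori)
        stack = synth.render_trial_stack(stim, gt_maps, noise=synth.NO_NOISE,
                                         seed=0)
        dff = pre.delta_f_over_f(stack)
        return pre.bandpass_stack(dff, mm_per_pixel=gt_maps.mm_per_pixel)

    def test_axis_decoder_signs(self, noiseless_templates, gt_maps):
        _, cmap = noiseless_templates
        var = dec.VarianceMaps(columnar=np.ones(gt_maps.grid_shape))
        last = {}
        for ori in (0.0, 90.0, 45.0, -45.0):
            s = self._render_bandpassed(gt_maps, ori)
            out = dec.decode_columnar_axis(s, cmap, var)
            last[ori] = out.values[-20:].mean()
        assert last[0.0] > 0
        assert last[90.0] < 0
        assert abs(last[45.0]) < 0.2 * abs(last[0.0])
        assert abs(last[-45.0]) < 0.2 * abs(last[0.0])

    def test_population_peaks_at_stimulus_orientation(
            self, noiseless_templates, gt_maps):
        _, cmap = noiseless_templates
        var = dec.VarianceMaps(columnar=np.ones(gt_maps.grid_shape))
        for ori, expect in ((0.0, 0.0), (45.0, 45.0)):
            s = self._render_bandpassed(gt_maps, ori)
            out = dec.decode_population(s, cmap, var)
            tuning = out.values[-20:].mean(axis=0)
            peak = out.channel_orientations[np.nanargmax(tuning)]
            assert peak == expect
            if ori == 0.0:
                trough = out.channel_orientations[np.nanargmin(tuning)]
                assert abs(trough) >= 75.0

    def test_population_channels_sum_to_zero_for_balanced_signal(
            self, noiseless_templates, gt_maps):
        # a pure columnar-band frame with zero spatial mean decodes into
        # channels whose weighted sum is (near) zero
        _, cmap = noiseless_templates
        var = dec.VarianceMaps(columnar=np.ones(gt_maps.grid_shape))
        s = self._render_bandpassed(gt_maps, 30.0)
        out = dec.decode_population(s, cmap, var)
        tuning = out.values[-20:].mean(axis=0)
        assert abs(np.nansum(tuning)) < 0.35 * np.nanmax(np.abs(tuning))

    def test_closed_loop_population_peaks(self, decoded_population):
        # default-SNR session: trial-averaged population decoder peaks in the
        # ground-truth background-orientation bin for every design orientation
        for ori, series in decoded_population.items():
            t = series.times_ms
            win = (t >= 50) & (t < 200)
            tuning = np.nanmean(series.values[win], axis=0)
            peak = series.channel_orientations[np.nanargmax(tuning)]
            d = (peak - ori + 90.0) % 180.0 - 90.0
            assert abs(d) < 1e-9, f"bg {ori}: peak at {peak}"
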