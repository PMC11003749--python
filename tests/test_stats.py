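"""Pooling, weighted statistics, censoring, correlation, trend selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp
from scipy import stats as sps

from vsdmask import stats as st
from vsdmask.decode import DecodedSeries


def _series(values, dt=10.0):
    values = np.asarray(values, float)
    return DecodedSeries(values=values,
                         times_ms=np.arange(values.shape[0]) * dt,
                         scale="0-90")


class TestSvdPooling:
    def _exp(self, response, contrasts=(0.1, 0.2, 0.4)):
        return {"contrasts": np.array(contrasts), "response": response}

    def test_single_experiment_unit_scale(self):
        rng = np.random.default_rng(0)
        pool = st.svd_pool_scale({"e1": self._exp(rng.random((30, 3)))})
        assert pool.scale_factors[0] == pytest.approx(1.0)
        assert pool.weights[0] == pytest.approx(1.0)

    def test_rank_one_pair_scales(self):
        t = np.linspace(0, 1, 30)
        base = np.outer(np.sin(np.pi * t), [1.0, 2.0, 4.0])
        pool = st.svd_pool_scale({"a": self._exp(base),
                                  "b": self._exp(0.5 * base)})
        np.testing.assert_allclose(pool.scale_factors, [1.0, 2.0], rtol=1e-10)
        np.testing.assert_allclose(pool.weights, [1.0, 0.25], rtol=1e-10)

    def test_gain_invariant_pooled_contribution(self):
        t = np.linspace(0, 1, 30)
        base = np.outer(np.sin(np.pi * t), [1.0, 2.0, 4.0])
        for k in (0.3, 1.0, 2.5):
            pool = st.svd_pool_scale({"a": self._exp(base),
                                      "b": self._exp(k * base)})
            contrib = k * pool.scale_factors[1]
            assert contrib == pytest.approx(pool.scale_factors[0] * 1.0,
                                            rel=1e-8)

    def test_interpolation_to_union_grid(self):
        t = np.linspace(0, 1, 20)
        shape = np.sin(np.pi * t)
        a = self._exp(np.outer(shape, [1.0, 3.0]), contrasts=(0.1, 0.3))
        b = self._exp(np.outer(shape, [2.0, 3.0]), contrasts=(0.2, 0.3))
        pool = st.svd_pool_scale({"a": a, "b": b})
        np.testing.assert_allclose(pool.contrast_grid, [0.1, 0.2, 0.3])

    def test_rank_zero_rejected(self):
        with pytest.raises(ValueError):
            st.svd_pool_scale({"a": self._exp(np.zeros((10, 3)))})


class TestWeightedMeanSd:
    def test_unit_weights_reduce_to_ordinary(self):
        rng = np.random.default_rng(1)
        x = rng.random(40)
        mean, sd = st.weighted_mean_sd(x, np.ones(40))
        assert mean == pytest.approx(x.mean(), rel=1e-12)
        assert sd == pytest.approx(x.std(), rel=1e-12)

    def test_single_weighted_trial(self):
        mean, sd = st.weighted_mean_sd([2.0], [0.5])
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_matches_literal_formula_brute_force(self):
        rng = np.random.default_rng(2)
        r = rng.random(17)
        w = rng.uniform(0.2, 2.0, 17)
        mean, sd = st.weighted_mean_sd(r, w)
        n = r.size
        m_ref = sum(w[i] * r[i] for i in range(n)) / n
        sd_ref = np.sqrt(sum((w[i] * r[i] - m_ref) ** 2 for i in range(n)) / n)
        assert mean == pytest.approx(m_ref, rel=1e-12)
        assert sd == pytest.approx(sd_ref, rel=1e-12)


class TestZscore:
    def _trials(self, sd, n=20, seed=3):
        rng = np.random.default_rng(seed)
        base = np.sin(np.linspace(0, 3, 40))
        return [_series(base + sd * rng.standard_normal(40))
                for _ in range(n)]

    def test_scale_invariance(self):
        trials = self._trials(0.5)
        out1, _ = st.zscore_normalize(trials, ["c"] * len(trials), 1.0)
        scaled = [s.copy_with(7.0 * np.asarray(s.values)) for s in trials]
        out2, _ = st.zscore_normalize(scaled, ["c"] * len(trials), 1.0)
        np.testing.assert_allclose(out1[0].values, out2[0].values, rtol=1e-10)

    def test_planted_noise_normalized_to_unit_sd(self):
        trials = self._trials(0.37, n=60)
        out, sd = st.zscore_normalize(trials, ["c"] * len(trials), 1.0)
        vals = np.stack([np.asarray(s.values) for s in out])
        resid = vals - vals.mean(axis=0, keepdims=True)
        t = out[0].times_ms
        sel = (t >= 50) & (t < 250)
        assert resid[:, sel].std() == pytest.approx(1.0, rel=0.05)

    def test_zero_residual_rejected(self):
        trials = [_series(np.ones(40))] * 3
        with pytest.raises(ValueError):
            st.zscore_normalize(trials, ["c"] * 3, 1.0)


class TestCensoring:
    def test_no_saccade_keeps_everything(self):
        s = _series(np.arange(20.0))
        out = st.censor_after_saccade(s, None, mode="framewise")
        np.testing.assert_allclose(out.values, np.arange(20.0))

    def test_integrate_up_to_rt_frame(self):
        s = _series(np.arange(20.0))          # frames at 0,10,...,190 ms
        out = st.censor_after_saccade(s, 95.0, mode="integrate")
        assert out == pytest.approx(np.arange(10).mean())

    def test_framewise_two_trial_average(self):
        a = st.censor_after_saccade(_series(np.full(20, 2.0)), 95.0,
                                    mode="framewise")
        b = st.censor_after_saccade(_series(np.full(20, 6.0)), 195.0,
                                    mode="framewise")
        stack = np.stack([a.values, b.values])
        mean = np.nanmean(stack, axis=0)
        np.testing.assert_allclose(mean[:10], 4.0)
        np.testing.assert_allclose(mean[10:], 6.0)

    def test_rt_before_onset_rejected(self):
        with pytest.raises(ValueError):
            st.censor_after_saccade(_series(np.arange(5.0)), -10.0)


class TestWeightedCorrelation:
    def test_equal_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(15), rng.random(15)
        res = st.weighted_correlation(x, y, np.ones(15))
        assert res.rho == pytest.approx(sps.pearsonr(x, y)[0], abs=1e-12)
        assert res.n_eff == pytest.approx(15.0, rel=1e-12)

    def test_perfect_linearity(self):
        x = np.arange(8.0)
        res = st.weighted_correlation(x, 3 * x + 1, np.arange(1.0, 9.0))
        assert res.rho == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_entropy_effective_n_concentrated_weights(self):
        w = np.array([0.97, 0.01, 0.01, 0.01])
        ne = st.effective_n(w)
        wn = w / w.sum()
        assert ne == pytest.approx(np.exp(-np.sum(wn * np.log(wn))), rel=1e-12)
        assert ne < 1.3

    @given(st_hyp.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_and_weight_rescale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(10), rng.random(10)
        w = rng.uniform(0.5, 3.0, 10)
        base = st.weighted_correlation(x, y, w).rho
        moved = st.weighted_correlation(2.5 * x - 1, -0.5 * y + 4, 10 * w).rho
        assert moved == pytest.approx(-base, abs=1e-10)

    def test_n_eff_maximized_at_equal_weights(self):
        rng = np.random.default_rng(5)
        n = 12
        for _ in range(200):
            w = rng.uniform(0.01, 1.0, n)
            assert st.effective_n(w) <= n + 1e-9
        assert st.effective_n(np.full(n, 0.3)) == pytest.approx(n, rel=1e-12)

    def test_zero_variance_flagged(self):
        res = st.weighted_correlation(np.ones(5), np.arange(5.0), np.ones(5))
        assert not res.defined


class TestTrendSelection:
    def test_linear_data_keeps_flat_model(self):
        th = np.arange(-75.0, 90.1, 15.0)
        tf = st.fit_orientation_trend(0.01 * th + 2.0, th)
        assert tf.model == "flat"
        assert not tf.chosen

    def test_gaussian_data_recovered_exactly(self):
        th = np.arange(-75.0, 90.1, 15.0)
        y = 2.0 * np.exp(-(th ** 2) / (2 * 30.0 ** 2)) + 1.0
        tf = st.fit_orientation_trend(y, th)
        assert tf.model == "gaussian"
        A, sigma, c = tf.gaussian_params
        assert A == pytest.approx(2.0, abs=1e-6)
        assert sigma == pytest.approx(30.0, abs=1e-5)
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_too_few_orientations_rejected(self):
        with pytest.raises(ValueError):
            st.fit_orientation_trend([1.0, 2.0, 3.0], [0.0, 30.0, 60.0])
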