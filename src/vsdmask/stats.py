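"""Cross-experiment pooling and the analysis's bespoke statistics.

Implements:

* SVD-based amplitude equalization across experiment days (``svd_pool_scale``),
  with reliability weights ``w_exp = 1/scale^2``;
* a deliberately literal weighted mean/SD estimator (weights inside both
  sums, divisor n) used for pooled response averages;
* modified z-score normalization by the weighted SD of condition-mean
  residuals in a 50-250 ms window;
* post-saccade frame censoring (integrate or frame-wise modes);
* the trial-count-weighted Pearson correlation with an entropy-based
  effective sample size and t-distributed p-values;
* flat-vs-Gaussian trend fitting with nested F-test model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats as sps

from .decode import DecodedSeries


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

@dataclass
class PoolingScale:
    """Per-experiment SVD1 loadings, scale factors, and reliability weights.

    The maximum-loading experiment has scale 1; ``weights = 1/scale**2``.
    """

    loadings: np.ndarray
    scale_factors: np.ndarray
    weights: np.ndarray
    experiments: list
    contrast_grid: np.ndarray
    temporal_component: np.ndarray


def svd_pool_scale(reference_responses: dict, window_mask=None) -> PoolingScale:
    """Amplitude-equalize experiments from their target-contrast responses.

    ``reference_responses`` maps experiment id -> ``(times_or_frames x
    contrasts)`` response DataFrame-like: a dict with keys ``contrasts``
    (1D array) and ``response`` (2D array, frames x contrasts).  Responses
    are linearly interpolated onto the union contrast grid (edge contrasts
    clamped), stacked side by side, and the first singular component
    extracted over the (optionally ``window_mask``-restricted) frames.  Each
    experiment's loading is the norm of its SVD1 coefficients; scales match
    every experiment to the largest loading.
    """
    if not reference_responses:
        raise ValueError("no experiments provided")
    exps = list(reference_responses)
    grids = [np.asarray(reference_responses[e]["contrasts"], float) for e in exps]
    union = np.unique(np.concatenate(grids))

    blocks = []
    for e, grid in zip(exps, grids):
        resp = np.asarray(reference_responses[e]["response"], float)
        if resp.shape[1] != grid.size:
            raise ValueError(f"experiment {e}: response/contrast shape mismatch")
        order = np.argsort(grid)
        grid, resp = grid[order], resp[:, order]
        interp = np.empty((resp.shape[0], union.size))
        for i, c in enumerate(union):
            cc = np.clip(c, grid[0], grid[-1])   # clamp: no extrapolation
            j = np.searchsorted(grid, cc)
            if j == 0 or grid[min(j, grid.size - 1)] == cc:
                interp[:, i] = resp[:, min(j, grid.size - 1)]
            else:
                f = (cc - grid[j - 1]) / (grid[j] - grid[j - 1])
                interp[:, i] = (1 - f) * resp[:, j - 1] + f * resp[:, j]
        blocks.append(interp)

    stacked = np.concatenate(blocks, axis=1)
    if window_mask is not None:
        stacked = stacked[np.asarray(window_mask, bool)]
    if not np.any(stacked):
        raise ValueError("rank-0 input: all responses are zero")
    u, s, vt = np.linalg.svd(stacked, full_matrices=False)
    u1, v1 = u[:, 0], s[0] * vt[0]
    if u1.sum() < 0:                     # fix sign: temporal component positive
        u1, v1 = -u1, -v1
    nc = union.size
    loadings = np.array([np.linalg.norm(v1[i * nc:(i + 1) * nc])
                         for i in range(len(exps))])
    if loadings.max() == 0:
        raise ValueError("rank-0 input: zero SVD1 loadings")
    scales = loadings.max() / np.where(loadings > 0, loadings, np.nan)
    weights = 1.0 / scales ** 2
    return PoolingScale(loadings=loadings, scale_factors=scales,
                        weights=weights, experiments=exps,
                        contrast_grid=union, temporal_component=u1)


def weighted_mean_sd(values, weights):
    """Pooled estimator with the weight inside both sums and divisor n.

    ``mean = (1/n) sum_i w_i r_i``; ``sd = sqrt((1/n) sum_i (w_i r_i - mean)^2)``.
    Not a conventional weighted mean; the literal form is kept because the
    statistics built on it (see weighted_correlation) are invariant to the
    quirk.
    """
    r = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("empty input")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if w.size == 1:
        w = np.full_like(r, w[0])
    wr = w * r
    mean = wr.mean()
    sd = float(np.sqrt(((wr - mean) ** 2).mean()))
    return float(mean), sd


def zscore_normalize(series_list, condition_labels, weights,
                     window_ms=(50.0, 250.0)):
    """Express decoded series as modified z-scores.

    The divisor is the weighted SD (literal estimator) of condition-mean-
    subtracted residuals over ``window_ms``, pooled over all trials;
    ``weights`` is one reliability weight per trial.  Returns the normalized
    series list and the SD used.
    """
    t = series_list[0].times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    if not sel.any():
        raise ValueError("z-score window covers no frames")
    w_arr = np.asarray(weights, dtype=float)
    if w_arr.ndim == 0:
        w_arr = np.full(len(series_list), float(w_arr))
    groups = {}
    for i, lab in enumerate(condition_labels):
        groups.setdefault(lab, []).append(i)
    resid, rw = [], []
    for lab, idx in groups.items():
        vals = np.stack([np.asarray(series_list[i].values, float) for i in idx])
        r = vals - vals.mean(axis=0, keepdims=True)
        for i, row in zip(idx, r):
            chunk = np.asarray(row)[sel].ravel()
            resid.append(chunk)
            rw.append(np.full(chunk.size, w_arr[i]))
    resid = np.concatenate(resid)
    rw = np.concatenate(rw)
    _, sd = weighted_mean_sd(resid, rw)
    if sd == 0:
        raise ValueError("zero residual SD; cannot z-score")
    out = [s.copy_with(np.asarray(s.values, float) / sd, units="zscore")
           for s in series_list]
    return out, sd


def censor_after_saccade(series: DecodedSeries, rt_ms: Optional[float],
                         mode: str = "framewise"):
    """Drop frames after the saccade.

    ``integrate``: returns the trial mean over frames up to (and including)
    the reaction-time frame.  ``framewise``: returns a copy with post-RT
    frames set to NaN, so cross-trial frame averages simply drop the trial
    beyond its RT.  Trials with an RT before onset are rejected.
    """
    if rt_ms is None:
        if mode == "integrate":
            return float(np.nanmean(series.values))
        return series.copy_with(np.asarray(series.values, float).copy())
    if rt_ms < 0:
        raise ValueError("reaction time before stimulus onset")
    keep = series.times_ms <= rt_ms
    vals = np.asarray(series.values, dtype=float)
    if mode == "integrate":
        return float(np.nanmean(vals[keep], axis=0).mean())
    out = vals.copy()
    out[~keep] = np.nan
    return series.copy_with(out)


# ---------------------------------------------------------------------------
# weighted correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    n_eff: float
    p_value: float
    t_stat: float
    weights: np.ndarray

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rho)


def effective_n(weights) -> float:
    """Entropy-based effective sample count: ``exp(-sum w~ ln w~)``."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 0]
    wn = w / w.sum()
    return float(np.exp(-np.sum(wn * np.log(wn))))


def weighted_correlation(x, y, w) -> CorrelationResult:
    """Trial-count-weighted Pearson correlation with entropy-based df.

    Implements a weighted covariance with the weight applied inside the
    deviations: ``cov(x,y;w) = sum(w_i(x_i-m_x) * w_i(y_i-m_y)) / sum(w_i)``
    with weighted means ``m``.  ``rho`` is invariant to affine transforms of
    x and y and to rescaling of w, and reduces to the ordinary Pearson r at
    equal weights.  The two-sided p-value uses a t distribution with
    (possibly non-integer) ``n_eff - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.size == y.size == w.size):
        raise ValueError("x, y, w must have equal length")
    ok = w > 0
    x, y, w = x[ok], y[ok], w[ok]
    if x.size < 3:
        raise ValueError("need at least 3 points with positive weight")

    mx = np.sum(w * x) / w.sum()
    my = np.sum(w * y) / w.sum()
    cov_xy = np.sum((w * (x - mx)) * (w * (y - my))) / w.sum()
    cov_xx = np.sum((w * (x - mx)) ** 2) / w.sum()
    cov_yy = np.sum((w * (y - my)) ** 2) / w.sum()
    ne = effective_n(w)
    if cov_xx <= 0 or cov_yy <= 0:
        return CorrelationResult(np.nan, ne, np.nan, np.nan, w)
    rho = float(cov_xy / np.sqrt(cov_xx * cov_yy))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = ne - 2.0
    if df <= 0:
        return CorrelationResult(rho, ne, np.nan, np.nan, w)
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, ne, 0.0, np.inf * np.sign(rho), w)
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(rho, ne, float(p), float(t), w)


# ---------------------------------------------------------------------------
# trend fitting
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """Flat-line vs Gaussian trend comparison across background orientation."""

    model: str                     # 'flat' | 'gaussian'
    flat_params: tuple             # (m, c)
    gaussian_params: Optional[tuple]   # (A, sigma, c) or None
    f_stat: float
    p_value: float
    ss_flat: float
    ss_gaussian: float
    df_flat: int
    df_gaussian: int
    chosen: bool                   # True when the Gaussian was selected


def _gauss_trend(theta, A, sigma, c):
    return A * np.exp(-(theta ** 2) / (2.0 * sigma ** 2)) + c


def fit_orientation_trend(values, orientations, alpha: float = 0.05) -> TrendFit:
    """Fit flat-line and Gaussian trends; select by nested F-test.

    Flat: ``r = m*theta + c``.  Gaussian: ``r = A*exp(-theta^2/(2 sigma^2)) + c``
    (A may be negative, capturing inverted profiles).  The Gaussian is chosen
    iff the F statistic for its extra parameter exceeds the ``alpha``
    critical value.  A non-convergent Gaussian fit falls back to the flat
    model with ``gaussian_params=None``.
    """
    y = np.asarray(values, dtype=float)
    th = np.asarray(orientations, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 orientations")

    m, c = np.polyfit(th, y, 1)
    ss_flat = float(np.sum((y - (m * th + c)) ** 2))
    df_flat = n - 2

    span = max(th.max() - th.min(), 1.0)
    amp0 = y[np.argmin(np.abs(th))] - y.mean()
    try:
        popt, _ = optimize.curve_fit(
            _gauss_trend, th, y, p0=[amp0 if amp0 != 0 else y.std() or 1.0,
                                     span / 4.0, y.mean()],
            bounds=([-np.inf, 1.0, -np.inf], [np.inf, 10 * span, np.inf]),
            maxfev=20000)
        gp = tuple(float(v) for v in popt)
        ss_gau = float(np.sum((y - _gauss_trend(th, *popt)) ** 2))
    except RuntimeError:
        return TrendFit(model="flat", flat_params=(float(m), float(c)),
                        gaussian_params=None, f_stat=np.nan, p_value=np.nan,
                        ss_flat=ss_flat, ss_gaussian=np.nan,
                        df_flat=df_flat, df_gaussian=n - 3, chosen=False)

    df_gau = n - 3
    d_df = df_flat - df_gau
    if ss_gau <= 0:
        f = np.inf
        p = 0.0
    else:
        f = max((ss_flat - ss_gau) / d_df / (ss_gau / df_gau), 0.0)
        p = float(sps.f.sf(f, d_df, df_gau))
    chosen = p < alpha
    return TrendFit(model="gaussian" if chosen else "flat",
                    flat_params=(float(m), float(c)), gaussian_params=gp,
                    f_stat=float(f), p_value=p, ss_flat=ss_flat,
                    ss_gaussian=ss_gau, df_flat=df_flat, df_gaussian=df_gau,
                    chosen=chosen)
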