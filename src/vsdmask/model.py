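"""Delayed, orientation-tuned divisive-normalization population model.

Twelve orientation channels (-75 to 90 deg in 15-deg steps) respond to a
stimulus ``s = (C_T, theta_T, C_B, theta_B, D)``.  Each channel builds an
excitatory drive ``r_e`` and a normalization drive ``r_n`` by convolving the
channel's effective input contrast with a separable spatiotemporal kernel
(2D Gaussian x gamma density) and evaluating at the stimulus center; the
output is

    r(t) = r_e(t)^p / (r_n(t)^p + r0^p)

The two pathways share a peak orientation but the normalization pool is
more broadly tuned (sigma_n > sigma_e) and temporally slower (gamma scale
b_n > b_e): the delayed, tuned denominator is what produces the biphasic
masking dynamics.

Drives are linear in the stimulus root-mean-square contrast (a grating of
Michelson contrast C has rms contrast C/sqrt(2)); with contrast expressed
this way, r0 = 1/32 plays the role of a semisaturation contrast (~3%).
Effective target+background contrast combines components in quadrature with
the phase-dependent correction ``lambda(x)``, computed from the local rms
contrast of the summed luminance patterns, so an in-phase parallel pair sums
linearly while orthogonal pairs combine incoherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .stats import weighted_correlation
from .synth import StimulusSpec
from .utils import CHANNEL_ORIENTATIONS, raised_cosine_window, wrap_orientation


@dataclass(frozen=True)
class PathwayParams:
    """One pathway's tuning/pooling/temporal parameters.

    sigma: orientation tuning SD (deg); s: spatial pooling SD (deg of visual
    angle); a, b: gamma shape and scale (ms) of the temporal impulse response.
    """

    sigma: float
    s: float
    a: float
    b: float


@dataclass(frozen=True)
class ModelParams:
    """Printed defaults of the normalization model.

    ``p`` response exponent; ``r0`` normalization constant (rms-contrast
    units); excitation Omega_e = (15 deg, 0.28 deg, 9, 8 ms); normalization
    Omega_n = (20 deg, 0.28 deg, 9, 10.64 ms).  ``dt`` is the simulation
    step, ``frame_ms`` the box-average used to mirror the imaging frame
    rate, and the spatial grid covers +/-``extent_deg`` at
    ``grid_step_deg`` per sample.
    """

    p: float = 2.0
    r0: float = 0.03125
    excitation: PathwayParams = PathwayParams(sigma=15.0, s=0.28, a=9.0, b=8.0)
    normalization: PathwayParams = PathwayParams(sigma=20.0, s=0.28, a=9.0, b=10.64)
    dt: float = 1.0
    t_max: float = 400.0
    frame_ms: float = 10.0
    grid_step_deg: float = 0.02
    extent_deg: float = 3.0
    channel_orientations: tuple = tuple(CHANNEL_ORIENTATIONS)

    def __post_init__(self):
        for name in ("p", "r0", "dt", "t_max", "frame_ms", "grid_step_deg",
                     "extent_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.normalization.sigma <= self.excitation.sigma:
            raise ValueError("normalization tuning must be broader than excitation")

    def with_untuned_normalization(self) -> "ModelParams":
        """Variant with sigma_n = sigma_e (bypasses the sigma_n > sigma_e check)."""
        obj = replace(self)
        object.__setattr__(obj, "normalization",
                           replace(self.normalization, sigma=self.excitation.sigma))
        return obj


@dataclass
class Kernel:
    """Separable spatiotemporal impulse response, unit mass in each factor."""

    spatial: np.ndarray       # (H, W), sums to 1
    temporal: np.ndarray      # (T,), sums to 1
    dt: float
    grid_step_deg: float


@dataclass
class EffectiveContrast:
    """Per-channel effective contrast fields (separable space x time).

    Each component is ``spatial(x) * pulse(t)``; ``c_tb`` already includes
    the quadrature combination with the lambda correction.
    """

    c_b: Optional[np.ndarray]      # spatial field or None
    c_t: Optional[np.ndarray]
    c_tb: Optional[np.ndarray]
    pulse: np.ndarray              # (T,), unit-height box of width D
    lam: Optional[np.ndarray]      # lambda(x) correction factor


@dataclass
class ModelResponse:
    """Population response at the stimulus center.

    ``r`` is (12, T) in units of the 24%-contrast target-only response
    averaged over 50-200 ms (=1 by construction); ``r_e``/``r_n`` keep the
    raw pathway drives for inspection.
    """

    times_ms: np.ndarray
    r: np.ndarray
    r_e: np.ndarray
    r_n: np.ndarray
    channel_orientations: np.ndarray
    params: ModelParams
    output_scale: float

    def to_frames(self, frame_ms: Optional[float] = None):
        """Box-average to imaging frames; times are bin centers.

        Returns ``(frame_times_ms, (12, n_frames) response)``.
        """
        fm = frame_ms if frame_ms is not None else self.params.frame_ms
        step = int(round(fm / self.params.dt))
        nf = self.r.shape[1] // step
        rf = self.r[:, : nf * step].reshape(self.r.shape[0], nf, step).mean(axis=2)
        t = (np.arange(nf) + 0.5) * fm
        return t, rf


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _grid(params: ModelParams):
    ax = np.arange(-params.extent_deg, params.extent_deg + params.grid_step_deg / 2,
                   params.grid_step_deg)
    X, Y = np.meshgrid(ax, ax)
    return ax, X, Y


def impulse_kernel(s: float, a: float, b: float, dt: float = 1.0,
                   grid_step_deg: float = 0.02, t_max: float = 400.0,
                   spatial_extent_sd: float = 4.0) -> Kernel:
    """Discrete separable kernel: 2D Gaussian (SD ``s`` deg) x gamma(a, b).

    Both factors are normalized to unit sum so convolving a spatially
    uniform, temporally sustained input of contrast C returns C.  The
    temporal support is truncated where the gamma tail falls below 1e-6 of
    its peak.
    """
    if dt > b / 4.0:
        raise ValueError("dt too coarse to resolve the gamma kernel")
    half = int(np.ceil(spatial_extent_sd * s / grid_step_deg))
    ax = np.arange(-half, half + 1) * grid_step_deg
    gx = np.exp(-(ax ** 2) / (2 * s ** 2))
    spatial = np.outer(gx, gx)
    spatial /= spatial.sum()

    t = np.arange(0.0, t_max, dt)
    with np.errstate(divide="ignore"):
        k = np.where(t > 0, t ** (a - 1.0) * np.exp(-t / b), 0.0)
    peak = k.max()
    nz = np.nonzero(k > 1e-6 * peak)[0]
    k = k[: nz[-1] + 1] if nz.size else k
    k = k / k.sum()
    return Kernel(spatial=spatial, temporal=k, dt=dt, grid_step_deg=grid_step_deg)


def _orientation_gain(theta_stim: float, theta_max: float, sigma: float) -> float:
    d = float(wrap_orientation(theta_stim - theta_max))
    return float(np.exp(-(d ** 2) / (2.0 * sigma ** 2)))


def _local_rms_contrast(pattern: np.ndarray, window_sd_px: float) -> np.ndarray:
    """Local rms contrast of a zero-mean luminance modulation pattern.

    Scaled by sqrt(2) so a full-field grating of amplitude C reports C.
    """
    power = ndimage.gaussian_filter(pattern ** 2, window_sd_px, mode="nearest")
    return np.sqrt(2.0 * np.clip(power, 0.0, None))


def effective_contrast(stimulus: StimulusSpec, theta_max: float, sigma: float,
                       params: ModelParams = ModelParams(),
                       rms_input: bool = True) -> EffectiveContrast:
    """Effective-contrast fields seen by one orientation channel.

    Spatial profiles: the target's Gaussian envelope (sigma 0.14 deg) and the
    background's 4-deg raised-cosine window, each multiplied by the wrapped
    orientation-tuning Gaussian ``exp(-(theta-theta_max)^2/(2 sigma^2))``.
    The combined field is ``c_tb = lambda(x)*sqrt(c_b^2 + c_t^2)`` with
    ``lambda = C_TB / sqrt(C_B^2 + C_T^2)`` computed from local rms contrasts
    of the rendered luminance patterns; for the in-phase 0-deg pair this
    reduces to ``C_T + C_B`` at center.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ax, X, Y = _grid(params)
    R = np.hypot(X, Y)
    rms = 1.0 / np.sqrt(2.0) if rms_input else 1.0

    pulse_len = int(round(params.t_max / params.dt))
    t = np.arange(pulse_len) * params.dt
    pulse = (t < stimulus.duration_ms).astype(float)

    c_t_env = None
    if stimulus.target_contrast > 0:
        env = np.exp(-(R ** 2) / (2.0 * stimulus.target_sigma ** 2))
        c_t_env = rms * stimulus.target_contrast * env
    c_b_env = None
    if stimulus.background_contrast > 0:
        win = raised_cosine_window(R, radius=stimulus.background_diameter / 2.0,
                                   taper=0.5)
        c_b_env = rms * stimulus.background_contrast * win

    g_t = _orientation_gain(stimulus.target_orientation, theta_max, sigma)
    g_b = _orientation_gain(stimulus.background_orientation, theta_max, sigma)
    c_t = c_t_env * g_t if c_t_env is not None else None
    c_b = c_b_env * g_b if c_b_env is not None else None

    lam = None
    c_tb = None
    if c_t is not None and c_b is not None:
        lam = _contrast_correction_cached(stimulus, params)
        c_tb = lam * np.sqrt(c_b ** 2 + c_t ** 2)
    elif c_t is not None:
        c_tb = c_t
    elif c_b is not None:
        c_tb = c_b
    return EffectiveContrast(c_b=c_b, c_t=c_t, c_tb=c_tb, pulse=pulse, lam=lam)


from functools import lru_cache


@lru_cache(maxsize=32)
def _contrast_correction_cached(stimulus: StimulusSpec,
                                params: ModelParams) -> np.ndarray:
    return _contrast_correction(stimulus, params)


def _contrast_correction(stimulus: StimulusSpec, params: ModelParams) -> np.ndarray:
    """lambda(x) = C_TB(x) / sqrt(C_B(x)^2 + C_T(x)^2) from rendered patterns.

    Luminance modulations of the two gratings are rendered on the model grid
    (both cosine-centered), summed, and reduced to local rms contrast in a
    Gaussian window of SD ``s_e``; where both components vanish lambda = 1.
    """
    ax, X, Y = _grid(params)
    R = np.hypot(X, Y)
    f = stimulus.spatial_frequency
    win_px = params.excitation.s / params.grid_step_deg

    tho = np.deg2rad(stimulus.target_orientation)
    # stripes along the orientation: wavevector is perpendicular to it
    phase_t = 2 * np.pi * f * (X * np.sin(tho) + Y * np.cos(tho))
    env_t = np.exp(-(R ** 2) / (2.0 * stimulus.target_sigma ** 2))
    pat_t = stimulus.target_contrast * env_t * np.cos(phase_t)

    thb = np.deg2rad(stimulus.background_orientation)
    phase_b = 2 * np.pi * f * (X * np.sin(thb) + Y * np.cos(thb))
    win_b = raised_cosine_window(R, radius=stimulus.background_diameter / 2.0,
                                 taper=0.5)
    pat_b = stimulus.background_contrast * win_b * np.cos(phase_b)

    c_sum = _local_rms_contrast(pat_t + pat_b, win_px)
    c_t = _local_rms_contrast(pat_t, win_px)
    c_b = _local_rms_contrast(pat_b, win_px)
    quad = np.sqrt(c_t ** 2 + c_b ** 2)
    lam = np.ones_like(quad)
    ok = quad > 1e-9
    lam[ok] = c_sum[ok] / quad[ok]
    return lam


def channel_drive(spatial_field: np.ndarray, pulse: np.ndarray,
                  kernel: Kernel, x0=(0.0, 0.0),
                  extent_deg: float = 3.0) -> np.ndarray:
    """Spatiotemporal convolution of a separable input, evaluated at ``x0``.

    The input is ``spatial_field(x) * pulse(t)``; because the kernel is
    separable the result is a scalar spatial projection times the causal
    temporal convolution of the pulse with the unit-mass gamma kernel.
    """
    n = spatial_field.shape[0]
    step = kernel.grid_step_deg
    if kernel.spatial.shape[0] > 2 * n:
        raise ValueError("spatial grid too coarse for the kernel extent")
    ax = np.linspace(-extent_deg, extent_deg, n)
    iy = int(round((x0[1] + extent_deg) / step))
    ix = int(round((x0[0] + extent_deg) / step))
    kh = kernel.spatial.shape[0] // 2
    y0, y1 = iy - kh, iy + kh + 1
    x0i, x1i = ix - kh, ix + kh + 1
    if y0 < 0 or x0i < 0 or y1 > n or x1i > n:
        raise ValueError("kernel support exceeds the grid at x0")
    s0 = float(np.sum(spatial_field[y0:y1, x0i:x1i] * kernel.spatial))
    temporal = np.convolve(pulse, kernel.temporal)[: pulse.size]
    return s0 * temporal


def normalize_response(r_e: np.ndarray, r_n: np.ndarray,
                       params: ModelParams) -> np.ndarray:
    """Divisive normalization: ``r = r_e^p / (r_n^p + r0^p)`` pointwise."""
    p = params.p
    return r_e ** p / (r_n ** p + params.r0 ** p)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

_REFERENCE_TARGET_CONTRAST = 0.24
_REFERENCE_WINDOW_MS = (50.0, 200.0)


def _channel_response(stimulus, theta_max, params, kernels):
    ke, kn = kernels
    ec_e = effective_contrast(stimulus, theta_max, params.excitation.sigma, params)
    ec_n = effective_contrast(stimulus, theta_max, params.normalization.sigma, params)
    r_e = channel_drive(ec_e.c_tb, ec_e.pulse, ke, extent_deg=params.extent_deg) \
        if ec_e.c_tb is not None else np.zeros_like(ec_e.pulse)
    r_n = channel_drive(ec_n.c_tb, ec_n.pulse, kn, extent_deg=params.extent_deg) \
        if ec_n.c_tb is not None else np.zeros_like(ec_n.pulse)
    return r_e, r_n


def _kernels(params: ModelParams):
    ke = impulse_kernel(params.excitation.s, params.excitation.a,
                        params.excitation.b, params.dt, params.grid_step_deg,
                        params.t_max)
    kn = impulse_kernel(params.normalization.s, params.normalization.a,
                        params.normalization.b, params.dt, params.grid_step_deg,
                        params.t_max)
    return ke, kn


def _reference_scale(params: ModelParams, kernels) -> float:
    """50-200 ms mean response of the 24% target-only stimulus at its own
    orientation channel; all outputs are expressed in these units."""
    stim = StimulusSpec(target_contrast=_REFERENCE_TARGET_CONTRAST,
                        duration_ms=250.0)
    r_e, r_n = _channel_response(stim, 0.0, params, kernels)
    r = normalize_response(r_e, r_n, params)
    t = np.arange(r.size) * params.dt
    lo, hi = _REFERENCE_WINDOW_MS
    sel = (t >= lo) & (t < hi)
    scale = float(r[sel].mean())
    if scale <= 0:
        raise ValueError("degenerate reference response")
    return scale


def simulate_population(stimulus: StimulusSpec,
                        params: ModelParams = ModelParams()) -> ModelResponse:
    """Simulate all 12 orientation channels for one stimulus.

    Outputs are scaled so the 24%-contrast target-only response (at the
    target's own channel) averages 1 over 50-200 ms.
    """
    kernels = _kernels(params)
    scale = _reference_scale(params, kernels)
    chans = np.asarray(params.channel_orientations, dtype=float)
    R, RE, RN = [], [], []
    for th in chans:
        r_e, r_n = _channel_response(stimulus, th, params, kernels)
        R.append(normalize_response(r_e, r_n, params) / scale)
        RE.append(r_e)
        RN.append(r_n)
    t = np.arange(len(R[0])) * params.dt
    return ModelResponse(times_ms=t, r=np.array(R), r_e=np.array(RE),
                         r_n=np.array(RN), channel_orientations=chans,
                         params=params, output_scale=scale)


def population_vector_timecourse(response: ModelResponse, frame_ms=None):
    """Complex population-vector magnitude/angle per imaging frame.

    Returns ``(frame_times_ms, magnitude, angle_deg)``.
    """
    t, rf = response.to_frames(frame_ms)
    phasor = np.exp(2j * np.deg2rad(response.channel_orientations))
    z = rf.T @ phasor
    return t, np.abs(z), wrap_orientation(np.rad2deg(np.angle(z)) / 2.0)


def background_only_peak_time(background_contrast: float = 0.12,
                              background_orientation: float = 0.0,
                              duration_ms: float = 250.0,
                              params: ModelParams = ModelParams()) -> float:
    """Frame time (ms, bin center) of the background-only population-vector
    magnitude maximum - the model's delayed-normalization signature."""
    stim = StimulusSpec(background_contrast=background_contrast,
                        background_orientation=background_orientation,
                        duration_ms=duration_ms)
    resp = simulate_population(stim, params)
    t, mag, _ = population_vector_timecourse(resp)
    return float(t[np.argmax(mag)])


def target_evoked_response(params: ModelParams = ModelParams(),
                           target_contrast: float = 0.24,
                           background_contrast: float = 0.12,
                           background_orientations=None):
    """Target-evoked (TB - B) responses across background orientations.

    Returns ``(orientations, responses)`` where ``responses[ori]`` is a dict
    with the full-channel TB, B and TB-B (12, T) arrays.
    """
    if background_orientations is None:
        background_orientations = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0)
    out = {}
    for ori in background_orientations:
        tb = simulate_population(StimulusSpec(
            target_contrast=target_contrast,
            background_contrast=background_contrast,
            background_orientation=ori), params)
        b = simulate_population(StimulusSpec(
            background_contrast=background_contrast,
            background_orientation=ori), params)
        out[float(ori)] = {"tb": tb, "b": b, "evoked": tb.r - b.r}
    return tuple(float(o) for o in background_orientations), out


def model_behavior_correlation(responses: dict, behavior_dprime: dict,
                               weights: Optional[dict] = None,
                               frame_ms: float = 10.0):
    """Per-frame weighted correlation of model target-evoked response vs d'.

    ``responses`` is the output of :func:`target_evoked_response`;
    ``behavior_dprime`` maps background orientation -> d'.  The neural value
    per orientation and frame is the 0-90 axis projection (real part of the
    complex population sum) of the target-evoked channel responses, mirroring
    the columnar-axis decoder.  Returns ``(frame_times, rho, p)`` arrays;
    frames where the correlation is undefined hold NaN.
    """
    oris = sorted(responses)
    any_resp = responses[oris[0]]["tb"]
    dt = any_resp.params.dt
    step = int(round(frame_ms / dt))
    phasor = np.exp(2j * np.deg2rad(any_resp.channel_orientations))

    proj = []
    for ori in oris:
        ev = responses[ori]["evoked"]
        nf = ev.shape[1] // step
        evf = ev[:, : nf * step].reshape(ev.shape[0], nf, step).mean(axis=2)
        proj.append((evf.T @ phasor).real)
    proj = np.array(proj)                       # (n_ori, n_frames)
    t = (np.arange(proj.shape[1]) + 0.5) * frame_ms

    y = np.array([behavior_dprime[o] for o in oris], dtype=float)
    w = np.array([weights[o] for o in oris], dtype=float) if weights \
        else np.ones_like(y)
    rho = np.full(proj.shape[1], np.nan)
    p = np.full(proj.shape[1], np.nan)
    for i in range(proj.shape[1]):
        res = weighted_correlation(proj[:, i], y, w)
        rho[i], p[i] = res.rho, res.p_value
    return t, rho, p
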