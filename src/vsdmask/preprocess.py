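"""Image stabilization, dF/F normalization, downsampling, columnar bandpass,
and flash-frequency response extraction.

Stabilization uses the separable motion model ``I(x,t) = I0(x,t) + alpha(x).v(t)``:
a single global sub-pixel translation ``v(t)`` is estimated per frame from the
central quarter of the image by phase correlation against a reference
(the mean of the pre-onset frames), and per-pixel coupling coefficients
``alpha(x)`` are then fit by least squares.  Subtracting ``alpha(x).v(t)``
removes motion artifacts including non-rigid and sub-pixel components that
pixel-shifting registration cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .synth import ImageStack


@dataclass
class MotionTrace:
    """Estimated global translation per frame and per-pixel coupling.

    ``v`` is (T, 2) in pixels, ordered (vx, vy); ``alpha`` is (2, H, W) in
    camera units per pixel of motion.  ``v_mean`` stores the mean removed
    before the alpha fit (the model is only identified up to a constant
    image, so v is mean-centered).
    """

    v: np.ndarray
    alpha: np.ndarray
    v_mean: np.ndarray


@dataclass
class FlashResponseMap:
    """Per-pixel Fourier amplitude and phase at the flash frequency."""

    amplitude: np.ndarray
    phase: np.ndarray
    flash_frequency: float
    mm_per_pixel: float = None

    def __post_init__(self):
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")


def _central_quarter(frame: np.ndarray) -> np.ndarray:
    h, w = frame.shape
    return frame[h // 4: 3 * h // 4, w // 4: 3 * w // 4]


def estimate_motion(stack: ImageStack, upsample_factor: int = 50) -> MotionTrace:
    """Estimate the global motion trace and per-pixel coupling coefficients.

    ``v(t)`` is the apparent translation of each frame's central quarter
    relative to the reference (mean of pre-onset frames, or the overall mean
    when there are none), found by phase correlation with sub-pixel
    upsampling.  ``alpha(x)`` is the per-pixel least-squares regression of
    intensity on the mean-centered ``v(t)``, so the returned pair minimizes
    ``sum_t || I(x,t) - Ibar(x) - alpha(x).v(t) ||^2`` given the translation
    estimates.  An all-constant stack returns v = 0, alpha = 0.
    """
    frames = stack.frames
    T = frames.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames to estimate motion")

    ref_slice = frames[: stack.onset_index] if stack.onset_index >= 1 else frames
    reference = _central_quarter(ref_slice.mean(axis=0))

    v = np.zeros((T, 2))
    if reference.std() > 0:
        # Hann window + mean removal: suppresses the edge/DC bias that
        # otherwise shrinks sub-pixel shift estimates on smooth images
        hann = np.outer(np.hanning(reference.shape[0]),
                        np.hanning(reference.shape[1]))
        ref_w = (reference - reference.mean()) * hann
        for t in range(T):
            moving = _central_quarter(frames[t])
            shift, _, _ = phase_cross_correlation(
                ref_w, (moving - moving.mean()) * hann,
                upsample_factor=upsample_factor, normalization=None)
            # skimage returns (row, col) displacement of moving vs reference;
            # apparent content translation is the negative, stored as (vx, vy).
            v[t] = (-shift[1], -shift[0])

    v_mean = v.mean(axis=0)
    vc = v - v_mean
    gram = vc.T @ vc
    if np.linalg.matrix_rank(gram) < 2 or np.allclose(vc, 0):
        alpha = np.zeros((2,) + frames.shape[1:])
        return MotionTrace(v=v, alpha=alpha, v_mean=v_mean)

    # least squares per pixel: alpha = (V'V)^-1 V' (I - Ibar), vectorized
    resid = frames - frames.mean(axis=0, keepdims=True)
    rhs = np.tensordot(vc, resid, axes=(0, 0))          # (2, H, W)
    alpha = np.tensordot(np.linalg.inv(gram), rhs, axes=(1, 0))
    return MotionTrace(v=v, alpha=alpha, v_mean=v_mean)


def stabilize(stack: ImageStack, motion: MotionTrace) -> ImageStack:
    """Remove the motion-related component: ``I0 = I - alpha(x).v(t)``."""
    frames = stack.frames
    if motion.alpha.shape[1:] != frames.shape[1:]:
        raise ValueError("motion trace does not match stack geometry")
    if motion.v.shape[0] != frames.shape[0]:
        raise ValueError("motion trace has wrong number of frames")
    vc = motion.v - motion.v_mean
    corrected = frames - (vc[:, 0, None, None] * motion.alpha[0][None]
                          + vc[:, 1, None, None] * motion.alpha[1][None])
    return stack.copy_with(corrected)


def delta_f_over_f(stack: ImageStack) -> ImageStack:
    """Convert raw fluorescence to dF/F = (F - F0)/F0.

    F0 is the per-pixel mean over the baseline window (default -80..0 ms
    relative to onset).  Rejects stacks whose baseline is non-positive
    anywhere, reporting the offending pixel count.
    """
    if stack.is_dff:
        raise ValueError("stack is already dF/F")
    t = stack.times_ms()
    lo, hi = stack.baseline_window_ms
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("baseline window covers no frames")
    f0 = stack.frames[sel].mean(axis=0)
    bad = f0 <= 0
    if bad.any():
        idx = np.argwhere(bad)
        raise ValueError(
            f"non-positive baseline F0 at {bad.sum()} pixels "
            f"(first at {tuple(idx[0])})")
    out = stack.copy_with(stack.frames / f0[None] - 1.0)
    out.is_dff = True
    return out


def downsample(stack: ImageStack, factor: int = 4) -> ImageStack:
    """Spatial block-mean downsampling (e.g. 512 -> 128 with factor 4)."""
    T, H, W = stack.frames.shape
    if H % factor or W % factor:
        raise ValueError("grid not divisible by downsampling factor")
    f = stack.frames.reshape(T, H // factor, factor, W // factor, factor)
    return stack.copy_with(f.mean(axis=(2, 4)))


def _annulus_mask(shape, low, high, mm_per_pixel, edge_width):
    fy = np.fft.fftfreq(shape[0], d=mm_per_pixel)
    fx = np.fft.fftfreq(shape[1], d=mm_per_pixel)
    rad = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    mask = np.zeros(shape)
    mask[(rad >= low) & (rad <= high)] = 1.0
    if edge_width > 0:
        half = edge_width / 2.0
        lo_edge = (rad > low - half) & (rad < low + half)
        mask[lo_edge] = 0.5 * (1 - np.cos(np.pi * (rad[lo_edge] - (low - half)) / edge_width))
        hi_edge = (rad > high - half) & (rad < high + half)
        mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (rad[hi_edge] - (high - half)) / edge_width))
    mask[rad == 0] = 0.0
    return mask


def bandpass_columnar(field: np.ndarray, low: float = 0.8, high: float = 3.0,
                      mm_per_pixel: float = 8.0 / 128.0,
                      edge_width: float = 0.1) -> np.ndarray:
    """Isolate the columnar spatial band of a 2D field (cycles/mm).

    A hard frequency-domain annulus with raised-cosine edges of
    ``edge_width`` cyc/mm; DC is always removed, so the output is zero-mean.
    Accepts a single field (H, W) or a stack of fields (T, H, W).
    """
    field = np.asarray(field, dtype=float)
    single = field.ndim == 2
    if single:
        field = field[None]
    nyquist = 1.0 / (2.0 * mm_per_pixel)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist + 1e-12:
        raise ValueError(f"high={high} cyc/mm is at or above Nyquist {nyquist}")
    mask = _annulus_mask(field.shape[1:], low, high, mm_per_pixel, edge_width)
    out = np.fft.ifft2(np.fft.fft2(field, axes=(1, 2)) * mask[None], axes=(1, 2)).real
    return out[0] if single else out


def bandpass_stack(stack: ImageStack, low: float = 0.8, high: float = 3.0,
                   mm_per_pixel: float = 8.0 / 128.0,
                   edge_width: float = 0.1) -> ImageStack:
    """Apply the columnar bandpass frame-by-frame to an ImageStack."""
    return stack.copy_with(bandpass_columnar(stack.frames, low, high,
                                             mm_per_pixel, edge_width))


def extract_flash_response(stack: ImageStack, flash_frequency: float = 5.0,
                           window_ms: tuple = (0.0, 1000.0),
                           mm_per_pixel: float = None) -> FlashResponseMap:
    """Per-pixel Fourier amplitude/phase at the flash frequency.

    The window (ms relative to onset) should span an integer number of flash
    periods; amplitude is scaled so a pixel following ``a*sin(2*pi*f*t)``
    reports amplitude ``a``.  Rejects windows shorter than two periods or
    that do not resolve the flash frequency onto an FFT bin.
    """
    t = stack.times_ms()
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    n = int(sel.sum())
    if n * 1000.0 / stack.frame_rate < 2 * 1000.0 / flash_frequency:
        raise ValueError("window shorter than two flash periods")
    k_exact = flash_frequency * n / stack.frame_rate
    k = int(round(k_exact))
    if abs(k - k_exact) > 1e-6 or k < 1:
        raise ValueError(
            f"flash frequency {flash_frequency} Hz not resolvable from a "
            f"{n}-frame window at {stack.frame_rate} Hz")
    spec = np.fft.fft(stack.frames[sel], axis=0)[k]
    amplitude = 2.0 * np.abs(spec) / n
    phase = np.angle(spec)
    return FlashResponseMap(amplitude=amplitude, phase=phase,
                            flash_frequency=flash_frequency,
                            mm_per_pixel=mm_per_pixel)


def preprocess_detection_stack(stack: ImageStack) -> ImageStack:
    """Standard detection-block preprocessing: stabilize, then dF/F."""
    motion = estimate_motion(stack)
    return delta_f_over_f(stabilize(stack, motion))
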