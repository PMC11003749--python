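"""Reliability-weighted retinotopic and columnar template decoding.

Templates come from the fixation block: a 2D Gaussian fit to the flashed-
target response map (retinotopic template ``H_ret``), and the per-pixel
orientation tuning of the bandpassed flashed-grating responses (columnar map
``H_ori = H_ret * A * exp(2i*theta)``).  Each template pixel is divided by
its residual variance from the detection block before projection, so noisy
pixels are down-weighted.  Three decoders are produced per frame:

* ``r_ret``   - projection onto the reliability-weighted retinotopic Gaussian;
* ``r_0-90``  - projection onto ``real(H_ori)``, positive when 0-deg-tuned
  columns dominate, negative when 90-deg-tuned columns dominate;
* ``r_theta`` - 12 channels, each the normalized response of the pixels
  preferring one 15-deg orientation bin (-75 to 90 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .preprocess import FlashResponseMap, bandpass_columnar
from .synth import ImageStack
from .utils import CHANNEL_ORIENTATIONS, wrap_orientation

COLUMN_BAND = (0.8, 3.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RetinotopicTemplate:
    """Elliptical 2D Gaussian fit of the target's retinotopic footprint."""

    center: tuple            # (row, col) pixels
    sigma_major: float       # pixels
    sigma_minor: float       # pixels
    rotation_deg: float
    amplitude: float
    offset: float
    h_ret: np.ndarray        # rendered Gaussian (amplitude, no offset)
    mm_per_pixel: Optional[float] = None

    def ellipse_mask(self, n_sd: float = 2.0) -> np.ndarray:
        """Boolean mask of pixels within ``n_sd`` SDs of the fitted Gaussian."""
        h, w = self.h_ret.shape
        yy, xx = np.mgrid[0:h, 0:w]
        th = np.deg2rad(self.rotation_deg)
        dy, dx = yy - self.center[0], xx - self.center[1]
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        return (u / self.sigma_major) ** 2 + (v / self.sigma_minor) ** 2 <= n_sd ** 2


@dataclass
class ColumnarMap:
    """Complex columnar template and its 12-bin orientation partition.

    ``h_ori = h_ret * A * exp(2i*theta)`` pixelwise; ``partitions[k]`` is the
    non-negative weight field of pixels preferring the k-th channel
    orientation, normalized to sum to 1 over its pixel subset (empty bins
    hold None and propagate as missing channels downstream).
    """

    magnitude: np.ndarray           # A(x)
    orientation: np.ndarray         # theta(x), degrees in [0, 180)
    h_ori: np.ndarray               # complex
    channel_orientations: np.ndarray
    partitions: list                # list of (H, W) arrays or None
    include_mask: np.ndarray        # pixels eligible for columnar decoding


@dataclass
class VarianceMaps:
    """Per-pixel residual variance at the retinotopic and columnar scales.

    Values are floored at the 1st percentile of the positive entries so
    reliability weights 1/sigma^2 cannot explode at quiet pixels.
    """

    retinotopic: Optional[np.ndarray] = None
    columnar: Optional[np.ndarray] = None


@dataclass
class DecodedSeries:
    """Per-frame decoder output: scalar series or (T, 12) channel matrix."""

    values: np.ndarray
    times_ms: np.ndarray
    scale: str                                  # 'retinotopic' | '0-90' | 'population'
    channel_orientations: Optional[np.ndarray] = None
    units: str = "template"

    def copy_with(self, values, **kw) -> "DecodedSeries":
        out = DecodedSeries(values=np.asarray(values),
                            times_ms=self.times_ms.copy(), scale=self.scale,
                            channel_orientations=self.channel_orientations,
                            units=self.units)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _gauss2d_model(coords, amp, cy, cx, sy, sx, rot, off):
    yy, xx = coords
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(rot) + dy * np.sin(rot)
    v = -dx * np.sin(rot) + dy * np.cos(rot)
    return (amp * np.exp(-(u ** 2) / (2 * sx ** 2) - (v ** 2) / (2 * sy ** 2))
            + off).ravel()


def fit_retinotopic_template(amplitude_map: FlashResponseMap) -> RetinotopicTemplate:
    """Fit an elliptical 2D Gaussian (plus offset) to a flash-amplitude map.

    Initialization is from image moments of the offset-subtracted map.
    Rejects maps with no interior structure (flat input).
    """
    img = np.asarray(amplitude_map.amplitude, dtype=float)
    if img.std() == 0:
        raise ValueError("flat amplitude map: no retinotopic footprint to fit")
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]

    off0 = np.percentile(img, 10)
    pos = np.clip(img - off0, 0, None)
    total = pos.sum()
    cy0 = float((yy * pos).sum() / total)
    cx0 = float((xx * pos).sum() / total)
    sy0 = float(np.sqrt(((yy - cy0) ** 2 * pos).sum() / total)) or 1.0
    sx0 = float(np.sqrt(((xx - cx0) ** 2 * pos).sum() / total)) or 1.0
    amp0 = float(img.max() - off0)

    p0 = [amp0, cy0, cx0, sy0, sx0, 0.0, off0]
    bounds = ([0, -h, -w, 1e-3, 1e-3, -np.pi, -np.inf],
              [np.inf, 2 * h, 2 * w, 4 * h, 4 * w, np.pi, np.inf])
    popt, _ = curve_fit(_gauss2d_model, (yy, xx), img.ravel(), p0=p0,
                        bounds=bounds, maxfev=20000)
    amp, cy, cx, sy, sx, rot, off = popt
    major, minor = (sx, sy) if sx >= sy else (sy, sx)
    if sy > sx:
        rot = rot + np.pi / 2.0
    rendered = _gauss2d_model((yy, xx), amp, cy, cx, sy, sx, popt[5], 0.0).reshape(h, w)
    return RetinotopicTemplate(center=(float(cy), float(cx)),
                               sigma_major=float(major), sigma_minor=float(minor),
                               rotation_deg=float(np.rad2deg(rot)),
                               amplitude=float(amp), offset=float(off),
                               h_ret=rendered,
                               mm_per_pixel=amplitude_map.mm_per_pixel)


def fit_columnar_map(grating_amplitudes: dict, template: RetinotopicTemplate,
                     band: Optional[tuple] = COLUMN_BAND,
                     include_sd: float = 2.0,
                     channel_halfwidth: float = 7.5) -> ColumnarMap:
    """Estimate per-pixel orientation tuning from flashed-grating responses.

    ``grating_amplitudes`` maps orientation (deg) -> FlashResponseMap.  Each
    amplitude map is bandpassed to the columnar band (skip with
    ``band=None``), then tuning is the vector sum
    ``sum_k resp_k * exp(2i*theta_k)``: A = modulus, theta = half the angle.
    The complex template ``H_ori = H_ret * A * exp(2i*theta)`` is windowed by
    the retinotopic template and partitioned into 12 channels of half-width
    +/-7.5 deg (a pixel exactly on a bin edge goes to the lower bin).
    """
    if len(grating_amplitudes) < 3:
        raise ValueError("need at least 3 grating orientations")
    mm = template.mm_per_pixel
    z = None
    for ori, fmap in grating_amplitudes.items():
        resp = np.asarray(fmap.amplitude, dtype=float)
        if band is not None:
            resp = bandpass_columnar(resp, band[0], band[1], mm_per_pixel=mm)
        term = resp * np.exp(2j * np.deg2rad(float(ori)))
        z = term if z is None else z + term
    magnitude = np.abs(z)
    orientation = np.rad2deg(np.angle(z)) / 2.0 % 180.0
    h_ori = template.h_ret * magnitude * np.exp(2j * np.deg2rad(orientation))

    include = template.ellipse_mask(include_sd)
    centers = CHANNEL_ORIENTATIONS
    partitions = []
    theta_signed = wrap_orientation(orientation)
    for c in centers:
        d = wrap_orientation(theta_signed - c)
        sel = (d > -channel_halfwidth) & (d <= channel_halfwidth) & include
        if not sel.any():
            partitions.append(None)
            continue
        w = np.zeros_like(magnitude)
        w[sel] = np.abs(h_ori[sel])
        s = w.sum()
        partitions.append(w / s if s > 0 else None)
    return ColumnarMap(magnitude=magnitude, orientation=orientation,
                       h_ori=h_ori, channel_orientations=centers.copy(),
                       partitions=partitions, include_mask=include)


# ---------------------------------------------------------------------------
# reliability weights
# ---------------------------------------------------------------------------

def _floor_variance(var: np.ndarray) -> np.ndarray:
    pos = var[var > 0]
    floor = np.percentile(pos, 1) if pos.size else 1e-12
    return np.maximum(var, floor)


def estimate_pixel_variance(stacks, condition_labels, scale: str = "retinotopic",
                            band: tuple = COLUMN_BAND,
                            mm_per_pixel: float = 8.0 / 128.0) -> VarianceMaps:
    """Per-pixel variance of condition-mean-subtracted residuals.

    ``stacks`` are dF/F ImageStacks from the detection block and
    ``condition_labels`` their (hashable) stimulus labels.  Each condition's
    mean time course is subtracted from its trials; residual frames are
    pooled across all trials and frames.  Conditions with a single trial
    contribute nothing; if no condition has two trials the input is
    rejected.  For the columnar scale residual frames are bandpassed first.
    """
    if scale not in ("retinotopic", "columnar"):
        raise ValueError("scale must be 'retinotopic' or 'columnar'")
    groups = {}
    for s, lab in zip(stacks, condition_labels):
        groups.setdefault(lab, []).append(s)
    sum_sq = None
    count = 0
    for lab, trials in groups.items():
        if len(trials) < 2:
            continue
        data = np.stack([t.frames for t in trials])        # (n, T, H, W)
        resid = data - data.mean(axis=0, keepdims=True)
        resid = resid.reshape(-1, *resid.shape[2:])
        if scale == "columnar":
            resid = bandpass_columnar(resid, band[0], band[1], mm_per_pixel)
        sq = (resid ** 2).sum(axis=0)
        sum_sq = sq if sum_sq is None else sum_sq + sq
        count += resid.shape[0]
    if sum_sq is None:
        raise ValueError("all conditions have a single trial; variance undefined")
    var = _floor_variance(sum_sq / count)
    if scale == "retinotopic":
        return VarianceMaps(retinotopic=var)
    return VarianceMaps(columnar=var)


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------

def _weighted_projection(frames, template_field, variance, mask=None):
    var = _floor_variance(np.asarray(variance, dtype=float)) \
        if np.any(np.asarray(variance) <= 0) else np.asarray(variance, dtype=float)
    h_hat = template_field / var
    if mask is not None:
        h_hat = np.where(mask, h_hat, 0.0)
    norm = np.linalg.norm(h_hat)
    if norm == 0:
        raise ValueError("degenerate template: zero norm after weighting")
    flat = frames.reshape(frames.shape[0], -1)
    return flat @ (h_hat.ravel() / norm)


def decode_retinotopic(stack: ImageStack, template: RetinotopicTemplate,
                       var: VarianceMaps) -> DecodedSeries:
    """Project each dF/F frame onto the reliability-weighted retinotopic
    Gaussian: ``r_ret(t) = R(x,t) . (H_ret/sigma_ret^2) / ||H_ret/sigma_ret^2||``."""
    variance = var.retinotopic if var.retinotopic is not None else \
        np.ones_like(template.h_ret)
    values = _weighted_projection(stack.frames, template.h_ret, variance)
    return DecodedSeries(values=values, times_ms=stack.times_ms(),
                         scale="retinotopic")


def decode_columnar_axis(stack: ImageStack, columnar_map: ColumnarMap,
                         var: VarianceMaps) -> DecodedSeries:
    """0-90 axis decoder on columnar-band frames.

    Positive output = net activation of target-orientation (0 deg) columns,
    negative = orthogonal (90 deg); the template is ``real(H_ori)`` weighted
    by the columnar-scale reliability.
    """
    variance = var.columnar if var.columnar is not None else \
        np.ones(columnar_map.h_ori.shape)
    values = _weighted_projection(stack.frames, columnar_map.h_ori.real,
                                  variance, mask=columnar_map.include_mask)
    return DecodedSeries(values=values, times_ms=stack.times_ms(), scale="0-90")


def decode_population(stack: ImageStack, columnar_map: ColumnarMap,
                      var: VarianceMaps) -> DecodedSeries:
    """12-channel population decoder on columnar-band frames.

    Channel k projects onto the reliability-weighted, sum-normalized weight
    field of pixels preferring the k-th orientation bin; empty bins yield
    NaN columns (missing channels, excluded downstream).
    """
    variance = var.columnar if var.columnar is not None else \
        np.ones(columnar_map.h_ori.shape)
    T = stack.frames.shape[0]
    out = np.full((T, len(columnar_map.channel_orientations)), np.nan)
    for k, part in enumerate(columnar_map.partitions):
        if part is None:
            continue
        out[:, k] = _weighted_projection(stack.frames, part, variance)
    return DecodedSeries(values=out, times_ms=stack.times_ms(),
                         scale="population",
                         channel_orientations=columnar_map.channel_orientations.copy())
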