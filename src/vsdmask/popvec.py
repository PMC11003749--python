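"""Population tuning vectors and trajectory summaries.

The 12 orientation-channel responses are summed into a complex vector with
angle-doubled phases, ``z = sum_k r_k * exp(2i*theta_k)``: half its argument
is the decoded orientation, its modulus the tuning magnitude, and the
modulus divided by ``sum_k |r_k|`` a 0-1 coherence used to mask frames with
no reliable peak.  Negative channel values are retained in the sum (they
rotate the vector by 90 deg), matching the balanced +/- decomposition of a
zero-mean columnar signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import DecodedSeries
from .utils import wrap_orientation


@dataclass
class PopulationTrajectory:
    """Per-frame population vector with a coherence-masked heading."""

    times_ms: np.ndarray
    magnitude: np.ndarray
    angle_deg: np.ndarray           # in [-90, 90)
    coherence: np.ndarray           # in [0, 1]
    tuning: np.ndarray              # (T, 12) channel values
    peak_orientation: np.ndarray    # angle where coherence > threshold, else NaN
    coherence_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.times_ms, "magnitude": self.magnitude,
            "angle_deg": self.angle_deg, "coherence": self.coherence,
            "masked": ~np.isfinite(self.peak_orientation)})


def population_vector(tuning, channel_orientations):
    """Complex population vector of one 12-channel tuning curve.

    Missing channels (NaN) are excluded; if all are missing the result is
    (nan, nan, nan).  Returns ``(magnitude, angle_deg, coherence)`` with the
    angle in [-90, 90).
    """
    r = np.asarray(tuning, dtype=float)
    th = np.asarray(channel_orientations, dtype=float)
    ok = np.isfinite(r)
    if not ok.any():
        return (np.nan, np.nan, np.nan)
    z = np.sum(r[ok] * np.exp(2j * np.deg2rad(th[ok])))
    mag = float(np.abs(z))
    denom = float(np.abs(r[ok]).sum())
    coh = mag / denom if denom > 0 else 0.0
    ang = float(wrap_orientation(np.rad2deg(np.angle(z)) / 2.0)) if mag > 0 else 0.0
    return (mag, ang, coh)


def population_vector_series(series: DecodedSeries):
    """Vectorized population vector over a (T, 12) decoded series.

    Returns ``(magnitude, angle_deg, coherence)`` arrays of length T.
    """
    r = np.asarray(series.values, dtype=float)
    th = np.asarray(series.channel_orientations, dtype=float)
    phasor = np.exp(2j * np.deg2rad(th))
    rz = np.where(np.isfinite(r), r, 0.0)
    z = rz @ phasor
    mag = np.abs(z)
    denom = np.abs(rz).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, mag / denom, 0.0)
    ang = wrap_orientation(np.rad2deg(np.angle(z)) / 2.0)
    all_missing = ~np.isfinite(r).any(axis=1)
    mag[all_missing] = np.nan
    coh[all_missing] = np.nan
    ang = np.where(all_missing, np.nan, ang)
    return mag, ang, coh


def target_evoked_series(tb: DecodedSeries, b: DecodedSeries) -> DecodedSeries:
    """Target-evoked response: (target+background) minus background-only.

    Both inputs are condition-mean decoded series on the same frame grid and
    matched background condition; the subtraction is frame-wise (and
    channel-wise for population series).
    """
    if tb.values.shape != b.values.shape:
        raise ValueError("mismatched series shapes")
    if not np.allclose(tb.times_ms, b.times_ms):
        raise ValueError("mismatched frame grids")
    if tb.scale != b.scale:
        raise ValueError("mismatched decoder scales")
    return tb.copy_with(tb.values - b.values)


def trajectory_summary(series: DecodedSeries,
                       coherence_threshold: float = 0.2) -> PopulationTrajectory:
    """Per-frame population vector with the heading masked at low coherence.

    The peak orientation is reported only for frames whose normalized vector
    amplitude (coherence) exceeds ``coherence_threshold``.
    """
    if not 0.0 <= coherence_threshold < 1.0:
        raise ValueError("coherence threshold must be in [0, 1)")
    mag, ang, coh = population_vector_series(series)
    peak = np.where(np.nan_to_num(coh) > coherence_threshold, ang, np.nan)
    return PopulationTrajectory(
        times_ms=series.times_ms.copy(), magnitude=mag, angle_deg=ang,
        coherence=coh, tuning=np.asarray(series.values, dtype=float).copy(),
        peak_orientation=peak, coherence_threshold=coherence_threshold)


def pool_mirrored(series_by_orientation: dict) -> dict:
    """Pool clockwise/anticlockwise backgrounds of equal disparity.

    Input maps signed background orientation -> (T, 12) DecodedSeries; the
    negative-orientation member of each pair has its channel axis mirrored
    (channel at +theta swapped with -theta) before averaging, so pooled
    trajectories share a common heading convention.
    """
    out = {}
    done = set()
    for ori, s in series_by_orientation.items():
        key = abs(float(ori))
        if key in done:
            continue
        partner = next((o for o in series_by_orientation
                        if o != ori and abs(float(o)) == key), None)
        if partner is None:
            out[key] = s
        else:
            pos = s if float(ori) >= 0 else series_by_orientation[partner]
            neg = series_by_orientation[partner] if float(ori) >= 0 else s
            th = pos.channel_orientations
            mirror_idx = [int(np.argmin(np.abs(wrap_orientation(th - (-t0)))))
                          for t0 in th]
            mirrored = neg.values[:, mirror_idx]
            out[key] = pos.copy_with((pos.values + mirrored) / 2.0)
        done.add(key)
    return out
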