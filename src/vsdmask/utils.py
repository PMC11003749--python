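"""Small shared numerical helpers: orientation arithmetic and windows.

Orientations are in degrees with 180-degree periodicity throughout the
package; 0 deg is the (horizontal) target orientation and reported values
live in [-90, 90).
"""

from __future__ import annotations

import numpy as np

#: Channel centers of the 12-bin orientation partition, degrees.
CHANNEL_ORIENTATIONS = np.arange(-75.0, 90.1, 15.0)


def wrap_orientation(theta_deg):
    """Wrap orientation(s) to the interval [-90, 90) with 180-deg period."""
    return (np.asarray(theta_deg, dtype=float) + 90.0) % 180.0 - 90.0


def orientation_difference(a_deg, b_deg):
    """Smallest signed orientation difference a - b, wrapped to [-90, 90)."""
    return wrap_orientation(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def circular_orientation_correlation(a_deg, b_deg):
    """Correlation between two orientation maps on the doubled-angle circle.

    Both inputs are orientation angles in degrees (period 180).  The maps are
    mapped to unit phasors ``exp(2i*theta)`` and the magnitude-normalized
    inner product after removing any constant rotation is returned, so a
    perfect match (up to a global rotation) yields 1.
    """
    za = np.exp(2j * np.deg2rad(np.asarray(a_deg, float).ravel()))
    zb = np.exp(2j * np.deg2rad(np.asarray(b_deg, float).ravel()))
    c = np.vdot(zb, za) / za.size
    return float(np.abs(c))


def raised_cosine_window(r, radius, taper):
    """Circular window: 1 inside, cosine taper of width ``taper`` to 0 at ``radius``.

    Parameters
    ----------
    r : ndarray
        Radial coordinate (same units as ``radius``).
    radius : float
        Outer radius where the window reaches zero.
    taper : float
        Width of the raised-cosine transition band just inside ``radius``.
    """
    r = np.asarray(r, dtype=float)
    w = np.ones_like(r)
    inner = radius - taper
    edge = (r > inner) & (r < radius)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (r[edge] - inner) / taper))
    w[r >= radius] = 0.0
    return w


def gaussian_2d(shape, center, sigma, amplitude=1.0, offset=0.0):
    """Render an isotropic 2D Gaussian on a pixel grid.

    ``center`` and ``sigma`` are in pixels (row, col order for center).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    g = amplitude * np.exp(-(((yy - cy) ** 2) + ((xx - cx) ** 2)) / (2.0 * sigma ** 2))
    return g + offset


def spawn_rngs(seed, n):
    """Derive ``n`` independent child generators from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
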