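"""Circular arithmetic for orientations.

Orientations live on a circle of period pi (a grating rotated by 180 degrees
is the same stimulus), canonically represented in the half-open interval
[-pi/2, pi/2).  All wrapping helpers here respect that period; none of them
are suitable for *directions* (period 2*pi).
"""

from __future__ import annotations

import numpy as np

#: Period of the orientation circle.
PERIOD = np.pi

#: Canonical half-open range [-pi/2, pi/2).
LOW, HIGH = -np.pi / 2, np.pi / 2


def wrap_orientation(theta):
    """Wrap angles (radians) into the canonical range [-pi/2, pi/2).

    Accepts scalars or arrays; always returns a value strictly below pi/2,
    so every orientation has exactly one representative.
    """
    return (np.asarray(theta) + HIGH) % PERIOD + LOW if np.ndim(theta) else float(
        (theta + HIGH) % PERIOD + LOW
    )


def delta_po(a, b):
    """Signed orientation difference ``a - b`` wrapped into (-pi/2, pi/2].

    The boundary case (difference of exactly pi/2, e.g. orthogonal
    preferences) is reported as +pi/2.
    """
    d = (np.asarray(a) - np.asarray(b) + HIGH) % PERIOD + LOW
    d = np.where(d == LOW, HIGH, d)
    return float(d) if d.ndim == 0 else d


def circular_mean_orientation(angles, weights=None):
    """Weighted circular mean of orientations via the doubled-angle resultant.

    Returns NaN when the resultant vanishes (no meaningful mean).
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    z = np.sum(np.asarray(weights, dtype=float) * np.exp(2j * angles))
    if abs(z) < 1e-12:
        return float("nan")
    return wrap_orientation(0.5 * np.angle(z))
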