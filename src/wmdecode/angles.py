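"""Angle conventions used throughout the package.

All angles are polar angles in degrees. Absolute positions live on the
half-open circle ``[0, 360)``; signed differences are wrapped to
``(-180, 180]`` so that the antipode maps to +180, never -180.
"""

from __future__ import annotations

import numpy as np


def wrap360(angle):
    """Map angle(s) to the half-open interval [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def wrap180(angle):
    """Wrap signed angular difference(s) to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a - 360.0 * np.floor(a / 360.0 + 0.5)
    # floor-based wrap yields [-180, 180); move -180 to +180
    return np.where(wrapped == -180.0, 180.0, wrapped)


def ang_diff(a, b):
    """Signed difference a - b wrapped to (-180, 180]."""
    return wrap180(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def ang_dist(a, b):
    """Unsigned circular distance in [0, 180]."""
    return np.abs(ang_diff(a, b))
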