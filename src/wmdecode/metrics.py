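"""Reconstruction metrics: fidelity and circular-mean position decoding.

Fidelity projects an aligned reconstruction onto cos(theta),
F = mean_g r(theta_g) cos(theta_g): positive when net activation points at
the aligned position, and exactly invariant to any constant baseline on a
uniform full-circle grid (the mean of cos over the circle is zero).

The decoded position is the circular mean of the reconstruction,
WM_est = atan2(sum r sin(theta), sum r cos(theta)); negative activations
are kept as-is in both metrics (no rectification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import wrap180, wrap360
from .iem import Reconstruction

#: resultant lengths below EPS_FRAC * mean|r| are treated as undefined
EPS_FRAC = 1e-9


class UndefinedAngleError(ValueError):
    """The reconstruction's resultant vector is too short to define an angle."""


@dataclass(frozen=True)
class DecodedAngle:
    angle: float                 # degrees in [0, 360)
    resultant_length: float      # diagnostic, same units as r


def fidelity(recon: Reconstruction) -> float:
    """F = mean(r(theta) * cos(theta)) over the aligned reconstruction grid."""
    if recon.aligned_to is None:
        raise ValueError("reconstruction must be aligned before computing fidelity")
    theta = np.deg2rad(recon.grid)
    return float(np.mean(recon.activation * np.cos(theta)))


def decode_angle(recon: Reconstruction) -> DecodedAngle:
    """Circular mean of the reconstruction, as a position in [0, 360).

    Raises
    ------
    UndefinedAngleError
        If the resultant is numerically zero (flat or antipodally
        symmetric reconstructions have no defined circular mean).
    """
    theta = np.deg2rad(recon.grid)
    x = float(np.sum(recon.activation * np.cos(theta)))
    y = float(np.sum(recon.activation * np.sin(theta)))
    resultant = float(np.hypot(x, y))
    scale = float(np.mean(np.abs(recon.activation)))
    if resultant <= EPS_FRAC * max(scale, np.finfo(float).tiny) * recon.grid.size:
        raise UndefinedAngleError(
            f"resultant length {resultant:.3e} below threshold; "
            "circular mean undefined")
    return DecodedAngle(angle=float(wrap360(np.rad2deg(np.arctan2(y, x)))),
                        resultant_length=resultant)


def decoding_error(decoded: DecodedAngle | float, truth: float) -> float:
    """Signed decoded-minus-true angle wrapped to (-180, 180]."""
    angle = decoded.angle if isinstance(decoded, DecodedAngle) else float(decoded)
    return float(wrap180(angle - float(truth)))
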