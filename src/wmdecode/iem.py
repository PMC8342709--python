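"""Inverted encoding model (IEM) of polar angle.

The model treats each voxel's response as a linear combination of a small
set of smooth, circularly tuned information channels. Training data with
known stimulus angles give the channel-to-voxel weight matrix by ordinary
least squares (B = C W); test activity is mapped back into channel space
with the weights' pseudo-inverse, and a weighted sum of the channel
profiles over a dense angular grid yields the stimulus-space
reconstruction.

Channel basis: half-wave-rectified raised cosine raised to a power,

    f_i(theta) = 0.5 + 0.5 * cos(180 * (theta - psi_i) / (2 s))^p
                 for wrapped |theta - psi_i| < s, else 0,

with the cosine argument in degrees, size constant ``s = 180`` degrees and
``p = 8`` by default; eight channel centers ``psi_i`` tile the circle
evenly. Two precedence conventions exist for the exponent; the default
(``power_on_cosine``) raises the cosine alone to the power, and
``power_on_sum`` raises the whole half-raised cosine instead. Both modes
satisfy f_i(psi_i) = 1 and vanish outside the support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .angles import ang_dist

#: reciprocal-condition-number floor below which matrix inversions refuse to run
RCOND_MIN = 1e-10


class IllConditionedError(np.linalg.LinAlgError):
    """A design or weight matrix is rank deficient / numerically singular."""


@dataclass(frozen=True)
class ChannelBasis:
    """Circular channel basis over polar angle.

    Parameters
    ----------
    centers : array of channel centers psi_i in degrees, distinct mod 360.
    size_constant : support half-width s in degrees (> 0).
    exponent : positive integer power applied per ``precedence_mode``.
    precedence_mode : 'power_on_cosine' (default) or 'power_on_sum'.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.arange(8) * 45.0)
    size_constant: float = 180.0
    exponent: int = 8
    precedence_mode: Literal["power_on_cosine", "power_on_sum"] = "power_on_cosine"

    def __post_init__(self):
        centers = np.atleast_1d(np.asarray(self.centers, dtype=float)) % 360.0
        if np.unique(centers).size != centers.size:
            raise ValueError("channel centers must be distinct modulo 360")
        if self.size_constant <= 0:
            raise ValueError("size_constant must be positive")
        if self.exponent < 1 or int(self.exponent) != self.exponent:
            raise ValueError("exponent must be a positive integer")
        if self.precedence_mode not in ("power_on_cosine", "power_on_sum"):
            raise ValueError(f"unknown precedence_mode {self.precedence_mode!r}")
        object.__setattr__(self, "centers", centers)

    @property
    def n_channels(self) -> int:
        return self.centers.size


def channel_response(theta, basis: ChannelBasis) -> np.ndarray:
    """Evaluate every channel at stimulus angle(s) ``theta``.

    Returns shape ``(k,)`` for scalar theta, else ``theta.shape + (k,)``.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    scalar = theta.ndim == 0
    d = ang_dist(np.atleast_1d(theta)[:, None], basis.centers[None, :])
    arg_deg = 180.0 * d / (2.0 * basis.size_constant)
    cos_term = np.cos(np.deg2rad(arg_deg))
    if basis.precedence_mode == "power_on_cosine":
        f = 0.5 + 0.5 * cos_term ** basis.exponent
    else:
        f = (0.5 + 0.5 * cos_term) ** basis.exponent
    f = np.where(d < basis.size_constant, f, 0.0)
    return f[0] if scalar else f


def predicted_channel_matrix(angles, basis: ChannelBasis) -> np.ndarray:
    """Design matrix C (n stimuli x k channels), one row per stimulus angle."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.ndim != 1 or angles.size < 1:
        raise ValueError("angles must be a non-empty 1-D sequence")
    return channel_response(angles, basis)


@dataclass(frozen=True)
class EncodingModel:
    """Frozen estimated encoding model: basis + weights (k channels x m voxels).

    Immutable after estimation so that every reconstruction of any
    timepoint or condition is read out through one fixed model.
    """

    basis: ChannelBasis
    weights: np.ndarray
    training_window: tuple[float, float] | None = None
    n_training_trials: int | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != self.basis.n_channels:
            raise ValueError("weights must be (k channels x m voxels)")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


def _check_conditioning(square: np.ndarray, what: str) -> None:
    sv = np.linalg.svd(square, compute_uv=False)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if not np.isfinite(rcond) or rcond < RCOND_MIN:
        raise IllConditionedError(
            f"{what} is ill-conditioned (reciprocal condition number "
            f"{rcond:.3e} < {RCOND_MIN:.0e})")


def estimate_weights(C_trn: np.ndarray, B_trn: np.ndarray,
                     basis: ChannelBasis,
                     training_window: tuple[float, float] | None = None
                     ) -> EncodingModel:
    """Normal-equation weight estimate W_hat = (C'C)^-1 C'B.

    ``C_trn`` is (n trials x k channels), ``B_trn`` (n trials x m voxels);
    requires n >= k and a well-conditioned C_trn.
    """
    C = np.asarray(C_trn, dtype=float)
    B = np.asarray(B_trn, dtype=float)
    if C.ndim != 2 or B.ndim != 2 or C.shape[0] != B.shape[0]:
        raise ValueError("C_trn (n x k) and B_trn (n x m) must share n rows")
    n, k = C.shape
    if n < k:
        raise ValueError(
            f"underdetermined: {n} training trials for {k} channels")
    ctc = C.T @ C
    _check_conditioning(ctc, "C_trn' C_trn")
    W = np.linalg.solve(ctc, C.T @ B)
    return EncodingModel(basis=basis, weights=W,
                         training_window=training_window,
                         n_training_trials=n)


def invert(B_tst: np.ndarray, model: EncodingModel) -> np.ndarray:
    """Estimated channel responses C_tst = B_tst W' (W W')^-1.

    ``B_tst`` is (t observations x m voxels); returns (t x k).
    """
    B = np.atleast_2d(np.asarray(B_tst, dtype=float))
    W = model.weights
    k, m = W.shape
    if B.shape[1] != m:
        raise ValueError(f"B_tst has {B.shape[1]} voxels, model has {m}")
    if m < k:
        raise ValueError(f"need at least {k} voxels to invert, got {m}")
    wwt = W @ W.T
    _check_conditioning(wwt, "W W'")
    # solve (WW') x' = (B W')' rather than forming the explicit inverse
    return np.linalg.solve(wwt, (B @ W.T).T).T


@dataclass
class Reconstruction:
    """Stimulus-space reconstruction r(theta) on a uniform full-circle grid."""

    grid: np.ndarray
    activation: np.ndarray
    aligned_to: float | None = None

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        step = 360.0 / g.size
        if g.size < 2 or not np.allclose(np.diff(g), step) or g[0] != 0.0:
            raise ValueError(
                "grid must uniformly tile [0, 360) starting at 0")
        self.grid = g
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.shape != g.shape:
            raise ValueError("activation must match grid shape")

    @property
    def grid_step(self) -> float:
        return 360.0 / self.grid.size


def default_grid(n_points: int = 360) -> np.ndarray:
    """Uniform reconstruction grid over [0, 360); default 1-degree spacing."""
    return np.arange(n_points) * (360.0 / n_points)


def reconstruct(channel_resp: np.ndarray, basis: ChannelBasis,
                grid: np.ndarray | None = None) -> Reconstruction:
    """Weighted sum of channel profiles: r(theta_g) = sum_i c_i f_i(theta_g)."""
    c = np.asarray(channel_resp, dtype=float)
    if c.shape != (basis.n_channels,):
        raise ValueError(f"expected {basis.n_channels} channel responses")
    if grid is None:
        grid = default_grid()
    profiles = channel_response(grid, basis)      # (g, k)
    return Reconstruction(grid=grid, activation=profiles @ c)


def align(recon: Reconstruction, reference: float) -> Reconstruction:
    """Circularly shift so the activation at ``reference`` appears at 0 degrees.

    The reference is snapped to the nearest grid point (ties to the lower
    angle via round-half-even on the grid index); total activation is
    preserved exactly because the shift is a pure roll.
    """
    shift = int(np.round(float(reference) / recon.grid_step)) % recon.grid.size
    return Reconstruction(grid=recon.grid,
                          activation=np.roll(recon.activation, -shift),
                          aligned_to=float(reference) % 360.0)
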