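"""Ground-truth voxel populations with spatial (pRF-like) tuning.

Each simulated voxel gets a preferred polar angle, an eccentricity, a pRF
size, a simulated variance-explained score, an angular tuning width, and
response gains for the sustained delay signal and the transient
distractor-evoked signal. These parameters stand in for fitted
population-receptive-field estimates: the simulator assigns them as
ground truth, and downstream voxel-sorting analyses consume them exactly
as they would consume fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VoxelPopulation:
    prf_angle: np.ndarray        # deg, preferred polar angle in [0, 360)
    prf_ecc: np.ndarray          # deg visual angle, >= 0
    prf_size: np.ndarray         # deg, pRF radius
    r2: np.ndarray               # simulated variance explained, [0, 1]
    tuning_width: np.ndarray     # deg, circular-Gaussian SD of angular tuning
    gain_delay: np.ndarray       # a.u., sustained delay-period amplitude
    gain_distractor: np.ndarray  # a.u., transient distractor amplitude

    def __post_init__(self):
        n = self.prf_angle.size
        for name in ("prf_ecc", "prf_size", "r2", "tuning_width",
                     "gain_delay", "gain_distractor"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.any(self.prf_ecc < 0):
            raise ValueError("prf_ecc must be non-negative")
        if np.any((self.r2 < 0) | (self.r2 > 1)):
            raise ValueError("r2 must lie in [0, 1]")
        if np.any(self.tuning_width <= 0):
            raise ValueError("tuning_width must be positive")

    @property
    def n_voxels(self) -> int:
        return self.prf_angle.size


def generate_population(n_voxels: int, seed: int = 0,
                        width_range: tuple[float, float] = (25.0, 45.0),
                        r2_range: tuple[float, float] = (0.1, 0.8),
                        ecc_range: tuple[float, float] = (2.0, 15.0),
                        ) -> VoxelPopulation:
    """Draw a voxel population with uniformly tiled polar-angle preferences.

    Angles are uniform on [0, 360); eccentricities uniform over
    ``ecc_range`` (default 2-15 deg, the band the univariate voxel
    selection uses); pRF size grows linearly with eccentricity; tuning
    widths and variance explained are uniform over their ranges; delay
    gains are lognormal around 1 and distractor gains around 0.8.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be positive")
    for name, (lo, hi) in (("width_range", width_range),
                           ("r2_range", r2_range), ("ecc_range", ecc_range)):
        if hi < lo:
            raise ValueError(f"empty {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(*ecc_range, size=n_voxels)
    return VoxelPopulation(
        prf_angle=rng.uniform(0.0, 360.0, size=n_voxels),
        prf_ecc=ecc,
        prf_size=0.5 + 0.2 * ecc,
        r2=rng.uniform(*r2_range, size=n_voxels),
        tuning_width=rng.uniform(*width_range, size=n_voxels),
        gain_delay=rng.lognormal(mean=0.0, sigma=0.25, size=n_voxels),
        gain_distractor=0.8 * rng.lognormal(mean=0.0, sigma=0.25,
                                            size=n_voxels),
    )
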