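"""BOLD-like ROI time-series simulator.

Each trial's noiseless voxel signal is built from three components on a
fine time grid, convolved with a hemodynamic response function (HRF), and
sampled on the 750 ms TR grid:

* a sustained delay-period response tuned to the memory target (optionally
  rotated by a per-trial neural bias),
* on distractor-present trials, a transient response tuned to the
  distractor location during the 1 s distractor window, and
* on distractor-present trials, a transient attenuation of the sustained
  target response while the distractor task is being performed — stimulus
  plus response period (``target_suppression``) — the simulator's
  stand-in for the interference that occurs when target and distractor
  are jointly encoded by one population.

Voxel tuning is a circular Gaussian of each voxel's ground-truth width.
Gaussian white noise is added per (trial, TR, voxel), and each voxel is
finally z-scored across all volumes of each run, mirroring standard
preprocessing. The HRF is a canonical double-gamma (peak ~5 s) normalized
to unit integral, so a long boxcar of unit amplitude plateaus near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .angles import ang_diff
from .design import EVENT_TIMES
from .population import VoxelPopulation

TR_SECONDS = 0.75
#: default TR-onset grid, seconds relative to delay onset
DEFAULT_TR_ONSETS = np.arange(-4, 20) * TR_SECONDS   # -3.0 .. 14.25 s
FINE_DT = 0.075                                      # 10 samples per TR

DELAY_WINDOW = (0.0, 12.0)
DISTRACTOR_WINDOW = (EVENT_TIMES["t_distractor"],
                     EVENT_TIMES["t_distractor"] + 1.0)
#: window over which the distractor task suppresses the sustained target
#: response: 1 s stimulus plus the discrimination-response period
SUPPRESSION_WINDOW = (EVENT_TIMES["t_distractor"],
                      EVENT_TIMES["t_distractor"] + 2.5)


@dataclass
class ROITimeseries:
    """Per-trial ROI activation: ``data`` indexed (trial, TR, voxel)."""

    data: np.ndarray
    tr_onsets: np.ndarray
    run_ids: np.ndarray            # per trial
    participant_ids: np.ndarray    # per trial
    tr_seconds: float = TR_SECONDS
    zscored: bool = False

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, TR, voxel)")
        if self.tr_onsets.shape != (self.data.shape[1],):
            raise ValueError("tr_onsets must match the TR axis")
        if self.run_ids.shape != (self.data.shape[0],) or \
           self.participant_ids.shape != (self.data.shape[0],):
            raise ValueError("run/participant ids must match the trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[2]


def double_gamma_hrf(dt: float = FINE_DT, duration: float = 30.0,
                     peak_delay: float = 5.0, undershoot_delay: float = 15.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, normalized to unit integral."""
    t = np.arange(0.0, duration, dt)
    peak = sps.gamma.pdf(t, peak_delay + 1.0)
    under = sps.gamma.pdf(t, undershoot_delay + 1.0)
    h = peak - undershoot_ratio * under
    return h / (h.sum() * dt)


def circular_tuning(delta_deg: np.ndarray, width_deg: np.ndarray) -> np.ndarray:
    """Unimodal circular-Gaussian bump, peak 1 at delta = 0."""
    d = ang_diff(delta_deg, 0.0)
    return np.exp(-0.5 * (d / width_deg) ** 2)


def _regressor(window: tuple[float, float], hrf: np.ndarray,
               tr_onsets: np.ndarray) -> np.ndarray:
    """Boxcar over ``window`` convolved with the HRF, sampled at TR onsets."""
    t0 = min(tr_onsets[0], window[0]) - 1.0
    fine = np.arange(t0, tr_onsets[-1] + TR_SECONDS, FINE_DT)
    box = ((fine >= window[0]) & (fine < window[1])).astype(float)
    conv = np.convolve(box, hrf)[:fine.size] * FINE_DT
    return np.interp(tr_onsets, fine, conv)


def simulate_timeseries(design: pd.DataFrame, pop: VoxelPopulation,
                        noise_sd: float = 1.0,
                        neural_bias: np.ndarray | float = 0.0,
                        distractor_gain: float = 2.5,
                        target_suppression: float = 0.0,
                        hrf: np.ndarray | None = None,
                        tr_onsets: np.ndarray | None = None,
                        seed: int = 0,
                        zscore: bool = True) -> ROITimeseries:
    """Simulate z-scored ROI time series for every trial of ``design``.

    Parameters
    ----------
    neural_bias : scalar or per-trial array of degrees added to the target
        angle driving the sustained neural response (the decoded angle
        inherits this bias).
    distractor_gain : overall scale of the distractor-evoked transient
        (multiplied by each voxel's ``gain_distractor``).
    target_suppression : fraction in [0, 1] by which the sustained target
        response is attenuated while the distractor task is performed
        (stimulus plus response period) on distractor-present trials.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0.0 <= target_suppression <= 1.0:
        raise ValueError("target_suppression must lie in [0, 1]")
    n_trials = len(design)
    bias = np.broadcast_to(np.asarray(neural_bias, dtype=float),
                           (n_trials,))
    if tr_onsets is None:
        tr_onsets = DEFAULT_TR_ONSETS
    if hrf is None:
        hrf = double_gamma_hrf()
    rng = np.random.default_rng(seed)

    reg_delay = _regressor(DELAY_WINDOW, hrf, tr_onsets)
    reg_dist = _regressor(DISTRACTOR_WINDOW, hrf, tr_onsets)
    reg_suppr = _regressor(SUPPRESSION_WINDOW, hrf, tr_onsets)

    target = design["target_angle"].to_numpy(float)
    present = (design["condition"] == "distractor_present").to_numpy()
    dist_angle = design["distractor_angle"].to_numpy(float)

    # (trial, voxel) tuning amplitudes
    tune_target = pop.gain_delay * circular_tuning(
        ang_diff((target + bias)[:, None], pop.prf_angle[None, :]),
        pop.tuning_width[None, :])
    tune_dist = np.zeros_like(tune_target)
    if present.any():
        tune_dist[present] = distractor_gain * pop.gain_distractor * \
            circular_tuning(
                ang_diff(dist_angle[present, None], pop.prf_angle[None, :]),
                pop.tuning_width[None, :])
    suppression = np.where(present, target_suppression, 0.0)

    # (trial, TR, voxel): sustained target + transient distractor
    # - transient suppression of the target during the distractor task
    data = (reg_delay[None, :, None] * tune_target[:, None, :]
            + reg_dist[None, :, None] * tune_dist[:, None, :]
            - reg_suppr[None, :, None]
            * (suppression[:, None] * tune_target)[:, None, :])
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    ts = ROITimeseries(
        data=data, tr_onsets=np.asarray(tr_onsets, dtype=float),
        run_ids=design["run_id"].to_numpy(),
        participant_ids=design["participant_id"].to_numpy(), zscored=False)
    return zscore_per_run(ts) if zscore else ts


def zscore_per_run(ts: ROITimeseries) -> ROITimeseries:
    """Z-score each voxel over all volumes of each (participant, run)."""
    data = ts.data.copy()
    groups = pd.DataFrame({"p": ts.participant_ids, "r": ts.run_ids})
    for sel in groups.groupby(["p", "r"]).indices.values():
        block = data[sel]                       # (trials, TR, voxel)
        flat = block.reshape(-1, block.shape[-1])
        sd = flat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        data[sel] = (block - flat.mean(axis=0)) / sd
    return replace(ts, data=data, zscored=True)
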