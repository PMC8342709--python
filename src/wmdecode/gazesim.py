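"""Synthetic 500 Hz gaze traces for memory-guided saccade trials.

Each trial fixates the center through the delay, then executes a single
main-sequence-like saccade to the recorded behavioral endpoint after the
response cue. The saccade follows a raised-cosine position profile whose
duration scales with amplitude (~21 ms + 2.2 ms/deg), giving realistic
peak velocities well above detection threshold for the 12-degree
eccentricity used here. Optional blinks (validity dropouts) and white
positional jitter can be layered on. Ground-truth saccade onsets,
offsets and endpoints are returned with each trace so detector accuracy
can be measured exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gaze import SAMPLE_RATE_HZ, GazeRecord


def _saccade_duration_s(amplitude_deg: float) -> float:
    return 0.021 + 0.0022 * amplitude_deg


def synth_trial_trace(endpoint_xy: tuple[float, float],
                      rt_s: float = 0.35,
                      t_response_cue: float = 12.0,
                      t_target_return: float = 12.8,
                      t_start: float = -1.0,
                      t_end: float = 14.0,
                      noise_sd: float = 0.0,
                      blink_windows: list[tuple[float, float]] | None = None,
                      fs: float = SAMPLE_RATE_HZ,
                      rng: np.random.Generator | None = None) -> GazeRecord:
    """One trial's trace: fixation, then a saccade to ``endpoint_xy``."""
    if rng is None:
        rng = np.random.default_rng(0)
    time = np.arange(t_start, t_end, 1.0 / fs)
    x = np.zeros_like(time)
    y = np.zeros_like(time)
    ex, ey = endpoint_xy
    amp = float(np.hypot(ex, ey))
    # snap the onset to the sampling grid so ground truth is exact
    onset = t_start + round((t_response_cue + rt_s - t_start) * fs) / fs
    dur = _saccade_duration_s(amp)
    phase = np.clip((time - onset) / dur, 0.0, 1.0)
    profile = 0.5 * (1.0 - np.cos(np.pi * phase))
    x += ex * profile
    y += ey * profile
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=time.size)
        y += rng.normal(0.0, noise_sd, size=time.size)
    valid = np.ones(time.size, dtype=bool)
    for b0, b1 in blink_windows or []:
        valid &= ~((time >= b0) & (time < b1))
    return GazeRecord(
        time=time, x=x, y=y, valid=valid,
        events={"delay_start": 0.0, "response_cue": t_response_cue,
                "target_return": t_target_return},
        fixation_epochs=[(t_start, 0.0)],
        truth={"saccade_onset": onset, "saccade_offset": onset + dur,
               "endpoint": (ex, ey), "amplitude": amp, "rt_s": rt_s})


def simulate_gaze(design: pd.DataFrame, behavior: pd.DataFrame,
                  target_ecc: float = 12.0,
                  blink_rate: float = 0.0,
                  noise_sd: float = 0.0,
                  seed: int = 0) -> list[GazeRecord]:
    """Gaze traces for every trial, landing at the behavioral endpoints.

    ``blink_rate`` is the expected number of ~150 ms blinks per trial
    (Poisson); blinks are placed uniformly inside the delay period.
    """
    rng = np.random.default_rng(seed)
    records = []
    for (_, trial), (_, beh) in zip(design.iterrows(), behavior.iterrows()):
        angle = np.deg2rad(beh["saccade_endpoint_angle"])
        endpoint = (target_ecc * np.cos(angle), target_ecc * np.sin(angle))
        blinks = []
        for _ in range(rng.poisson(blink_rate)):
            b0 = rng.uniform(0.5, 11.0)
            blinks.append((b0, b0 + 0.15))
        rec = synth_trial_trace(
            endpoint, rt_s=beh["rt_ms"] / 1000.0,
            t_response_cue=trial["t_response"],
            t_target_return=trial["t_response"] + 0.8,
            noise_sd=noise_sd, blink_windows=blinks, rng=rng)
        rec.truth["target_angle"] = trial["target_angle"]
        records.append(rec)
    return records
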