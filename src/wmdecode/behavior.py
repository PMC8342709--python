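"""Behavioral simulators: memory-guided saccade endpoints and the
adaptive-staircase observer.

Saccade endpoint errors are generated as

    memory_error = rho * neural_bias + attract_bias * s + N(0, motor_sd)

wrapped to (-180, 180], where ``s`` is the sign pointing from the target
toward the distractor (0 on distractor-absent trials). ``rho`` couples
behavioral error to the trial-wise neural bias that also drives the
simulated BOLD signal, letting the neural-behavioral correlation analyses
be exercised with known ground truth.

The staircase simulator implements the classic 3-down/1-up rule: three
consecutive correct responses make the task harder by one step, any error
makes it easier. Its accuracy fixed point is the difficulty where
P(correct)^3 = 0.5, i.e. P ~ 0.794 — the "~80%" operating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .angles import wrap180, wrap360

BEHAVIOR_COLUMNS = ["participant_id", "run_id", "trial_id",
                    "saccade_endpoint_angle", "memory_error", "rt_ms",
                    "excluded", "exclusion_reason"]


def simulate_behavior(design: pd.DataFrame,
                      neural_bias: np.ndarray | float = 0.0,
                      coupling: float = 0.0,
                      attract_bias: float = 0.0,
                      motor_sd: float = 5.0,
                      rt_mean_ms: float = 350.0,
                      rt_sd_ms: float = 60.0,
                      seed: int = 0) -> pd.DataFrame:
    """Per-trial saccade endpoints, memory errors, and reaction times.

    ``attract_bias`` (degrees) pulls responses toward the distractor on
    present trials; ``coupling`` is the slope rho on the per-trial
    neural bias. Reaction times are Gaussian, floored at 100 ms.
    """
    if motor_sd < 0:
        raise ValueError("motor_sd must be non-negative")
    n = len(design)
    bias = np.broadcast_to(np.asarray(neural_bias, dtype=float), (n,))
    rng = np.random.default_rng(seed)
    present = (design["condition"] == "distractor_present").to_numpy()
    rel = design["relative_distractor_angle"].to_numpy(float)
    toward = np.where(present, np.sign(np.nan_to_num(rel)), 0.0)
    noise = rng.normal(0.0, motor_sd, size=n) if motor_sd > 0 else np.zeros(n)
    error = wrap180(coupling * bias + attract_bias * toward + noise)
    rt = np.maximum(rng.normal(rt_mean_ms, rt_sd_ms, size=n), 100.0)
    return pd.DataFrame({
        "participant_id": design["participant_id"].to_numpy(),
        "run_id": design["run_id"].to_numpy(),
        "trial_id": design["trial_id"].to_numpy(),
        "saccade_endpoint_angle": wrap360(
            design["target_angle"].to_numpy(float) + error),
        "memory_error": error,
        "rt_ms": rt,
        "excluded": np.zeros(n, dtype=bool),
        "exclusion_reason": [""] * n,
    })


@dataclass(frozen=True)
class StaircaseResult:
    coherence: np.ndarray     # difficulty level presented on each trial
    correct: np.ndarray       # response accuracy per trial
    converged_accuracy: float  # post-burn-in proportion correct
    burn_in_fraction: float


def simulate_staircase(psychometric: Callable[[float], float],
                       n_trials: int = 10_000,
                       step: float = 0.02,
                       start: float = 0.9,
                       bounds: tuple[float, float] = (0.0, 1.0),
                       burn_in_fraction: float = 0.25,
                       seed: int = 0) -> StaircaseResult:
    """Run a 3-down/1-up staircase against a stochastic observer.

    ``psychometric`` maps a difficulty value (e.g., motion coherence,
    higher = easier) to P(correct) and must be monotone non-decreasing;
    this is spot-checked on a coarse grid. The first
    ``burn_in_fraction`` of trials is discarded before computing the
    converged proportion correct.
    """
    if n_trials < 8:
        raise ValueError("n_trials too small for a meaningful staircase")
    lo, hi = bounds
    probe = np.linspace(lo, hi, 9)
    pvals = np.array([psychometric(c) for c in probe])
    if np.any(np.diff(pvals) < -1e-12):
        raise ValueError("psychometric function must be monotone increasing")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("psychometric values must be probabilities")

    rng = np.random.default_rng(seed)
    coherence = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    level = float(np.clip(start, lo, hi))
    streak = 0
    for t in range(n_trials):
        coherence[t] = level
        ok = rng.random() < psychometric(level)
        correct[t] = ok
        if ok:
            streak += 1
            if streak == 3:               # harder: lower coherence
                level = max(level - step, lo)
                streak = 0
        else:                             # easier: raise coherence
            level = min(level + step, hi)
            streak = 0
    burn = int(np.floor(burn_in_fraction * n_trials))
    return StaircaseResult(coherence=coherence, correct=correct,
                           converged_accuracy=float(correct[burn:].mean()),
                           burn_in_fraction=burn_in_fraction)
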