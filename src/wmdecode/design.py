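"""Trial-design generators for the memory-guided saccade experiment.

The main experiment mixes two pre-cued conditions within every 10-trial
run: 7 distractor-present and 3 distractor-absent trials in random order
(a 70/30 mix). On present trials the distractor appears at one of seven
counterbalanced angular offsets from the memory target — each offset bin
occurs exactly once per run — jittered by +/-12 degrees of polar angle.
Targets are drawn uniformly around the circle.

A separate distractor-free design trains the encoding model: 16 targets
evenly spaced (22.5 degrees apart) per run, with the grid staggered by
half a spacing on every other run so two consecutive runs tile 32 unique
positions.

Timing is expressed in seconds relative to delay onset and kept on the
750 ms TR grid: pre-cue at -2.25 s, target at -0.75 s (500 ms), delay
from 0 to 12 s, distractor at 4.5 s (1000 ms), response cue at 12 s.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import wrap180, wrap360

#: absolute target-distractor separations (deg) of the seven offset bins
DEFAULT_BIN_CENTERS = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0])
JITTER_DEG = 12.0

N_PRESENT_PER_RUN = 7
N_ABSENT_PER_RUN = 3

EVENT_TIMES = {
    "t_cue": -2.25,
    "t_target": -0.75,
    "t_delay": 0.0,
    "t_distractor": 4.5,
    "t_response": 12.0,
}

TRIAL_COLUMNS = [
    "participant_id", "run_id", "trial_id", "condition", "target_angle",
    "distractor_angle", "distractor_bin", "relative_distractor_angle",
    *EVENT_TIMES,
]


def generate_design(n_runs: int, n_participants: int = 1, seed: int = 0,
                    bin_centers: np.ndarray | None = None) -> pd.DataFrame:
    """Generate the experimental trial table.

    Returns a tidy DataFrame, one row per trial, with 10 trials per run
    (7 present / 3 absent). ``distractor_bin`` is 1..7 (NaN on absent
    trials) and indexes ``bin_centers`` sorted ascending; the signed
    relative distractor angle is ``sign * (center + U(-12, 12))`` with a
    random sign, wrapped to (-180, 180].
    """
    if n_runs < 1 or n_participants < 1:
        raise ValueError("n_runs and n_participants must be positive")
    centers = DEFAULT_BIN_CENTERS if bin_centers is None else \
        np.sort(np.asarray(bin_centers, dtype=float))
    if centers.size != 7 or np.unique(centers).size != 7:
        raise ValueError("exactly 7 distinct bin centers required")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"sub{p + 1:02d}"
        for run in range(n_runs):
            conditions = np.array(
                ["distractor_present"] * N_PRESENT_PER_RUN
                + ["distractor_absent"] * N_ABSENT_PER_RUN)
            rng.shuffle(conditions)
            bin_order = rng.permutation(7)
            b = 0
            for t, cond in enumerate(conditions):
                target = float(rng.uniform(0.0, 360.0))
                if cond == "distractor_present":
                    bin_idx = int(bin_order[b]); b += 1
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    rel = float(wrap180(
                        sign * (centers[bin_idx]
                                + rng.uniform(-JITTER_DEG, JITTER_DEG))))
                    dist = float(wrap360(target + rel))
                    row_bin: float | int = bin_idx + 1
                else:
                    rel, dist, row_bin = np.nan, np.nan, np.nan
                rows.append((pid, run, t, cond, target, dist, row_bin, rel,
                             *EVENT_TIMES.values()))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["distractor_bin"] = df["distractor_bin"].astype("Float64")
    return df


def generate_training_design(n_runs: int, n_participants: int = 1,
                             seed: int = 0) -> pd.DataFrame:
    """Distractor-free model-estimation design with staggered target grids.

    Each 16-trial run samples targets 22.5 degrees apart; odd runs are
    offset by 11.25 degrees, so any even/odd run pair covers 32 unique
    positions. Trial order within a run is randomized under ``seed``.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for the staggered design")
    if n_participants < 1:
        raise ValueError("n_participants must be positive")
    rng = np.random.default_rng(seed)
    spacing = 360.0 / 16
    rows = []
    for p in range(n_participants):
        pid = f"sub{p + 1:02d}"
        for run in range(n_runs):
            offset = (run % 2) * spacing / 2.0
            angles = rng.permutation(wrap360(np.arange(16) * spacing + offset))
            for t, target in enumerate(angles):
                rows.append((pid, run, t, "distractor_absent", float(target),
                             np.nan, np.nan, np.nan, *EVENT_TIMES.values()))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["distractor_bin"] = df["distractor_bin"].astype("Float64")
    return df


def validate_design(df: pd.DataFrame) -> None:
    """Raise AssertionError if the experimental-design invariants fail."""
    present = df["condition"] == "distractor_present"
    assert df.loc[~present, "distractor_angle"].isna().all()
    assert df.loc[~present, "distractor_bin"].isna().all()
    assert df.loc[present, "distractor_angle"].notna().all()
    for (_, _), run in df.groupby(["participant_id", "run_id"]):
        pres = run[run["condition"] == "distractor_present"]
        assert len(pres) == N_PRESENT_PER_RUN
        assert len(run) - len(pres) == N_ABSENT_PER_RUN
        assert sorted(pres["distractor_bin"].astype(int)) == list(range(1, 8))
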