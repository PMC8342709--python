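"""Gaze preprocessing and memory-guided saccade scoring.

The pipeline mirrors standard eye-tracking practice for memory-guided
saccade tasks: convert to degrees of visual angle, drop blinks and
extreme values, smooth with a 5 ms SD Gaussian kernel, drift-correct each
trial by the mean eye position during known fixation epochs, and
recalibrate each run by fitting 3rd-order polynomials (x and y
independently) mapping measured saccade endpoints to true target
positions.

Saccades are intervals where speed strictly exceeds 30 deg/s for at
least 7.5 ms (4 samples at 500 Hz, rounding up) with a net gaze shift of
at least 0.25 deg. A trial's behavioral report is the endpoint of the
last saccade landing before the target reappears (so corrective saccades
supersede the primary one); its reaction time is measured from the
response cue to the onset of the first saccade in the response window.

Exclusion rules (conjunctive flags, any one excludes the trial): the
initial response saccade lasts >= 150 ms, is smaller than 5 deg in
amplitude, or lands more than 5 deg (Euclidean) from the target; gaze
leaves fixation by >= 2.5 deg during the memory delay; or no saccade
occurs within the response window. The 150 ms rule is read as "valid
initial saccades last less than 150 ms in total".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .angles import wrap180, wrap360

SAMPLE_RATE_HZ = 500.0
VELOCITY_THRESH_DEG_S = 30.0     # strict >
MIN_SACCADE_DUR_S = 0.0075       # -> ceil to 4 samples at 500 Hz
MIN_SACCADE_AMP_DEG = 0.25
SMOOTH_SD_S = 0.005

MAX_INITIAL_DUR_S = 0.150
MIN_INITIAL_AMP_DEG = 5.0
MAX_ENDPOINT_ERR_DEG = 5.0
MAX_FIXATION_EXCURSION_DEG = 2.5


@dataclass
class GazeRecord:
    """One trial's gaze trace at 500 Hz, in degrees of visual angle.

    ``events`` carries trial timing in trace time: at least
    ``response_cue`` and ``target_return`` (seconds); ``fixation_epochs``
    is a list of (start, end) intervals known to be fixation.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    events: dict = field(default_factory=dict)
    fixation_epochs: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)   # simulator ground truth

    def __post_init__(self):
        n = self.time.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("time, x, y, valid must share length")
        dt = np.diff(self.time)
        if n > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("sampling must be uniform")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.diff(self.time[:2])[0])


@dataclass(frozen=True)
class SaccadeEvent:
    onset: float
    offset: float
    amplitude: float
    peak_velocity: float
    endpoint: tuple[float, float]

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must follow onset")


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel-to-degree conversion via small-angle approximation."""

    width_px: int
    height_px: int
    width_cm: float
    distance_cm: float

    @property
    def deg_per_px(self) -> float:
        cm_per_px = self.width_cm / self.width_px
        return float(np.rad2deg(np.arctan2(cm_per_px, self.distance_cm)))


def _interpolate_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return values
    if not valid.any():
        raise ValueError("no valid samples to interpolate from")
    idx = np.arange(values.size)
    return np.interp(idx, idx[valid], values[valid])


def preprocess_gaze(raw: GazeRecord, geometry: ScreenGeometry | None = None,
                    extreme_deg: float = 40.0,
                    drift_correct: bool = True) -> GazeRecord:
    """Per-trial preprocessing: units -> invalidation -> smoothing -> drift.

    Run-wise polynomial recalibration operates across trials; apply
    :func:`recalibrate_run` to the preprocessed records of one run.
    """
    x, y = raw.x.astype(float).copy(), raw.y.astype(float).copy()
    if geometry is not None:
        x *= geometry.deg_per_px
        y *= geometry.deg_per_px
    valid = raw.valid & np.isfinite(x) & np.isfinite(y)
    valid &= (np.abs(x) <= extreme_deg) & (np.abs(y) <= extreme_deg)
    sigma = SMOOTH_SD_S * raw.fs
    x = gaussian_filter1d(_interpolate_invalid(x, valid), sigma, mode="nearest")
    y = gaussian_filter1d(_interpolate_invalid(y, valid), sigma, mode="nearest")
    if drift_correct:
        if not raw.fixation_epochs:
            raise ValueError("drift correction requires fixation epochs")
        mask = np.zeros(raw.time.size, dtype=bool)
        for start, end in raw.fixation_epochs:
            mask |= (raw.time >= start) & (raw.time < end)
        mask &= valid
        if mask.sum() < 10:
            raise ValueError("insufficient valid fixation samples")
        x -= x[mask].mean()
        y -= y[mask].mean()
    return replace(raw, x=x, y=y, valid=valid)


def recalibrate_run(records: list[GazeRecord],
                    measured: np.ndarray, true_pos: np.ndarray,
                    order: int = 3) -> list[GazeRecord]:
    """Fit x/y polynomials (measured endpoint -> true target) and apply.

    ``measured`` and ``true_pos`` are (n_trials, 2) arrays of saccade
    endpoints and true target positions for the run, in degrees.
    """
    measured = np.asarray(measured, dtype=float)
    true_pos = np.asarray(true_pos, dtype=float)
    if measured.shape != true_pos.shape or measured.shape[0] <= order:
        raise ValueError("need more calibration trials than polynomial order")
    px = np.polynomial.polynomial.polyfit(measured[:, 0], true_pos[:, 0], order)
    py = np.polynomial.polynomial.polyfit(measured[:, 1], true_pos[:, 1], order)
    out = []
    for rec in records:
        out.append(replace(rec,
                           x=np.polynomial.polynomial.polyval(rec.x, px),
                           y=np.polynomial.polynomial.polyval(rec.y, py)))
    return out


def detect_saccades(gaze: GazeRecord,
                    velocity_thresh: float = VELOCITY_THRESH_DEG_S,
                    min_duration_s: float = MIN_SACCADE_DUR_S,
                    min_amplitude: float = MIN_SACCADE_AMP_DEG
                    ) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection on a preprocessed trace."""
    fs = gaze.fs
    vx = np.gradient(gaze.x) * fs
    vy = np.gradient(gaze.y) * fs
    speed = np.hypot(vx, vy)
    speed[~gaze.valid] = 0.0
    fast = speed > velocity_thresh
    min_samples = int(np.ceil(min_duration_s * fs))
    events: list[SaccadeEvent] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], fast.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):   # stop is exclusive
        if stop - start < min_samples:
            continue
        last = stop - 1
        amp = float(np.hypot(gaze.x[last] - gaze.x[start],
                             gaze.y[last] - gaze.y[start]))
        if amp < min_amplitude:
            continue
        events.append(SaccadeEvent(
            onset=float(gaze.time[start]), offset=float(gaze.time[last]),
            amplitude=amp, peak_velocity=float(speed[start:stop].max()),
            endpoint=(float(gaze.x[last]), float(gaze.y[last]))))
    return events


def score_trial(gaze: GazeRecord, events: list[SaccadeEvent],
                target_angle: float, target_ecc: float = 12.0,
                delay_window: tuple[float, float] | None = None) -> dict:
    """Score one memory-guided saccade trial against its target.

    Returns a dict with endpoint angle, signed memory error, RT (ms), the
    exclusion flag and a semicolon-joined reason string.
    """
    t_cue = gaze.events["response_cue"]
    t_return = gaze.events["target_return"]
    if delay_window is None:
        delay_window = (gaze.events.get("delay_start", gaze.time[0]), t_cue)
    reasons = []

    in_delay = (gaze.time >= delay_window[0]) & (gaze.time < delay_window[1]) \
        & gaze.valid
    if in_delay.any():
        excursion = np.hypot(gaze.x[in_delay], gaze.y[in_delay]).max()
        if excursion >= MAX_FIXATION_EXCURSION_DEG:
            reasons.append("fixation_break")

    window_events = [e for e in events if t_cue <= e.onset < t_return]
    if not window_events:
        reasons.append("no_saccade")
        return {"saccade_endpoint_angle": np.nan, "memory_error": np.nan,
                "rt_ms": np.nan, "excluded": True,
                "exclusion_reason": ";".join(reasons)}

    initial = window_events[0]
    rt_ms = (initial.onset - t_cue) * 1000.0
    if initial.offset - initial.onset >= MAX_INITIAL_DUR_S:
        reasons.append("long_duration")
    if initial.amplitude < MIN_INITIAL_AMP_DEG:
        reasons.append("small_amplitude")

    landed = [e for e in window_events if e.offset < t_return]
    final = landed[-1] if landed else window_events[-1]
    ex, ey = final.endpoint
    endpoint_angle = float(wrap360(np.rad2deg(np.arctan2(ey, ex))))
    tx = target_ecc * np.cos(np.deg2rad(target_angle))
    ty = target_ecc * np.sin(np.deg2rad(target_angle))
    if np.hypot(ex - tx, ey - ty) > MAX_ENDPOINT_ERR_DEG:
        reasons.append("endpoint_error")

    return {"saccade_endpoint_angle": endpoint_angle,
            "memory_error": float(wrap180(endpoint_angle - target_angle)),
            "rt_ms": float(rt_ms),
            "excluded": bool(reasons),
            "exclusion_reason": ";".join(reasons)}


def behavior_summary(records, conditions) -> "pd.DataFrame":
    """Saccade precision (SD of endpoint polar-angle error) and mean RT.

    ``records`` is a DataFrame of scored trials including ``memory_error``
    and ``rt_ms``; ``conditions`` a same-length Series of condition
    labels. Excluded trials are dropped; the SD is the ordinary sample
    SD of the wrapped errors (appropriate in the small-error regime).
    Requires >= 2 valid trials per (participant, condition) cell.
    """
    import pandas as pd

    df = records.copy()
    df["condition"] = np.asarray(conditions)
    df = df[~df["excluded"]]
    out = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"]):
        if len(grp) < 2:
            raise ValueError(
                f"need >=2 valid trials for {pid}/{cond}, got {len(grp)}")
        out.append({"participant_id": pid, "condition": cond,
                    "precision_sd": float(grp["memory_error"].std(ddof=1)),
                    "mean_rt_ms": float(grp["rt_ms"].mean()),
                    "n_trials": len(grp)})
    return pd.DataFrame(out)
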