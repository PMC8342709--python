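"""Trial-level analyses built on the encoding model.

Epoch windows are seconds relative to delay onset and are half-open
[start, end): a TR belongs to an epoch iff its onset falls inside the
window. On the 750 ms grid this makes the training window (5.25-12 s)
exactly 9 TRs, the pre-distractor window 2 TRs, and the distractor and
post-distractor windows 2 TRs each.

Reading out a trial means: invert the frozen encoding model on its voxel
pattern, reconstruct over the angular grid, align to the target (or
distractor) position, then summarize with fidelity or the circular-mean
decoded angle. The batch helpers here do exactly that, vectorized over
trials and timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import ang_dist
from .bold import ROITimeseries
from .iem import (ChannelBasis, EncodingModel, channel_response, default_grid,
                  estimate_weights, invert, predicted_channel_matrix)
from .metrics import EPS_FRAC
from .population import VoxelPopulation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochDefinition:
    name: str
    window: tuple[float, float]     # seconds, [start, end)


EPOCHS = {
    "PRE": EpochDefinition("PRE", (3.75, 5.25)),
    "DIST": EpochDefinition("DIST", (8.25, 9.75)),
    "POST": EpochDefinition("POST", (10.5, 12.0)),
    "TRAIN": EpochDefinition("TRAIN", (5.25, 12.0)),
}


def epoch_average(ts: ROITimeseries, epoch: EpochDefinition | str
                  ) -> np.ndarray:
    """Mean activation over the epoch's TRs: (trials, voxels)."""
    if isinstance(epoch, str):
        epoch = EPOCHS[epoch]
    start, end = epoch.window
    mask = (ts.tr_onsets >= start) & (ts.tr_onsets < end)
    if not mask.any():
        raise ValueError(f"epoch {epoch.name} covers no TR onsets")
    return ts.data[:, mask, :].mean(axis=1)


# ---------------------------------------------------------------------------
# batch readout helpers

def _snap(refs: np.ndarray, step: float) -> np.ndarray:
    return np.round(np.asarray(refs, float) / step) * step


def batch_fidelity(channel_resp: np.ndarray, basis: ChannelBasis,
                   refs: np.ndarray, grid: np.ndarray | None = None
                   ) -> np.ndarray:
    """Fidelity of each row's reconstruction aligned to ``refs``.

    Equivalent to reconstruct -> align -> fidelity per row: with the
    reference snapped to the grid, F = mean_g r(theta_g) cos(theta_g - ref).
    """
    if grid is None:
        grid = default_grid()
    C = np.atleast_2d(channel_resp)
    r = C @ channel_response(grid, basis).T                  # (t, g)
    refs = _snap(np.broadcast_to(refs, (C.shape[0],)), 360.0 / grid.size)
    cosmat = np.cos(np.deg2rad(grid[None, :] - refs[:, None]))
    return (r * cosmat).mean(axis=1)


def batch_decode(channel_resp: np.ndarray, basis: ChannelBasis,
                 grid: np.ndarray | None = None) -> np.ndarray:
    """Circular-mean decoded angle per row, NaN where undefined."""
    if grid is None:
        grid = default_grid()
    C = np.atleast_2d(channel_resp)
    r = C @ channel_response(grid, basis).T
    th = np.deg2rad(grid)
    x = r @ np.cos(th)
    y = r @ np.sin(th)
    resultant = np.hypot(x, y)
    floor = EPS_FRAC * np.maximum(np.abs(r).mean(axis=1),
                                  np.finfo(float).tiny) * grid.size
    angles = np.rad2deg(np.arctan2(y, x)) % 360.0
    return np.where(resultant > floor, angles, np.nan)


def train_encoding_model(design: pd.DataFrame, ts: ROITimeseries,
                         basis: ChannelBasis | None = None) -> EncodingModel:
    """Estimate the IEM from a training session's delay-period averages."""
    if basis is None:
        basis = ChannelBasis()
    B_trn = epoch_average(ts, EPOCHS["TRAIN"])
    C_trn = predicted_channel_matrix(design["target_angle"].to_numpy(float),
                                     basis)
    return estimate_weights(C_trn, B_trn, basis,
                            training_window=EPOCHS["TRAIN"].window)


# ---------------------------------------------------------------------------
# fidelity time courses

def _alignment_refs(design: pd.DataFrame, align_to: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(trial mask, reference angles) for target/distractor alignment."""
    if align_to == "target":
        mask = np.ones(len(design), dtype=bool)
        refs = design["target_angle"].to_numpy(float)
    elif align_to == "distractor":
        mask = (design["condition"] == "distractor_present").to_numpy()
        dropped = int((~mask).sum())
        if dropped:
            logger.info("distractor alignment: dropping %d absent trials",
                        dropped)
        refs = design["distractor_angle"].to_numpy(float)
    else:
        raise ValueError("align_to must be 'target' or 'distractor'")
    return mask, refs


def fidelity_timecourse(ts: ROITimeseries, design: pd.DataFrame,
                        model: EncodingModel, align_to: str = "target"
                        ) -> pd.DataFrame:
    """Per-trial, per-TR fidelity for one participant's session.

    Returns a tidy frame (trial, tr_onset, fidelity, condition).
    """
    mask, refs = _alignment_refs(design, align_to)
    if not mask.any():
        raise ValueError("no qualifying trials for this alignment")
    data = ts.data[mask]
    n_trials, n_tr, n_vox = data.shape
    C = invert(data.reshape(-1, n_vox), model)
    F = batch_fidelity(C, model.basis,
                       np.repeat(refs[mask], n_tr)).reshape(n_trials, n_tr)
    idx = np.flatnonzero(mask)
    return pd.DataFrame({
        "trial": np.repeat(idx, n_tr),
        "condition": np.repeat(design["condition"].to_numpy()[mask], n_tr),
        "tr_onset": np.tile(ts.tr_onsets, n_trials),
        "fidelity": F.ravel(),
    })


# ---------------------------------------------------------------------------
# leave-one-run-out cross-temporal generalization

def loro_generalization(ts: ROITimeseries, design: pd.DataFrame,
                        basis: ChannelBasis | None = None,
                        mode: str = "epoch") -> tuple[np.ndarray, list[str]]:
    """Train-by-test fidelity matrix from distractor-present trials only.

    For every training index (epoch or TR), an encoding model is
    estimated per leave-one-run-out fold from the present trials of the
    remaining runs; the held-out run is reconstructed at every test
    index and target-aligned fidelity is averaged once every trial has
    served as a test trial. Requires >= 2 runs with present trials.
    """
    if basis is None:
        basis = ChannelBasis()
    present = (design["condition"] == "distractor_present").to_numpy()
    runs = np.unique(ts.run_ids[present])
    if runs.size < 2:
        raise ValueError("leave-one-run-out needs >= 2 runs with present trials")
    if mode == "epoch":
        labels = ["PRE", "DIST", "POST"]
        feats = np.stack([epoch_average(ts, name)[present]
                          for name in labels], axis=1)   # (trials, idx, vox)
    elif mode == "timepoint":
        labels = [f"{t:.2f}" for t in ts.tr_onsets]
        feats = ts.data[present]
    else:
        raise ValueError("mode must be 'epoch' or 'timepoint'")
    angles = design["target_angle"].to_numpy(float)[present]
    run_ids = ts.run_ids[present]
    n_idx = feats.shape[1]
    total = np.zeros((n_idx, n_idx))
    count = np.zeros((n_idx, n_idx))
    for held in runs:
        test = run_ids == held
        train = ~test
        C_trn_design = predicted_channel_matrix(angles[train], basis)
        for i in range(n_idx):
            model = estimate_weights(C_trn_design, feats[train, i, :], basis)
            for j in range(n_idx):
                c_tst = invert(feats[test, j, :], model)
                total[i, j] += batch_fidelity(c_tst, basis, angles[test]).sum()
                count[i, j] += test.sum()
    return total / count, labels


# ---------------------------------------------------------------------------
# near-distractor behavior and neural-behavioral coupling

def near_distractor_select(design: pd.DataFrame, threshold: float = 12.0
                           ) -> pd.Series:
    """Boolean mask: present trials with |relative distractor angle| <= threshold."""
    rel = design["relative_distractor_angle"]
    present = design["condition"] == "distractor_present"
    return present & (rel.abs() <= threshold)


def toward_distractor(errors: np.ndarray, rel_angles: np.ndarray) -> np.ndarray:
    """Sign-flip signed errors so positive points toward the distractor."""
    return np.asarray(errors, float) * np.sign(np.asarray(rel_angles, float))


def behavioral_bias(memory_errors: np.ndarray, rel_angles: np.ndarray,
                    participant_ids: np.ndarray, n_perm: int = 1000,
                    seed: int = 0):
    """Mean signed bias toward the distractor + within-participant sign-flip test.

    Returns (per-participant mean bias Series, PermutationResult on the
    group mean, two-tailed).
    """
    from .stats import PermutationResult, _perm_p

    flipped = toward_distractor(memory_errors, rel_angles)
    pid = np.asarray(participant_ids)
    if flipped.size == 0:
        raise ValueError("no valid near-distractor trials")
    per_p = pd.Series(flipped).groupby(pd.Series(pid)).mean()
    observed = float(per_p.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, flipped.size))
    perm_trials = signs * flipped[None, :]
    null = np.array([pd.Series(row).groupby(pd.Series(pid)).mean().mean()
                     for row in perm_trials])
    res = PermutationResult(observed=observed, null=null,
                            p=_perm_p(observed, null, "two"),
                            tails="two", n_perm=n_perm)
    return per_p, res


@dataclass(frozen=True)
class CouplingResult:
    per_participant_r: pd.Series
    fisher_z: pd.Series
    t: float
    p: float                  # one-tailed permutation p on the group t
    null_t: np.ndarray
    quartile_points: pd.DataFrame
    quartile_r: float
    quartile_p: float
    n_dropped: int


R_CLIP = 1.0 - 1e-10


def _rowwise_corr(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between x (n,) and each row of Y (m, n)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (Yc ** 2).sum(axis=1))
    denom[denom == 0] = np.inf
    return (Yc @ xc) / denom


def coupling_analysis(neural_err: np.ndarray, behav_err: np.ndarray,
                      participant_ids: np.ndarray, n_perm: int = 1000,
                      seed: int = 0, min_trials: int = 3) -> CouplingResult:
    """Trial-wise neural-behavioral error coupling, with permutation inference.

    Per participant: Pearson r between decoded-angle error and behavioral
    memory error (both already sign-flipped toward the distractor by the
    caller), clipped and Fisher-z transformed; the group statistic is the
    one-sample t across participants' z. The null shuffles the
    behavior-neural pairing within each participant. A quartile variant
    bins trials by neural error within participant, averages both errors
    per quartile, pools the 4 x participants points, and compares the
    pooled Pearson r to a shuffle-before-binning null.
    """
    from .stats import _paired_t, _perm_p

    neural = np.asarray(neural_err, float)
    behav = np.asarray(behav_err, float)
    pid = np.asarray(participant_ids)
    ok = np.isfinite(neural) & np.isfinite(behav)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("coupling: dropping %d trials with undefined errors",
                    n_dropped)
    neural, behav, pid = neural[ok], behav[ok], pid[ok]

    rng = np.random.default_rng(seed)
    participants = pd.unique(pid)
    z_obs, r_obs = [], []
    z_null = np.zeros((n_perm, participants.size))
    q_rows, q_null_points = [], []
    for pi, p in enumerate(participants):
        sel = pid == p
        x, y = neural[sel], behav[sel]
        if x.size < min_trials:
            raise ValueError(f"participant {p}: fewer than {min_trials} trials")
        r = float(np.clip(np.corrcoef(x, y)[0, 1], -R_CLIP, R_CLIP))
        r_obs.append(r)
        z_obs.append(np.arctanh(r))
        idx = np.argsort(rng.random((n_perm, x.size)), axis=1)
        Yp = y[idx]                                  # permuted pairings
        z_null[:, pi] = np.arctanh(
            np.clip(_rowwise_corr(x, Yp), -R_CLIP, R_CLIP))
        # quartile binning: sort by neural error, intact and permuted
        order = np.argsort(x)
        quart = np.array_split(order, 4)
        for qi, q in enumerate(quart):
            q_rows.append({"participant_id": p, "quartile": qi + 1,
                           "neural_mean": float(x[q].mean()),
                           "behav_mean": float(y[q].mean())})
        q_null_points.append((x, Yp, quart))

    r_obs = pd.Series(r_obs, index=participants, name="r")
    z_obs = pd.Series(np.array(z_obs), index=participants, name="fisher_z")
    t_obs = _paired_t(z_obs.to_numpy())
    null_t = np.array([_paired_t(z_null[i]) for i in range(n_perm)])
    p_group = _perm_p(t_obs, null_t, "one")

    qdf = pd.DataFrame(q_rows)
    q_r = float(np.corrcoef(qdf["neural_mean"], qdf["behav_mean"])[0, 1])
    q_null = np.zeros(n_perm)
    for i in range(n_perm):
        xs, ys = [], []
        for x, Yp, quart in q_null_points:
            for q in quart:
                xs.append(x[q].mean())
                ys.append(Yp[i, q].mean())
        q_null[i] = np.corrcoef(xs, ys)[0, 1]
    q_p = _perm_p(q_r, q_null, "one")

    return CouplingResult(per_participant_r=r_obs, fisher_z=z_obs,
                          t=t_obs, p=p_group, null_t=null_t,
                          quartile_points=qdf, quartile_r=q_r, quartile_p=q_p,
                          n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# univariate RF-sorted time courses

def rf_sorted_timecourse(ts: ROITimeseries, pop: VoxelPopulation,
                         design: pd.DataFrame, align_to: str = "target",
                         r2_min: float = 0.10,
                         ecc_range: tuple[float, float] = (2.0, 15.0),
                         in_thresh: float = 15.0, out_thresh: float = 165.0,
                         baseline_window: tuple[float, float] = (-2.25, 0.0)
                         ) -> pd.DataFrame:
    """Event-related averages of stimulus-aligned (RF_in) vs opposite
    (RF_out) voxels, baseline-corrected.

    Voxels qualify with variance explained >= ``r2_min`` and eccentricity
    inside ``ecc_range``; RF_in requires pRF polar angle within
    ``in_thresh`` degrees of the aligned stimulus (inclusive), RF_out at
    least ``out_thresh`` degrees away (inclusive). Returns a tidy frame
    (condition, rf, tr_onset, activation); the per-time-course mean over
    the baseline window is subtracted.
    """
    mask, refs = _alignment_refs(design, align_to)
    base_ok = (pop.r2 >= r2_min) & (pop.prf_ecc >= ecc_range[0]) & \
        (pop.prf_ecc <= ecc_range[1])
    per_trial = {"RF_in": [], "RF_out": []}
    conditions = []
    for i in np.flatnonzero(mask):
        sep = ang_dist(refs[i], pop.prf_angle)
        sets = {"RF_in": base_ok & (sep <= in_thresh),
                "RF_out": base_ok & (sep >= out_thresh)}
        for name, vox in sets.items():
            if not vox.any():
                raise ValueError(f"trial {i}: no {name} voxels qualify")
            per_trial[name].append(ts.data[i][:, vox].mean(axis=1))
        conditions.append(design["condition"].iloc[i])
    conditions = np.asarray(conditions)
    bmask = (ts.tr_onsets >= baseline_window[0]) & \
        (ts.tr_onsets < baseline_window[1])
    rows = []
    for name, courses in per_trial.items():
        courses = np.asarray(courses)              # (trials, TR)
        for cond in np.unique(conditions):
            mean_tc = courses[conditions == cond].mean(axis=0)
            mean_tc = mean_tc - mean_tc[bmask].mean()
            rows.extend({"condition": cond, "rf": name, "tr_onset": t,
                         "activation": a}
                        for t, a in zip(ts.tr_onsets, mean_tc))
    return pd.DataFrame(rows)
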