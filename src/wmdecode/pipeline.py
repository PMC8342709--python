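"""End-to-end demonstration pipeline on synthetic data.

`run_pipeline` executes the full analysis flow the study applies to each
region of interest, on simulated participants: independent-session model
training, per-TR fidelity time courses aligned to target and distractor,
epoch-wise condition contrasts via the run-wise paired permutation test,
leave-one-run-out cross-temporal generalization, near-distractor
behavioral bias, and the trial-wise neural-behavioral coupling analysis.
All tables are written as TSV, arrays to an HDF5 store with a JSON
sidecar, and the configuration is mirrored into the output directory so
a persisted config re-runs to identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analyses import (EPOCHS, batch_decode, batch_fidelity, coupling_analysis,
                       behavioral_bias, epoch_average, fidelity_timecourse,
                       loro_generalization, near_distractor_select,
                       toward_distractor, train_encoding_model)
from .behavior import simulate_behavior
from .bold import simulate_timeseries
from .design import generate_design, generate_training_design
from .iem import ChannelBasis, invert
from .io import save_store, save_table
from .metrics import decoding_error
from .population import generate_population
from .stats import perm_paired_ttest

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one synthetic study run."""

    seed: int = 0
    n_participants: int = 7
    n_runs: int = 30          # per participant; the study ran 25-36
    n_train_runs: int = 6
    n_voxels: int = 160
    noise_sd: float = 1.0
    neural_bias_sd: float = 10.0       # SD of the per-trial neural bias (deg)
    coupling: float = 0.5              # rho: behavior follows neural bias
    attract_bias: float = 1.0          # deg pulled toward the distractor
    motor_sd: float = 5.0              # deg of motor noise on saccades
    distractor_gain: float = 2.5
    target_suppression: float = 0.5
    n_perm: int = 1000
    basis_centers: list = field(default_factory=lambda: [i * 45.0 for i in range(8)])
    out_dir: str = "results/pipeline"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _participant_seed(base_seed: int, participant: int, stream: int) -> int:
    """Deterministic per-participant, per-stream sub-seed (< 2**31)."""
    ss = np.random.SeedSequence([base_seed, participant, stream])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_participant(config: RunConfig, participant: int) -> dict:
    """Simulate one participant: training session, task session, behavior."""
    s = lambda stream: _participant_seed(config.seed, participant, stream)
    basis = ChannelBasis(centers=np.asarray(config.basis_centers, float))
    pop = generate_population(config.n_voxels, seed=s(0))

    pid = f"sub{participant + 1:02d}"
    train_design = generate_training_design(config.n_train_runs, seed=s(1))
    train_design["participant_id"] = pid
    train_ts = simulate_timeseries(train_design, pop,
                                   noise_sd=config.noise_sd, seed=s(2))
    model = train_encoding_model(train_design, train_ts, basis)

    design = generate_design(config.n_runs, seed=s(3))
    design["participant_id"] = pid
    rng = np.random.default_rng(s(4))
    bias = rng.normal(0.0, config.neural_bias_sd, size=len(design))
    ts = simulate_timeseries(design, pop, noise_sd=config.noise_sd,
                             neural_bias=bias,
                             distractor_gain=config.distractor_gain,
                             target_suppression=config.target_suppression,
                             seed=s(5))
    behavior = simulate_behavior(design, neural_bias=bias,
                                 coupling=config.coupling,
                                 attract_bias=config.attract_bias,
                                 motor_sd=config.motor_sd, seed=s(6))
    return {"participant": participant, "basis": basis, "pop": pop,
            "design": design, "ts": ts, "behavior": behavior,
            "model": model, "neural_bias": bias}


def _epoch_run_fidelity(part: dict, epoch: str) -> pd.DataFrame:
    """Run-wise mean target fidelity per condition for one participant."""
    B = epoch_average(part["ts"], EPOCHS[epoch])
    C = invert(B, part["model"])
    F = batch_fidelity(C, part["basis"],
                       part["design"]["target_angle"].to_numpy(float))
    df = pd.DataFrame({
        "run_id": part["design"]["run_id"],
        "condition": part["design"]["condition"],
        "fidelity": F})
    return df.groupby(["run_id", "condition"], as_index=False).mean()


def post_decoding_errors(part: dict) -> pd.DataFrame:
    """Near-distractor trials' decoded-angle and behavioral errors (POST epoch),
    both sign-flipped so positive = toward the distractor."""
    design = part["design"]
    near = near_distractor_select(design).to_numpy()
    B = epoch_average(part["ts"], EPOCHS["POST"])[near]
    decoded = batch_decode(invert(B, part["model"]), part["basis"])
    target = design["target_angle"].to_numpy(float)[near]
    rel = design["relative_distractor_angle"].to_numpy(float)[near]
    neural = np.array([decoding_error(d, t) if np.isfinite(d) else np.nan
                       for d, t in zip(decoded, target)])
    behav = part["behavior"]["memory_error"].to_numpy(float)[near]
    return pd.DataFrame({
        "participant_id": design["participant_id"].to_numpy()[near],
        "run_id": design["run_id"].to_numpy()[near],
        "rel_angle": rel,
        "neural_error_toward": toward_distractor(neural, rel),
        "behav_error_toward": toward_distractor(behav, rel)})


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full synthetic-study analysis; returns a result bundle."""
    t0 = time.time()
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        parts = [simulate_participant(config, p)
                 for p in range(config.n_participants)]

        stage = "fidelity_timecourse"
        tc_frames = []
        for part in parts:
            for align in ("target", "distractor"):
                tc = fidelity_timecourse(part["ts"], part["design"],
                                         part["model"], align_to=align)
                tc["align_to"] = align
                tc["participant_id"] = f"sub{part['participant'] + 1:02d}"
                tc_frames.append(tc)
        timecourses = pd.concat(tc_frames, ignore_index=True)
        group_tc = (timecourses
                    .groupby(["align_to", "condition", "tr_onset"])["fidelity"]
                    .agg(["mean", "sem"]).reset_index())

        stage = "epoch_contrasts"
        epoch_rows, contrasts = [], []
        for epoch in ("PRE", "DIST", "POST"):
            runs_a, runs_b = [], []
            for part in parts:
                rw = _epoch_run_fidelity(part, epoch)
                piv = rw.pivot(index="run_id", columns="condition",
                               values="fidelity")
                runs_a.append(piv["distractor_present"].to_numpy())
                runs_b.append(piv["distractor_absent"].to_numpy())
                epoch_rows.append({
                    "participant": part["participant"], "epoch": epoch,
                    "present": piv["distractor_present"].mean(),
                    "absent": piv["distractor_absent"].mean()})
            res = perm_paired_ttest(runs_a, runs_b, tails="two",
                                    n_perm=config.n_perm, seed=config.seed)
            contrasts.append({"epoch": epoch, "t": res.observed, "p": res.p})
        epoch_fidelity = pd.DataFrame(epoch_rows)
        epoch_tests = pd.DataFrame(contrasts)

        stage = "generalization"
        gen_mats = []
        for part in parts:
            mat, labels = loro_generalization(part["ts"], part["design"],
                                              part["basis"], mode="epoch")
            gen_mats.append(mat)
        generalization = np.mean(gen_mats, axis=0)

        stage = "coupling"
        err_df = pd.concat([post_decoding_errors(p) for p in parts],
                           ignore_index=True)
        coupling = coupling_analysis(
            err_df["neural_error_toward"].to_numpy(),
            err_df["behav_error_toward"].to_numpy(),
            err_df["participant_id"].to_numpy(),
            n_perm=config.n_perm, seed=config.seed)

        stage = "behavioral_bias"
        near_frames = []
        for part in parts:
            near = near_distractor_select(part["design"]).to_numpy()
            near_frames.append(pd.DataFrame({
                "participant_id": part["design"]["participant_id"][near],
                "memory_error":
                    part["behavior"]["memory_error"].to_numpy()[near],
                "rel_angle":
                    part["design"]["relative_distractor_angle"]
                    .to_numpy()[near]}))
        near_df = pd.concat(near_frames, ignore_index=True)
        bias_per_p, bias_test = behavioral_bias(
            near_df["memory_error"].to_numpy(),
            near_df["rel_angle"].to_numpy(),
            near_df["participant_id"].to_numpy(),
            n_perm=config.n_perm, seed=config.seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    bundle = {
        "config": config,
        "group_timecourse": group_tc,
        "epoch_fidelity": epoch_fidelity,
        "epoch_tests": epoch_tests,
        "generalization": generalization,
        "generalization_labels": labels,
        "coupling": coupling,
        "behavioral_bias": bias_per_p,
        "behavioral_bias_test": bias_test,
        "elapsed_s": time.time() - t0,
    }
    if write:
        save_table(group_tc, out / "group_fidelity_timecourse.tsv")
        save_table(epoch_fidelity, out / "epoch_fidelity.tsv")
        save_table(epoch_tests, out / "epoch_condition_tests.tsv")
        save_table(coupling.quartile_points, out / "coupling_quartiles.tsv")
        pd.DataFrame({"label": labels}).assign(
            **{f"test_{l}": generalization[:, i]
               for i, l in enumerate(labels)}).to_csv(
            out / "generalization_epoch_matrix.tsv", sep="\t", index=False)
        first = parts[0]
        save_store(out / "participant01.h5", ts=first["ts"],
                   pop=first["pop"], model=first["model"],
                   sidecar={"seed": config.seed, "package": "wmdecode",
                            "version": __version__,
                            "config": dataclasses.asdict(config)})
        summary = {
            "seed": config.seed, "version": __version__,
            "elapsed_s": bundle["elapsed_s"], "n_perm": config.n_perm,
            "coupling_t": coupling.t, "coupling_p": coupling.p,
            "behavioral_bias_deg": float(bias_per_p.mean()),
            "behavioral_bias_p": bias_test.p,
            "epoch_tests": contrasts,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("pipeline finished in %.1f s", bundle["elapsed_s"])
    return bundle
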