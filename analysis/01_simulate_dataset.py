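"""Simulate one synthetic study: designs, voxel populations, BOLD-like
time series, behavior, and gaze — then archive and validate the store.

Writes per-participant trial/behavior tables and an HDF5 store for the
first participant under results/dataset/, and prints the design facts a
session must satisfy (70/30 condition mix, per-run bin counterbalancing,
32-position training grid).
"""

from pathlib import Path

import pandas as pd

from wmdecode.design import validate_design
from wmdecode.io import save_store, save_table, validate_store
from wmdecode.pipeline import RunConfig, simulate_participant

OUT = Path("results/dataset")
OUT.mkdir(parents=True, exist_ok=True)

config = RunConfig(seed=1, n_participants=7, n_voxels=120)
config.to_yaml(OUT / "config.yaml")

designs, behaviors = [], []
for p in range(config.n_participants):
    part = simulate_participant(config, p)
    validate_design(part["design"])
    designs.append(part["design"])
    behaviors.append(part["behavior"])
    if p == 0:
        save_store(OUT / "participant01.h5", ts=part["ts"], pop=part["pop"],
                   model=part["model"],
                   sidecar={"seed": config.seed,
                            "n_runs": config.n_runs,
                            "n_voxels": config.n_voxels})

design = pd.concat(designs, ignore_index=True)
behavior = pd.concat(behaviors, ignore_index=True)
save_table(design, OUT / "trials.tsv")
save_table(behavior, OUT / "behavior.tsv")

present_frac = (design["condition"] == "distractor_present").mean()
report = validate_store(OUT / "participant01.h5")
print(f"simulated {config.n_participants} participants x "
      f"{config.n_runs} runs ({len(design)} trials)")
print(f"distractor-present fraction: {present_frac:.2f} (design target 0.70)")
print(f"store validation: {len(report['errors'])} errors, "
      f"{len(report['warnings'])} warnings")
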