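"""On-disk formats: TSV tables, an HDF5 array store, JSON sidecars.

Trial tables and behavioral records are plain TSV with the column names
used throughout the package. Array-valued objects (ROI time series,
voxel populations, encoding-model weights) live in one HDF5 container
per dataset, with a JSON sidecar recording the generating parameters and
seed so any store can be regenerated.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .bold import ROITimeseries
from .iem import ChannelBasis, EncodingModel
from .population import VoxelPopulation

_POP_FIELDS = ("prf_angle", "prf_ecc", "prf_size", "r2", "tuning_width",
               "gain_delay", "gain_distractor")


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_store(path: str | Path, ts: ROITimeseries | None = None,
               pop: VoxelPopulation | None = None,
               model: EncodingModel | None = None,
               sidecar: dict | None = None) -> None:
    """Write arrays to an HDF5 container plus a JSON parameter sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        if ts is not None:
            g = f.create_group("timeseries")
            g.create_dataset("data", data=ts.data)
            g.create_dataset("tr_onsets", data=ts.tr_onsets)
            g.create_dataset("run_ids", data=np.asarray(ts.run_ids, dtype=int))
            g.create_dataset(
                "participant_ids",
                data=np.asarray(ts.participant_ids, dtype="S16"))
            g.attrs["tr_seconds"] = ts.tr_seconds
            g.attrs["zscored"] = ts.zscored
        if pop is not None:
            g = f.create_group("population")
            for name in _POP_FIELDS:
                g.create_dataset(name, data=getattr(pop, name))
        if model is not None:
            g = f.create_group("model")
            g.create_dataset("weights", data=model.weights)
            g.create_dataset("centers", data=model.basis.centers)
            g.attrs["size_constant"] = model.basis.size_constant
            g.attrs["exponent"] = model.basis.exponent
            g.attrs["precedence_mode"] = model.basis.precedence_mode
            if model.training_window is not None:
                g.attrs["training_window"] = model.training_window
            if model.n_training_trials is not None:
                g.attrs["n_training_trials"] = model.n_training_trials
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str))


def load_store(path: str | Path) -> dict:
    """Load whichever of timeseries / population / model the store holds."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "timeseries" in f:
            g = f["timeseries"]
            out["timeseries"] = ROITimeseries(
                data=g["data"][()], tr_onsets=g["tr_onsets"][()],
                run_ids=g["run_ids"][()],
                participant_ids=g["participant_ids"][()].astype(str),
                tr_seconds=float(g.attrs["tr_seconds"]),
                zscored=bool(g.attrs["zscored"]))
        if "population" in f:
            g = f["population"]
            out["population"] = VoxelPopulation(
                **{name: g[name][()] for name in _POP_FIELDS})
        if "model" in f:
            g = f["model"]
            basis = ChannelBasis(centers=g["centers"][()],
                                 size_constant=float(g.attrs["size_constant"]),
                                 exponent=int(g.attrs["exponent"]),
                                 precedence_mode=str(g.attrs["precedence_mode"]))
            tw = g.attrs.get("training_window")
            out["model"] = EncodingModel(
                basis=basis, weights=g["weights"][()],
                training_window=tuple(tw) if tw is not None else None,
                n_training_trials=int(g.attrs["n_training_trials"])
                if "n_training_trials" in g.attrs else None)
    sidecar_path = Path(path).with_suffix(Path(path).suffix + ".json")
    if sidecar_path.exists():
        out["sidecar"] = json.loads(sidecar_path.read_text())
    return out


def validate_store(path: str | Path) -> dict:
    """Schema and invariant checks; returns {'errors': [...], 'warnings': [...]}."""
    path = Path(path)
    errors, warnings = [], []
    if not path.exists():
        return {"errors": [f"store {path} does not exist"], "warnings": []}
    try:
        contents = load_store(path)
    except Exception as exc:            # malformed container
        return {"errors": [f"failed to load store: {exc}"], "warnings": []}
    ts = contents.get("timeseries")
    if ts is not None and ts.zscored:
        groups = pd.DataFrame({"p": ts.participant_ids, "r": ts.run_ids})
        for key, sel in groups.groupby(["p", "r"]).indices.items():
            flat = ts.data[sel].reshape(-1, ts.data.shape[-1])
            if np.abs(flat.mean(axis=0)).max() > 1e-6 or \
               np.abs(flat.std(axis=0) - 1.0).max() > 1e-6:
                errors.append(
                    f"z-scoring invariant violated for run {key}")
    pop = contents.get("population")
    if pop is not None:
        try:
            VoxelPopulation(**{n: getattr(pop, n) for n in _POP_FIELDS})
        except ValueError as exc:
            errors.append(f"population invariant violated: {exc}")
    model = contents.get("model")
    if model is not None and not np.all(np.isfinite(model.weights)):
        errors.append("model weights contain non-finite values")
    if "sidecar" not in contents:
        warnings.append("missing JSON sidecar (no provenance record)")
    elif "seed" not in contents["sidecar"]:
        warnings.append("sidecar lacks a seed entry")
    return {"errors": errors, "warnings": warnings}
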