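"""HDF5 / JSON persistence for activations, traces, null distributions and
voxel data."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .criteria import NullDistribution
from .simulate import VoxelResponses
from .synthesis import SynthesisTrace


def save_trace(trace: SynthesisTrace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("loss", data=trace.loss)
        f.create_dataset("eta", data=trace.eta)
        f.create_dataset("step_norms", data=trace.step_norms)


def load_trace(path) -> SynthesisTrace:
    with h5py.File(path, "r") as f:
        return SynthesisTrace(f["loss"][...], f["eta"][...], f["step_norms"][...])


def save_null(null: NullDistribution, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["stage"] = null.stage
        f.attrs["seed"] = null.seed
        f.attrs["n_resampled"] = null.n_resampled
        if null.threshold_quantile is not None:
            f.attrs["threshold_quantile"] = null.threshold_quantile
        for m, v in null.samples.items():
            f.create_dataset(f"samples/{m}", data=v)


def load_null(path) -> NullDistribution:
    with h5py.File(path, "r") as f:
        samples = {m: f[f"samples/{m}"][...] for m in f["samples"]}
        tq = f.attrs.get("threshold_quantile")
        return NullDistribution(str(f.attrs["stage"]), samples,
                                int(f.attrs["seed"]),
                                None if tq is None else float(tq),
                                int(f.attrs["n_resampled"]))


def save_voxels(vox: VoxelResponses, path, roi_labels=None, stimulus_ids=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voxels", data=vox.responses)
        f.create_dataset("weights", data=vox.weights)
        f.attrs["stage"] = vox.stage
        f.attrs["noise_std"] = vox.noise_std
        if roi_labels is not None:
            f.create_dataset("roi_labels", data=np.asarray(roi_labels, dtype="S"))
        if stimulus_ids is not None:
            f.create_dataset("stimulus_ids", data=np.asarray(stimulus_ids, dtype="S"))


def load_voxels(path) -> VoxelResponses:
    with h5py.File(path, "r") as f:
        return VoxelResponses(f["voxels"][...], f["weights"][...],
                              str(f.attrs["stage"]), float(f.attrs["noise_std"]))


def save_features(features: dict, path) -> None:
    """stage name -> (stimuli, units) matrices under features/<stage>."""
    with h5py.File(path, "w") as f:
        for stage, mat in features.items():
            f.create_dataset(f"features/{stage}", data=np.asarray(mat))


def load_features(path) -> dict:
    with h5py.File(path, "r") as f:
        return {s: f[f"features/{s}"][...] for s in f["features"]}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
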