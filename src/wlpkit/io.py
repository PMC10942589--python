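"""HDF5 persistence for Recording objects.

Layout (one file per trial)::

    /layout/positions   (N, 2) float64, mm
    /layout/shape       (3,)  [n_rows, n_cols, pitch]
    /lfp                (N, T) float32, uV
    /meta               attrs: sample_rate, duration, stim_times, seed
    /spikes/ch{k}       float64 spike times, s
    /ground_truth/...   optional: module_labels, module_onsets, params_json

The ground-truth group is optional on read so files converted from real
recordings (which have no ground truth) use the same layout.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .layout import ElectrodeLayout
from .simulate import Recording

__all__ = ["write_recording", "read_recording", "FormatError"]


class FormatError(ValueError):
    """A recording file is missing or malforms a required dataset."""


def write_recording(rec: Recording, path: str) -> None:
    """Write a Recording; LFP stored float32, spike times float64."""
    with h5py.File(path, "w") as f:
        lay = f.create_group("layout")
        lay.create_dataset("positions", data=rec.layout.positions, dtype="float64")
        lay.create_dataset(
            "shape", data=np.array([rec.layout.n_rows, rec.layout.n_cols, rec.layout.pitch])
        )
        f.create_dataset("lfp", data=rec.lfp.astype(np.float32))
        meta = f.create_group("meta")
        meta.attrs["sample_rate"] = float(rec.sample_rate)
        meta.attrs["duration"] = float(rec.duration)
        meta.create_dataset("stim_times", data=np.asarray(rec.stim_times, dtype="float64"))
        if rec.seed is not None:
            meta.attrs["seed"] = int(rec.seed)
        sp = f.create_group("spikes")
        for k, st in enumerate(rec.spikes):
            sp.create_dataset(f"ch{k}", data=np.asarray(st, dtype="float64"))
        if rec.ground_truth is not None:
            gt = f.create_group("ground_truth")
            g = dict(rec.ground_truth)
            gt.create_dataset("module_labels", data=np.asarray(g.pop("module_labels"), dtype="int64"))
            gt.create_dataset("module_onsets", data=np.asarray(g.pop("module_onsets"), dtype="float64"))
            params = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in g.items()}
            gt.create_dataset("params_json", data=json.dumps(params))


def read_recording(path: str) -> Recording:
    """Read a Recording; raises FormatError naming the missing dataset."""
    with h5py.File(path, "r") as f:
        for key in ("lfp", "layout/positions", "layout/shape", "meta/stim_times", "spikes"):
            if key not in f:
                raise FormatError(f"{path}: missing required dataset/group '/{key}'")
        shape = f["layout/shape"][:]
        layout = ElectrodeLayout(int(shape[0]), int(shape[1]), float(shape[2]))
        lfp = f["lfp"][:].astype(np.float64)
        if lfp.shape[0] != layout.n_channels:
            raise FormatError(f"{path}: '/lfp' rows do not match layout channel count")
        meta = f["meta"]
        spikes = []
        for k in range(layout.n_channels):
            name = f"ch{k}"
            if name not in f["spikes"]:
                raise FormatError(f"{path}: missing '/spikes/{name}'")
            spikes.append(f["spikes"][name][:])
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = {
                "module_labels": g["module_labels"][:],
                "module_onsets": g["module_onsets"][:],
            }
            if "params_json" in g:
                gt.update(json.loads(g["params_json"][()].decode()))
        return Recording(
            layout=layout,
            sample_rate=float(meta.attrs["sample_rate"]),
            lfp=lfp,
            spikes=spikes,
            stim_times=meta["stim_times"][:],
            ground_truth=gt,
            seed=int(meta.attrs["seed"]) if "seed" in meta.attrs else None,
        )
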