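"""File formats: delimited-text signals, CSV manifests, named-point
landmark files, JSON noise-model sidecars, HDF5 dataset/checkpoint
containers."""

from __future__ import annotations

import json
import pathlib

import h5py
import numpy as np
import pandas as pd

from .preprocessing import ARNoiseModel, CleanSignal, RawRecording
from .vfss import LandmarkSet

__all__ = [
    "write_signal", "read_signal",
    "write_manifest", "read_manifest",
    "write_landmarks", "read_landmarks",
    "save_noise_model", "load_noise_model",
    "save_noise_models", "load_noise_models",
    "save_dataset", "load_dataset",
    "save_checkpoint", "load_checkpoint",
]

_MANIFEST_COLUMNS = ["swallow_id", "path", "onset_frame", "offset_frame",
                     "fps", "truth_ratio"]


# -- signals (3-column delimited text, one column per axis) -----------------

def write_signal(path, rec) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"fs={rec.fs:g} channels={','.join(rec.channel_labels)}"
    np.savetxt(path, rec.samples.T, fmt="%.8g", header=header)
    return path


def read_signal(path) -> RawRecording:
    path = pathlib.Path(path)
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    fs = float(meta.get("fs", 20000.0))
    labels = tuple(meta["channels"].split(",")) if "channels" in meta else ("A-P", "S-I", "M-L")
    data = np.loadtxt(path)
    return RawRecording(np.atleast_2d(data).T, fs, labels)


# -- manifests ---------------------------------------------------------------

def write_manifest(path, manifest: pd.DataFrame) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest[_MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


# -- landmarks (structured text: "name x y" per line) ------------------------

_LANDMARK_FIELDS = ("c2_ai", "c3_as", "c3_ai", "c4_ai", "tracheal_notch",
                    "ues_anterior", "ues_posterior")


def write_landmarks(path, lm: LandmarkSet) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"frame {lm.frame_index}"]
    for name in _LANDMARK_FIELDS:
        x, y = getattr(lm, name)
        lines.append(f"{name} {x:.6f} {y:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_landmarks(path) -> LandmarkSet:
    points, frame = {}, 0
    for line in pathlib.Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "frame":
            frame = int(parts[1])
        else:
            points[parts[0]] = np.array([float(parts[1]), float(parts[2])])
    return LandmarkSet(frame_index=frame, **points)


# -- AR noise-model sidecars (JSON) ------------------------------------------

def save_noise_model(path, model: ARNoiseModel) -> pathlib.Path:
    return save_noise_models(path, [model])


def save_noise_models(path, models) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [dict(order=m.order, coefficients=list(map(float, m.coefficients)),
                    bic=m.selection_score) for m in models]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def load_noise_models(path) -> list:
    payload = json.loads(pathlib.Path(path).read_text())
    return [ARNoiseModel(coefficients=np.array(m["coefficients"]),
                         order=int(m["order"]), selection_score=float(m["bic"]))
            for m in payload]


def load_noise_model(path) -> ARNoiseModel:
    return load_noise_models(path)[0]


# -- assembled datasets (HDF5, one group per swallow) ------------------------

def save_dataset(path, samples) -> pathlib.Path:
    from .datasets import SwallowSample  # local import avoids a cycle

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for s in samples:
            g = f.create_group(s.swallow_id)
            g.create_dataset("chunks", data=s.chunks, compression="gzip")
            g.create_dataset("mask", data=s.mask)
            g.attrs["target_ratio"] = s.target_ratio
            g.attrs["valid_chunks"] = s.valid_chunks
    return path


def load_dataset(path) -> list:
    from .datasets import SwallowSample

    samples = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            samples.append(SwallowSample(
                chunks=g["chunks"][()], mask=g["mask"][()],
                target_ratio=float(g.attrs["target_ratio"]),
                valid_chunks=int(g.attrs["valid_chunks"]), swallow_id=sid,
            ))
    return samples


# -- model checkpoints (HDF5: parameter arrays + embedded config) ------------

def save_checkpoint(path, params: dict, config) -> pathlib.Path:
    from dataclasses import asdict

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(config))
        g = f.create_group("params")
        for k, v in params.items():
            g.create_dataset(k, data=v)
    return path


def load_checkpoint(path):
    from .model import ModelConfig

    with h5py.File(path, "r") as f:
        cfg = ModelConfig(**json.loads(f.attrs["config"]))
        params = {k: f["params"][k][()] for k in f["params"]}
    return params, cfg
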