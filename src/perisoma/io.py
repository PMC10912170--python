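"""File interfaces: OME-TIFF volumes, CSV tables, PLY meshes, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .volume import LabeledVolume


def write_ome_tiff(path: str | Path, array: np.ndarray, voxel_size: tuple[float, float, float]) -> None:
    """Write a (z, y, x) volume as OME-TIFF with um pixel sizes."""
    vz, vy, vx = voxel_size
    tifffile.imwrite(
        str(path),
        np.asarray(array),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def read_ome_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def read_labeled_volume(directory: str | Path, voxel_size: tuple[float, float, float]) -> LabeledVolume:
    """Load ``neuron_labels.ome.tif`` / ``microglia_labels.ome.tif`` from a run directory."""
    directory = Path(directory)
    labels = {}
    for role in ("neuron", "microglia"):
        p = directory / f"{role}_labels.ome.tif"
        if p.exists():
            labels[role] = read_ome_tiff(p).astype(np.int32)
    if not labels:
        raise FileNotFoundError(f"no *_labels.ome.tif channels found in {directory}")
    return LabeledVolume(labels=labels, voxel_size=voxel_size)


def write_mesh_ply(path: str | Path, mesh) -> None:
    mesh.export(str(path))


def write_trace_csv(path: str | Path, trace: np.ndarray, fs: float, unit: str = "a.u.") -> None:
    """Trace CSV whose header names the unit and sampling rate."""
    df = pd.DataFrame({f"value_{unit}_fs{fs}Hz": np.asarray(trace)})
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    col = df.columns[0]
    fs = float(col.rsplit("_fs", 1)[1].rstrip("Hz"))
    return df[col].to_numpy(dtype=float), fs


def write_yaml(path: str | Path, data: dict) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(path: str | Path, data: dict) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
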