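"""File I/O: NIfTI volumes, FSL-style bval/bvec, JSON sidecars, configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .models import AcquisitionScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_scheme",
    "load_scheme",
    "load_config",
    "save_json",
]


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_scheme(scheme: AcquisitionScheme, stem) -> None:
    """Write FSL-dialect bval/bvec (3 x N rows) plus a JSON timing sidecar."""
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".bval"), scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(stem.with_suffix(".bvec"), scheme.directions.T, fmt="%.8f")
    sidecar = {
        "delta_s": scheme.delta,
        "Delta_s": scheme.Delta,
        "gamma_rad_per_s_per_T": scheme.gamma,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_scheme(stem) -> AcquisitionScheme:
    stem = Path(stem)
    b = np.loadtxt(stem.with_suffix(".bval")).ravel()
    g = np.loadtxt(stem.with_suffix(".bvec"))
    if g.shape[0] == 3:
        g = g.T
    side = json.loads(stem.with_suffix(".json").read_text())
    return AcquisitionScheme(
        b_values=b,
        directions=g,
        delta=side["delta_s"],
        Delta=side["Delta_s"],
        gamma=side.get("gamma_rad_per_s_per_T", 2.675e8),
    )


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
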