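"""End-to-end orchestration: simulate -> correct -> fit -> select -> compare.

`run_pipeline` drives the whole analysis from a single configuration
dictionary and writes a report bundle (tables as TSV, maps as NIfTI, a
JSON manifest echoing the config and seed).  Each stage failure marks the
bundle partial rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .fitting import FitConfig, fit_volume
from .groupstats import group_compare
from .models import MODEL_SPECS
from .phantom import PhantomSpec, make_phantom, make_scheme, simulate_signals
from .selection import best_model_map, bmax_sweep, select_models
from .tensor import compute_angles

__all__ = ["run_pipeline", "heart_summary", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scheme": {"n_directions": 257, "b_max": 10000.0, "n_non_dw": 4, "style": "grid-half"},
    "phantom": {
        "groups": {"sham": 2, "tac": 2},
        "model": "beta",
        "shape": [20, 20, 5],
        "roi_voxels": 60,
        "noise_sd": 243.0,
        "s0": 2.36e4,
    },
    "models": ["dt", "beta"],
    "fit": {"freeze_frame": True, "dk_b_cap": 5000.0},
    "sweep": None,  # e.g. {"grid": [2000, 10000], "n_voxels": 20}
    "compare": [["tac", "sham"]],
}


def _validate_models(model_ids):
    unknown = [m for m in model_ids if m not in MODEL_SPECS]
    if unknown:
        raise ValueError(f"unknown model name(s): {unknown}")


def heart_summary(volume_fit, model_id: str, roi_mask: np.ndarray) -> dict:
    """ROI-mean fitted parameters and derived moments of one heart."""
    fits = volume_fit.results[model_id]
    acc: dict[str, list] = {}
    for f in fits:
        if f is None:
            continue
        row = {}
        for nm, vals in f.axis_params.items():
            for ax in range(3):
                row[f"{nm}_v{ax + 1}"] = vals[ax]
        row.update(f.global_params)
        try:
            mom = f.derived_moments()
            for key, vals in mom.items():
                for ax in range(3):
                    row[f"{key}_v{ax + 1}"] = vals[ax]
        except Exception:
            pass
        for k, v in row.items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full synthetic-study pipeline and write the report bundle.

    Returns the manifest dict; ``manifest["status"]`` is "complete" or
    "partial" (with per-stage errors under ``manifest["errors"]``).
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    _validate_models(cfg["models"])
    errors: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "status": "running",
    }

    scheme = make_scheme(seed=seed, **cfg["scheme"])
    io.save_scheme(scheme, out / "scheme")

    ph = cfg["phantom"]
    fitcfg = FitConfig(seed=seed, **cfg.get("fit", {}))
    summaries: dict[str, pd.DataFrame] = {}
    first_heart = None
    heart_idx = 0
    for group, n_hearts in ph["groups"].items():
        rows = []
        for h in range(int(n_hearts)):
            heart_seed = seed * 1000 + heart_idx
            heart_idx += 1
            spec = PhantomSpec(
                shape=tuple(ph["shape"]),
                model_id=ph.get("model", "beta"),
                group=group,
                s0=float(ph.get("s0", 2.36e4)),
                noise_sd=float(ph.get("noise_sd", 243.0)),
                roi_voxels=int(ph.get("roi_voxels", 247)),
                seed=heart_seed,
            )
            gt = make_phantom(spec)
            sim = simulate_signals(gt, scheme, seed=heart_seed + 1)
            data = sim.real_corrected()
            try:
                vf = fit_volume(data, gt.roi_mask, cfg["models"], scheme, config=fitcfg)
            except Exception:
                errors[f"fit:{group}:{h}"] = traceback.format_exc(limit=3)
                continue
            primary = cfg["models"][-1]
            rows.append(heart_summary(vf, primary, gt.roi_mask))
            if first_heart is None:
                first_heart = (gt, sim, data, vf)
        if rows:
            summaries[group] = pd.DataFrame(rows)
            summaries[group].to_csv(out / f"summary_{group}.tsv", sep="\t", index=False)

    # scalar/angle maps and model selection on the first heart
    if first_heart is not None:
        gt, sim, data, vf = first_heart
        try:
            sels = select_models(vf, data, scheme)
            code_map, legend = best_model_map(
                sels, vf.voxels, gt.spec.shape, cfg["models"]
            )
            io.save_nifti(code_map, out / "best_model.nii.gz")
            io.save_json(legend, out / "best_model_legend.json")
        except Exception:
            errors["select"] = traceback.format_exc(limit=3)
        try:
            v1 = np.zeros(gt.spec.shape + (3,))
            v3 = np.zeros(gt.spec.shape + (3,))
            for vi, (i, j, k) in enumerate(vf.voxels):
                dtf = vf.dt_fits[vi]
                if dtf is None:
                    continue
                v1[i, j, k] = dtf.eigenvectors[:, 0]
                v3[i, j, k] = dtf.eigenvectors[:, 2]
            ang = compute_angles(v1, v3, gt.wall_frame)
            io.save_nifti(np.where(gt.roi_mask, ang.helix, np.nan), out / "helix.nii.gz")
            io.save_nifti(
                np.where(gt.roi_mask, ang.sheetlet, np.nan), out / "sheetlet.nii.gz"
            )
        except Exception:
            errors["angles"] = traceback.format_exc(limit=3)
        if cfg.get("sweep"):
            try:
                sw = cfg["sweep"]
                sweep_mask = gt.roi_mask.copy()
                nv = int(sw.get("n_voxels", 0))
                if nv:
                    idx = np.argwhere(sweep_mask)[:nv]
                    sweep_mask = np.zeros_like(sweep_mask)
                    sweep_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
                table = bmax_sweep(
                    data, sweep_mask, cfg["models"], scheme,
                    grid=sw.get("grid"), config=fitcfg,
                )
                table.to_csv(out / "bmax_sweep.tsv", sep="\t", index=False)
            except Exception:
                errors["sweep"] = traceback.format_exc(limit=3)

    if cfg.get("compare") and len(summaries) >= 2:
        try:
            comparisons = [tuple(c) for c in cfg["compare"]]
            table = group_compare(summaries, comparisons)
            table.to_csv(out / "group_compare.tsv", sep="\t", index=False)
        except Exception:
            errors["compare"] = traceback.format_exc(limit=3)

    manifest["errors"] = errors
    manifest["status"] = "partial" if errors else "complete"
    io.save_json(manifest, out / "manifest.json")
    return manifest
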