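"""AICc model ranking and the maximum-b-value sweep.

Models are compared through the Akaike information criterion with the
small-sample correction,

    AICc = n ln(eps^2) + 2P + 2P(P+1)/(n - P - 1),

where eps^2 is the mean squared residual, n the number of measurements and
P the parameter count including the residual variance (8 for the diffusion
tensor; 14 for the stretched exponential, kurtosis, truncated Gaussian and
gamma models; 15 for the biexponential and beta models).  The relative
likelihood of model i — the probability that it minimizes information
loss — is exp((AICc_min - AICc_i)/2).

For the b-value sweep, every model is refit from scratch on the data with
b <= b_max for each b_max on the grid.  The kurtosis model's input data
are further capped at 5000 s/mm^2, but its residuals enter AICc on the
full b <= b_max subset so that n is identical across models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .fitting import FitConfig, fit_volume
from .models import MODEL_SPECS, AcquisitionScheme

__all__ = [
    "aicc",
    "relative_likelihood",
    "SelectionResult",
    "select_models",
    "best_model_map",
    "bmax_sweep",
]

log = logging.getLogger(__name__)


def aicc(n: int, P: int, mse: float) -> float:
    """Corrected Akaike information criterion (natural logarithm)."""
    if mse <= 0:
        raise ValueError("mean squared error must be positive")
    if n <= P + 1:
        raise ValueError(
            f"finite-sample correction is singular: need n > P + 1, got n={n}, P={P}"
        )
    return float(n * np.log(mse) + 2 * P + 2 * P * (P + 1) / (n - P - 1))


def relative_likelihood(aicc_values: dict | np.ndarray):
    """Relative likelihood exp((AICc_min - AICc_i)/2) of each model."""
    if isinstance(aicc_values, dict):
        if not aicc_values:
            raise ValueError("no AICc values supplied")
        keys = list(aicc_values)
        vals = np.array([aicc_values[k] for k in keys], dtype=float)
        p = np.exp((vals.min() - vals) / 2.0)
        return dict(zip(keys, p))
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no AICc values supplied")
    return np.exp((vals.min() - vals) / 2.0)


@dataclass
class SelectionResult:
    """Per-voxel AICc comparison across models."""

    model_ids: list[str]
    aicc: dict  # model -> value
    delta: dict  # model -> AICc - min
    likelihood: dict  # model -> relative likelihood
    n: int
    best: str

    @staticmethod
    def from_mse(mse: dict, n: int) -> "SelectionResult":
        a = {m: aicc(n, MODEL_SPECS[m].n_params_fit, v) for m, v in mse.items()}
        amin = min(a.values())
        # tie break: lowest parameter count, then lexicographic id
        best = min(
            a, key=lambda m: (a[m] - amin > 1e-12, MODEL_SPECS[m].n_params_fit, m)
        )
        return SelectionResult(
            model_ids=list(mse),
            aicc=a,
            delta={m: v - a[best] for m, v in a.items()},
            likelihood=relative_likelihood(a),
            n=n,
            best=best,
        )


def select_models(volume_fit, signals_volume, scheme: AcquisitionScheme) -> list:
    """AICc comparison in every fitted voxel.

    Residuals are re-evaluated on the common measurement set of ``scheme``
    (so the kurtosis model's b-cap does not change n).
    """
    out = []
    models = list(volume_fit.results)
    for vi, (i, j, k) in enumerate(volume_fit.voxels):
        fits = {m: volume_fit.results[m][vi] for m in models}
        if any(f is None for f in fits.values()):
            out.append(None)
            continue
        sig = signals_volume[i, j, k]
        mse = {m: f.residual_mse(sig, scheme) for m, f in fits.items()}
        out.append(SelectionResult.from_mse(mse, n=len(scheme)))
    return out


def best_model_map(
    selections: list, voxels: np.ndarray, shape: tuple, model_ids: list[str]
) -> tuple[np.ndarray, dict]:
    """Integer-coded map of the winning model plus its legend.

    Code 0 marks voxels without a selection; model codes start at 1 in the
    given model order.
    """
    legend = {m: i + 1 for i, m in enumerate(model_ids)}
    out = np.zeros(shape, dtype=np.int16)
    for sel, (i, j, k) in zip(selections, voxels):
        if sel is not None:
            out[i, j, k] = legend[sel.best]
    return out, legend


def bmax_sweep(
    volume: np.ndarray,
    mask: np.ndarray,
    model_ids: list[str],
    scheme: AcquisitionScheme,
    grid=None,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Refit all models for each maximum b-value and rank them by AICc.

    The default grid runs from 1200 to 10,000 s/mm^2 in steps of 400.
    Returns a tidy table with one row per (b_max, model): the ROI-mean RMSE
    and ROI-mean relative likelihood, and the measurement count n.  Cells
    where n <= P + 1 are marked invalid (NaN) rather than failing the
    sweep.
    """
    cfg = config or FitConfig()
    if grid is None:
        grid = np.arange(1200, 10001, 400)
    grid = np.asarray(grid, dtype=float)
    bmax_avail = scheme.b_values.max()
    if np.any(grid > bmax_avail * (1 + 1e-9)):
        raise ValueError("sweep grid exceeds the available b range")
    rows = []
    for b_max in grid:
        keep = scheme.b_values <= b_max
        sub = scheme.subset(keep)
        n = int(np.sum(keep))
        feasible = [m for m in model_ids if n > MODEL_SPECS[m].n_params_fit + 1]
        for m in set(model_ids) - set(feasible):
            rows.append(
                {"b_max": b_max, "model": m, "mean_rmse": np.nan,
                 "mean_rel_likelihood": np.nan, "n": n}
            )
        if not feasible:
            continue
        cfg_b = _dc_replace(cfg, b_max=float(b_max))
        vf = fit_volume(volume[..., keep], mask, feasible, sub, config=cfg_b)
        sels = select_models(vf, volume[..., keep], sub)
        rmse_acc = {m: [] for m in feasible}
        lik_acc = {m: [] for m in feasible}
        for vi, sel in enumerate(sels):
            if sel is None:
                continue
            sig = volume[tuple(vf.voxels[vi])][keep]
            for m in feasible:
                rmse_acc[m].append(np.sqrt(vf.results[m][vi].residual_mse(sig, sub)))
                lik_acc[m].append(sel.likelihood[m])
        for m in feasible:
            rows.append(
                {
                    "b_max": b_max,
                    "model": m,
                    "mean_rmse": float(np.mean(rmse_acc[m])) if rmse_acc[m] else np.nan,
                    "mean_rel_likelihood": float(np.mean(lik_acc[m])) if lik_acc[m] else np.nan,
                    "n": n,
                }
            )
        log.info("sweep b_max=%g done (n=%d)", b_max, n)
    return pd.DataFrame(rows, columns=["b_max", "model", "mean_rmse", "mean_rel_likelihood", "n"])
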