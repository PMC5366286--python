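"""Voxelwise nonlinear least-squares fitting in the tensor eigenframe.

Non-Gaussian models are one-dimensional, so the observed attenuation is
factorized as the product of the attenuation along each diffusion-tensor
eigenvector,

    S(b)/S(0) = f(b1) * f(b2) * f(b3),    b_i = b (g . v_i)^2,

with per-axis shape parameters plus any global scalars.  Six symmetric
tensor elements parameterize the reference frame; only their eigenvectors
enter the forward model of the non-Gaussian models (their eigenvalues are
redundant there, but the parameterization matches the per-model parameter
counts used for AICc).  Optimization uses a trust-region-reflective
bounded least-squares solver with positivity constraints.

Initialization cascade: the diffusion tensor and diffusion kurtosis models
are initialized by linear least squares on the log-signal; the stretched
exponential starts from the tensor fit (a = 1); the biexponential from
segmented monoexponential fits to low (< 1000 s/mm^2) and high
(> 6000 s/mm^2) b-values; the truncated Gaussian, gamma and beta models
from the mean diffusivity and kurtosis of the kurtosis fit, the beta
model's Dmax starting at the diffusivity of free water at room
temperature, 2.3e-3 mm^2/s.  Diffusion-kurtosis fits use only
measurements with b <= 5000 s/mm^2, where the truncated cumulant
expansion is trustworthy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import models as M
from .models import AcquisitionScheme, MODEL_SPECS
from .tensor import TensorFit, fit_dt_linear, project_b

__all__ = [
    "FitConfig",
    "FitResult",
    "VolumeFitResult",
    "fit_dk_linear",
    "initialize",
    "fit_voxel",
    "fit_volume",
    "DEFAULT_BOUNDS",
]

log = logging.getLogger(__name__)

#: free-water diffusivity at room temperature, mm^2/s (beta-model Dmax start)
D_FREE_WATER = 2.3e-3

#: physical ceiling on diffusivity-like parameters, mm^2/s
D_CEIL = 5e-3

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "D": (0.0, D_CEIL),
    "Ds": (0.0, D_CEIL),
    "a": (1e-6, 1.0),
    "K": (0.0, 10.0),
    "Dfast": (0.0, D_CEIL),
    "Dslow": (0.0, D_CEIL),
    "v": (0.0, 1.0),
    "Dm": (0.0, D_CEIL),
    "sigma": (1e-6 * 1e-3, 5e-3),  # mm^2/s scale of the diffusivity spread
    "theta": (1e-9, D_CEIL),
    "k": (1e-6, 1e3),
    "alpha": (1e-6, 1e3),
    "beta": (1e-6, 1e3),
    "Dmax": (0.5e-3, D_CEIL),
}


@dataclass
class FitConfig:
    """Fitting configuration.

    b_max restricts the data entering all fits (None = use everything);
    dk_b_cap additionally restricts the diffusion-kurtosis model's input
    data (default 5000 s/mm^2).  Tolerances are for the trust-region
    solver.  With ``freeze_frame`` the eigenframe is taken from the tensor
    fit instead of being optimized jointly.
    """

    b_max: float | None = None
    dk_b_cap: float = 5000.0
    dt_b_max: float = 2000.0
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_iter: int = 500
    seed: int = 0
    n_frame_restarts: int = 3
    freeze_frame: bool = False
    stretched_form: str = "b^a*Ds"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self):
        if self.ftol <= 0 or self.xtol <= 0 or self.max_iter <= 0:
            raise ValueError("tolerances and max_iter must be positive")


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------


class _Layout:
    """Maps the flat optimizer vector to named model parameters.

    Vector order: S0, then (unless the frame is frozen) the six symmetric
    tensor elements Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, then each per-axis
    parameter as a triplet, then global scalars.
    """

    def __init__(self, model_id: str, cfg: FitConfig, s0_hint: float):
        spec = MODEL_SPECS[model_id]
        self.model_id = model_id
        self.frozen = cfg.freeze_frame and model_id != "dt"
        self.with_frame = model_id == "dt" or not self.frozen
        names: list[str] = ["S0"]
        lo: list[float] = [0.0]
        hi: list[float] = [max(10.0 * s0_hint, 1.0)]
        if self.with_frame:
            for nm in ("Dxx", "Dyy", "Dzz"):
                names.append(nm)
                lo.append(0.0)
                hi.append(D_CEIL)
            for nm in ("Dxy", "Dxz", "Dyz"):
                names.append(nm)
                lo.append(-D_CEIL)
                hi.append(D_CEIL)
        self.axis_slices: dict[str, slice] = {}
        for nm in spec.axis_params:
            self.axis_slices[nm] = slice(len(names), len(names) + 3)
            b = cfg.bounds[nm]
            for ax in (1, 2, 3):
                names.append(f"{nm}_{ax}")
                lo.append(b[0])
                hi.append(b[1])
        self.global_idx: dict[str, int] = {}
        for nm in spec.global_params:
            self.global_idx[nm] = len(names)
            b = cfg.bounds[nm]
            names.append(nm)
            lo.append(b[0])
            hi.append(b[1])
        self.names = names
        self.lo = np.array(lo)
        self.hi = np.array(hi)
        self.n = len(names)

    def tensor_of(self, x: np.ndarray) -> np.ndarray | None:
        if not self.with_frame:
            return None
        dxx, dyy, dzz, dxy, dxz, dyz = x[1:7]
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])

    def axis_params_of(self, x: np.ndarray, axis: int) -> dict:
        p = {nm: x[sl][axis] for nm, sl in self.axis_slices.items()}
        for nm, i in self.global_idx.items():
            p[nm] = x[i]
        return p

    def pack(self, s0, tensor, axis_params: dict, global_params: dict) -> np.ndarray:
        x = np.empty(self.n)
        x[0] = s0
        if self.with_frame:
            t = np.asarray(tensor)
            x[1:7] = [t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]
        for nm, sl in self.axis_slices.items():
            x[sl] = axis_params[nm]
        for nm, i in self.global_idx.items():
            x[i] = global_params[nm]
        return np.clip(x, self.lo, self.hi)


def _eigvecs_desc(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lams, vecs = np.linalg.eigh(tensor)
    order = np.argsort(lams)[::-1]
    return lams[order], vecs[:, order]


def _forward(x, layout: _Layout, b, g, frozen_vecs, stretched_form):
    s0 = x[0]
    model_id = layout.model_id
    if model_id == "dt":
        D = layout.tensor_of(x)
        quad = np.einsum("ni,ij,nj->n", g, D, g)
        return s0 * np.exp(-b * quad)
    if layout.with_frame:
        _, V = _eigvecs_desc(layout.tensor_of(x))
    else:
        V = frozen_vecs
    bproj = b[:, None] * (g @ V) ** 2
    att = np.ones_like(b)
    fn = M._SIGNALS[model_id]
    for ax in range(3):
        p = layout.axis_params_of(x, ax)
        if model_id == "biexp" and p["Dfast"] < p["Dslow"]:
            p = {**p, "Dfast": p["Dslow"], "Dslow": p["Dfast"]}
        if model_id == "stretched" and stretched_form == "(b*Ds)^a":
            att = att * np.exp(-((bproj[:, ax] * p["Ds"]) ** p["a"]))
        else:
            att = att * fn(bproj[:, ax], p)
    return s0 * att


# ---------------------------------------------------------------------------
# linear diffusion-kurtosis fit (initialization backbone)
# ---------------------------------------------------------------------------


def fit_dk_linear(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    eigenvectors: np.ndarray,
    b_cap: float = 5000.0,
) -> dict:
    """Linear least-squares kurtosis fit along a fixed eigenframe.

    Regresses the log-signal on the projected weightings b_i and b_i^2,
    yielding per-axis apparent diffusivity and kurtosis.
    """
    signals = np.asarray(signals, dtype=float)
    keep = (scheme.b_values <= b_cap) & (signals > 0)
    bproj = project_b(scheme, eigenvectors)[keep]
    y = np.log(signals[keep])
    X = np.column_stack([np.ones(bproj.shape[0]), -bproj, bproj**2 / 6.0])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    D = coef[1:4]
    w = coef[4:7]  # = D_i^2 K_i
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(D != 0, w / D**2, 0.0)
    return {"s0": float(np.exp(coef[0])), "D": D, "K": K}


# ---------------------------------------------------------------------------
# initialization cascade
# ---------------------------------------------------------------------------


def _moments_to_gamma(Dbar, K):
    k = 3.0 / K
    return {"k": k, "theta": Dbar / k}


def _moments_to_truncgauss(Dbar, K):
    return {"Dm": Dbar, "sigma": Dbar * np.sqrt(K / 3.0)}


def _moments_to_beta(Dbar, K, Dmax):
    mu = np.clip(Dbar / Dmax, 1e-6, 0.99)
    alpha = 3.0 * (1.0 - mu) / K - mu
    alpha = np.maximum(alpha, 1e-6)
    beta = alpha * (1.0 - mu) / mu
    return {"alpha": alpha, "beta": beta}


def initialize(
    model_id: str,
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    dt_fit: TensorFit,
    dk_fit: dict | None = None,
    config: FitConfig | None = None,
) -> np.ndarray:
    """Starting vector for :func:`fit_voxel`, clipped into bounds."""
    cfg = config or FitConfig()
    layout = _Layout(model_id, cfg, dt_fit.s0)
    lams = np.clip(dt_fit.eigenvalues, 1e-6, D_CEIL)
    axis: dict = {}
    glob: dict = {}
    if model_id in ("dt", "monoexp"):
        pass
    elif model_id == "stretched":
        axis = {"Ds": lams, "a": np.ones(3)}
    elif model_id in ("dk", "truncgauss", "gamma", "beta"):
        if dk_fit is None:
            dk_fit = fit_dk_linear(
                signals, scheme, dt_fit.eigenvectors, b_cap=cfg.dk_b_cap
            )
        D = np.clip(dk_fit["D"], 1e-6, D_CEIL)
        K = np.asarray(dk_fit["K"], dtype=float).copy()
        if np.any(K <= 0):
            warnings.warn(
                "nonpositive kurtosis at initialization; falling back to K=0.01",
                stacklevel=2,
            )
            K[K <= 0] = 0.01
        K = np.clip(K, 1e-4, 10.0)
        if model_id == "dk":
            axis = {"D": D, "K": K}
        elif model_id == "gamma":
            axis = _moments_to_gamma(D, K)
        elif model_id == "truncgauss":
            axis = _moments_to_truncgauss(D, K)
        else:
            axis = _moments_to_beta(D, K, D_FREE_WATER)
            glob = {"Dmax": D_FREE_WATER}
    elif model_id == "biexp":
        sig = np.asarray(signals, dtype=float)
        bproj = project_b(scheme, dt_fit.eigenvectors)
        lo = (scheme.b_values < 1000.0) & (sig > 0)
        hi = (scheme.b_values > 6000.0) & (sig > 0)
        Dfast = lams.copy()
        Dslow = 0.3 * lams
        v = 0.8
        if np.sum(lo) >= 4:
            Xl = np.column_stack([np.ones(int(np.sum(lo))), -bproj[lo]])
            cl, _, _, _ = np.linalg.lstsq(Xl, np.log(sig[lo]), rcond=None)
            Dfast = np.clip(cl[1:4], 1e-6, D_CEIL)
        if np.sum(hi) >= 4:
            Xh = np.column_stack([np.ones(int(np.sum(hi))), -bproj[hi]])
            ch, _, _, _ = np.linalg.lstsq(Xh, np.log(sig[hi]), rcond=None)
            Dslow = np.clip(ch[1:4], 1e-6, D_CEIL)
            # intercept of the high-b segment estimates (1-v) S0
            v = float(np.clip(1.0 - np.exp(ch[0]) / dt_fit.s0, 0.0, 1.0))
        Dslow = np.minimum(Dslow, Dfast)
        axis = {"Dfast": Dfast, "Dslow": Dslow}
        glob = {"v": v}
    else:
        raise ValueError(f"unknown model '{model_id}'")
    return layout.pack(dt_fit.s0, dt_fit.tensor, axis, glob)


# ---------------------------------------------------------------------------
# voxel fit
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged (or best-found) parameters of one voxel/model fit."""

    model_id: str
    x: np.ndarray
    names: list[str]
    s0: float
    frame_tensor: np.ndarray | None
    eigenvectors: np.ndarray
    axis_params: dict  # per-axis arrays of length 3
    global_params: dict
    eps2: float  # mean squared residual over the fitted measurements
    rmse: float
    n_used: int
    converged: bool
    n_iter: int
    _layout: _Layout = field(repr=False, default=None)
    _stretched_form: str = field(repr=False, default="b^a*Ds")

    def predict(self, scheme: AcquisitionScheme) -> np.ndarray:
        """Forward-model signal at the given scheme's measurements."""
        return _forward(
            self.x,
            self._layout,
            scheme.b_values,
            scheme.directions,
            self.eigenvectors,
            self._stretched_form,
        )

    def residual_mse(self, signals: np.ndarray, scheme: AcquisitionScheme) -> float:
        """Mean squared residual of this fit on an arbitrary measurement set."""
        r = np.asarray(signals, dtype=float) - self.predict(scheme)
        return float(np.mean(r**2))

    @property
    def params(self) -> dict:
        out = {"S0": self.s0}
        out.update({k: np.asarray(v) for k, v in self.axis_params.items()})
        out.update(self.global_params)
        return out

    def derived_moments(self) -> dict:
        """Per-axis mean diffusivity / kurtosis / skewness of the fitted model."""
        if self.model_id == "dt":
            lams, _ = _eigvecs_desc(self.frame_tensor)
            per_axis = [M.derived_moments("monoexp", {"D": max(l, 0.0)}) for l in lams]
        else:
            per_axis = [
                M.derived_moments(self.model_id, self._layout.axis_params_of(self.x, ax))
                for ax in range(3)
            ]
        keys = per_axis[0].keys()
        return {k: np.array([m[k] for m in per_axis]) for k in keys}


def _frame_candidates(dt_fit: TensorFit, n_restarts: int) -> list[TensorFit]:
    """Initial eigenframes: the tensor frame plus rotations in its most
    degenerate eigen-plane.

    The log-linear tensor fit cannot separate eigenvectors whose apparent
    diffusivities nearly coincide (non-Gaussian attenuation compresses
    distinct axes toward equal low-b slopes), so the joint fit is restarted
    from frames rotated within that plane and the lowest-residual solution
    kept.  Deterministic: rotation angles are a fixed grid.
    """
    if n_restarts <= 1:
        return [dt_fit]
    lam = dt_fit.eigenvalues
    V = dt_fit.eigenvectors
    # rotate within the plane of the closest eigenvalue pair
    gap12 = abs(lam[0] - lam[1])
    gap23 = abs(lam[1] - lam[2])
    i, j = (1, 2) if gap23 <= gap12 else (0, 1)
    thetas = np.linspace(0.0, np.pi / 2.0, n_restarts)[1:]
    out = [dt_fit]
    # distinct surrogate eigenvalues keep the rebuilt tensor's eigh ordering
    lam_tilde = np.sort(lam)[::-1] + np.array([2e-6, 1e-6, 0.0])
    for th in thetas:
        Vr = V.copy()
        c, s = np.cos(th), np.sin(th)
        Vr[:, i] = c * V[:, i] + s * V[:, j]
        Vr[:, j] = -s * V[:, i] + c * V[:, j]
        tensor_r = Vr @ np.diag(lam_tilde) @ Vr.T
        out.append(
            TensorFit(
                s0=dt_fit.s0,
                tensor=tensor_r,
                eigenvalues=lam_tilde,
                eigenvectors=Vr,
                mean_adc=dt_fit.mean_adc,
                fa=dt_fit.fa,
                residual_mse=dt_fit.residual_mse,
                n_used=dt_fit.n_used,
                negative_eigenvalues=dt_fit.negative_eigenvalues,
            )
        )
    return out


def fit_voxel(
    model_id: str,
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
    dt_fit: TensorFit | None = None,
    dk_fit: dict | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Bounded trust-region least-squares fit of one model to one voxel.

    Returns the best-found parameters with ``converged=False`` when the
    iteration cap is reached; never raises for nonconvergence.
    """
    cfg = config or FitConfig()
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (len(scheme),):
        raise ValueError(f"signal length {signals.shape} != scheme length {len(scheme)}")
    b_cap = cfg.b_max if cfg.b_max is not None else np.inf
    if model_id == "dk":
        b_cap = min(b_cap, cfg.dk_b_cap)
    keep = scheme.b_values <= b_cap
    sub = scheme.subset(keep)
    y = signals[keep]
    if dt_fit is None:
        dt_fit = fit_dt_linear(signals, scheme, b_max=min(cfg.dt_b_max, b_cap))
    layout = _Layout(model_id, cfg, dt_fit.s0)
    if y.size < layout.n:
        raise ValueError(
            f"{y.size} measurements < {layout.n} free parameters for '{model_id}'"
        )
    b, g = sub.b_values, sub.directions

    def solve_from(x0_c, frozen_vecs):
        def resid(x):
            return _forward(x, layout, b, g, frozen_vecs, cfg.stretched_form) - y

        # scale columns so diffusivities (~1e-3) and S0 (~1e4) step comparably
        x_scale = np.maximum(np.abs(x0_c), (layout.hi - layout.lo) * 1e-3)
        return least_squares(
            resid,
            x0_c,
            bounds=(layout.lo, layout.hi),
            method="trf",
            ftol=cfg.ftol,
            xtol=cfg.xtol,
            gtol=1e-12,
            max_nfev=cfg.max_iter * layout.n,
            x_scale=x_scale,
        )

    if x0 is not None or model_id == "dt":
        if x0 is None:
            x0 = initialize(model_id, signals, scheme, dt_fit, dk_fit=dk_fit, config=cfg)
        x0 = np.clip(np.asarray(x0, dtype=float), layout.lo, layout.hi)
        frozen_vecs = dt_fit.eigenvectors
        sol = solve_from(x0, frozen_vecs)
    else:
        sol = None
        frozen_vecs = dt_fit.eigenvectors
        for ci, cand in enumerate(_frame_candidates(dt_fit, cfg.n_frame_restarts)):
            with warnings.catch_warnings():
                if ci > 0:  # rotated frames routinely see negative apparent K
                    warnings.simplefilter("ignore")
                x0_c = initialize(
                    model_id, signals, scheme, cand,
                    dk_fit=dk_fit if ci == 0 else None, config=cfg,
                )
            x0_c = np.clip(x0_c, layout.lo, layout.hi)
            sol_c = solve_from(x0_c, cand.eigenvectors)
            if sol is None or sol_c.cost < sol.cost:
                sol = sol_c
                frozen_vecs = cand.eigenvectors
    x = sol.x

    def resid(x):
        return _forward(x, layout, b, g, frozen_vecs, cfg.stretched_form) - y

    # Canonical axis order.  The factorized forward model is invariant to
    # permuting axis labels together with the eigenvectors, and for the
    # non-Gaussian models the frame tensor's eigenvalues (which define the
    # label order) are not part of the forward model.  Relabel so that axis 1
    # has the highest apparent diffusivity (strongest attenuation at a
    # reference b), matching the fiber/sheetlet/sheetlet-normal convention.
    if layout.axis_slices and model_id != "dt":
        b_ref = np.array([1000.0])
        att = []
        for ax in range(3):
            p = layout.axis_params_of(x, ax)
            if model_id == "biexp" and p["Dfast"] < p["Dslow"]:
                p = {**p, "Dfast": p["Dslow"], "Dslow": p["Dfast"]}
            fn = M._SIGNALS[model_id]
            if model_id == "stretched" and cfg.stretched_form == "(b*Ds)^a":
                att.append(float(np.exp(-((b_ref[0] * p["Ds"]) ** p["a"]))))
            else:
                att.append(float(fn(b_ref, p)[0]))
        perm = np.argsort(att)  # most attenuated (highest D) first
        if not np.array_equal(perm, [0, 1, 2]):
            for sl in layout.axis_slices.values():
                x[sl] = x[sl][perm]
            if layout.with_frame:
                _, V_old = _eigvecs_desc(layout.tensor_of(x))
                V_new = V_old[:, perm]
                d = np.array([3e-3, 2e-3, 1e-3])  # surrogate, order-encoding only
                t = V_new @ np.diag(d) @ V_new.T
                x[1:7] = [t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]]
            else:
                frozen_vecs = frozen_vecs[:, perm]

    if model_id == "biexp":  # resolve label switching
        sl_f, sl_s = layout.axis_slices["Dfast"], layout.axis_slices["Dslow"]
        df, ds = x[sl_f].copy(), x[sl_s].copy()
        swap = df < ds
        df[swap], ds[swap] = ds[swap], df[swap].copy()
        x[sl_f], x[sl_s] = df, ds
    r = resid(x)
    eps2 = float(np.mean(r**2))
    if layout.with_frame and model_id != "dt":
        _, V = _eigvecs_desc(layout.tensor_of(x))
    elif model_id == "dt":
        _, V = _eigvecs_desc(layout.tensor_of(x))
    else:
        V = frozen_vecs
    return FitResult(
        model_id=model_id,
        x=x,
        names=layout.names,
        s0=float(x[0]),
        frame_tensor=layout.tensor_of(x),
        eigenvectors=V,
        axis_params={nm: x[sl].copy() for nm, sl in layout.axis_slices.items()},
        global_params={nm: float(x[i]) for nm, i in layout.global_idx.items()},
        eps2=eps2,
        rmse=float(np.sqrt(eps2)),
        n_used=int(y.size),
        converged=bool(sol.status > 0 and sol.status != 0),
        n_iter=int(sol.nfev),
        _layout=layout,
        _stretched_form=cfg.stretched_form,
    )


# ---------------------------------------------------------------------------
# volume fit
# ---------------------------------------------------------------------------


@dataclass
class VolumeFitResult:
    """Per-voxel fit results for a set of models over a mask."""

    voxels: np.ndarray  # (K, 3) integer coordinates
    results: dict  # model_id -> list of FitResult | None (skipped voxels)
    dt_fits: list
    n_skipped: int


def fit_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    model_ids: list[str],
    scheme: AcquisitionScheme,
    config: FitConfig | None = None,
) -> VolumeFitResult:
    """Fit every requested model in every mask voxel of a 4-D volume.

    Deterministic given the configuration; all-zero voxels are skipped and
    counted.  The diffusion-tensor and linear kurtosis fits are shared
    across the per-voxel model fits.
    """
    cfg = config or FitConfig()
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.ndim != 4 or volume.shape[-1] != len(scheme):
        raise ValueError(
            f"volume shape {volume.shape} incompatible with scheme length {len(scheme)}"
        )
    if mask.shape != volume.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} != volume grid {volume.shape[:3]}")
    voxels = np.argwhere(mask)
    results: dict = {m: [] for m in model_ids}
    dt_fits: list = []
    needs_dk = {"dk", "truncgauss", "gamma", "beta"}
    n_skipped = 0
    for idx, (i, j, k) in enumerate(voxels):
        sig = volume[i, j, k]
        if not np.any(sig > 0):
            n_skipped += 1
            dt_fits.append(None)
            for m in model_ids:
                results[m].append(None)
            continue
        b_cap = cfg.b_max if cfg.b_max is not None else np.inf
        dt_fit = fit_dt_linear(sig, scheme, b_max=min(cfg.dt_b_max, b_cap))
        dt_fits.append(dt_fit)
        dk_lin = None
        if needs_dk.intersection(model_ids):
            dk_lin = fit_dk_linear(
                sig, scheme, dt_fit.eigenvectors, b_cap=min(cfg.dk_b_cap, b_cap)
            )
        for m in model_ids:
            results[m].append(
                fit_voxel(m, sig, scheme, config=cfg, dt_fit=dt_fit, dk_fit=dk_lin)
            )
        if (idx + 1) % 50 == 0:
            log.info("fit %d/%d voxels", idx + 1, len(voxels))
    return VolumeFitResult(
        voxels=voxels, results=results, dt_fits=dt_fits, n_skipped=n_skipped
    )
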