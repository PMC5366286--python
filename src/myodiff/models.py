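"""Closed-form diffusion signal models, diffusivity distributions and moments.

Seven models of the diffusion-weighted MR signal are implemented, each
expressed as a normalized attenuation ``S(b)/S(0)`` along a single axis:

* ``monoexp``    — single Gaussian compartment, ``exp(-b*D)``
* ``stretched``  — stretched exponential, ``exp(-b**a * Ds)``
* ``dk``         — diffusion kurtosis (quadratic cumulant expansion)
* ``biexp``      — two Gaussian compartments with volume fraction ``v``
* ``truncgauss`` — Gaussian distribution of diffusivities truncated at 0
* ``gamma``      — gamma distribution of diffusivities
* ``beta``       — beta distribution of diffusivities on ``(0, Dmax)``
* ``dt``         — alias of ``monoexp`` used for volume fitting, where the
  per-axis diffusivities are the eigenvalues of the diffusion tensor

The statistical models (truncgauss, gamma, beta, and the Gaussian density
underlying dk) arise from the spectrum-of-diffusivities picture

    S(b)/S(0) = integral P(D) exp(-b D) dD

so every closed form here can be cross-checked against numerical quadrature
of its diffusivity density (:func:`signal_from_pdf_numeric`).

Units: b-values in s/mm^2, diffusivities in mm^2/s, times in s.
Kurtosis throughout is the normalized variance of the diffusivity
distribution, K = 3 Var[D] / E[D]^2 (zero for a single Gaussian
compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, special

__all__ = [
    "MODEL_IDS",
    "AcquisitionScheme",
    "ModelSpec",
    "MODEL_SPECS",
    "DiffusivityPDF",
    "Propagator",
    "UnsupportedModelOperation",
    "HypergeometricError",
    "evaluate_signal",
    "evaluate_pdf",
    "point_mass_pdf",
    "derived_moments",
    "signal_from_pdf_numeric",
    "displacement_profile",
    "b_value_from_gradient",
]

#: gyromagnetic ratio of the proton, rad/s/T
GAMMA_PROTON = 2.675e8

MODEL_IDS = ("monoexp", "stretched", "dk", "biexp", "truncgauss", "gamma", "beta", "dt")


class UnsupportedModelOperation(ValueError):
    """Raised when a model does not define the requested quantity."""


class HypergeometricError(RuntimeError):
    """Confluent hypergeometric evaluation failed to converge.

    Carries ``args = (a, b, z)`` of the offending Kummer M(a, b, z) call.
    """


# ---------------------------------------------------------------------------
# acquisition scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionScheme:
    """q-space sampling design of a pulsed-gradient acquisition.

    Parameters
    ----------
    b_values : (N,) array
        Diffusion weighting per measurement, s/mm^2.
    directions : (N, 3) array
        Unit gradient directions; rows for b=0 measurements may be zero.
    delta : float
        Gradient pulse duration, s.
    Delta : float
        Diffusion time (pulse separation), s.
    gamma : float
        Gyromagnetic ratio, rad/s/T.
    G : (N,) array, optional
        Gradient amplitude per measurement, T/m.  If given it must be
        consistent with ``b = (gamma*delta*G)^2 (Delta - delta/3)``.
    """

    b_values: np.ndarray
    directions: np.ndarray
    delta: float
    Delta: float
    gamma: float = GAMMA_PROTON
    G: np.ndarray | None = None

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError(f"shape mismatch: b {b.shape}, directions {g.shape}")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(g, axis=1)
        dw = b > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must have unit norm")
        if not self.delta < self.Delta:
            raise ValueError("gradient duration delta must be < diffusion time Delta")
        if self.G is not None:
            G = np.asarray(self.G, dtype=float)
            object.__setattr__(self, "G", G)
            b_pred = b_value_from_gradient(self.gamma, self.delta, G, self.Delta)
            scale = np.maximum(b, 1.0)
            if np.any(np.abs(b_pred - b) / scale > 1e-3):
                raise ValueError("G inconsistent with b = (gamma*delta*G)^2 (Delta - delta/3)")

    def __len__(self) -> int:
        return self.b_values.size

    @property
    def n_non_dw(self) -> int:
        return int(np.sum(self.b_values == 0))

    @property
    def diffusion_time_effective(self) -> float:
        """Effective diffusion time Delta - delta/3, s."""
        return self.Delta - self.delta / 3.0

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        """Restrict the scheme to the measurements selected by ``mask``."""
        mask = np.asarray(mask, dtype=bool)
        return AcquisitionScheme(
            b_values=self.b_values[mask],
            directions=self.directions[mask],
            delta=self.delta,
            Delta=self.Delta,
            gamma=self.gamma,
            G=None if self.G is None else self.G[mask],
        )


def b_value_from_gradient(gamma: float, delta, G, Delta) -> np.ndarray | float:
    """b-value of a rectangular pulsed-gradient pair, in s/mm^2.

    b = (gamma*delta*G)^2 (Delta - delta/3), evaluated in SI (s/m^2) and
    converted to s/mm^2 by the explicit factor 1e-6.
    """
    if np.any(np.asarray(gamma) <= 0) or np.any(np.asarray(delta) <= 0):
        raise ValueError("gamma and delta must be positive")
    if np.any(np.asarray(G) < 0):
        raise ValueError("gradient amplitude must be nonnegative")
    if not np.all(np.asarray(delta) < np.asarray(Delta)):
        raise ValueError("delta must be smaller than Delta")
    b_si = (gamma * delta * np.asarray(G)) ** 2 * (Delta - delta / 3.0)
    return b_si * 1e-6


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Identity and parameter accounting of one signal model.

    ``n_params_fit`` is the parameter count P entering AICc: S(0), the six
    tensor elements defining the eigenframe, the model's own shape
    parameters, and the residual variance.
    """

    model_id: str
    n_params_fit: int
    axis_params: tuple[str, ...]  # fitted per eigenvector axis
    global_params: tuple[str, ...]  # shared across axes
    has_pdf: bool
    has_moments: bool


MODEL_SPECS: dict[str, ModelSpec] = {
    s.model_id: s
    for s in [
        # P counts include S0 (1), tensor frame (6) and the residual variance (1)
        ModelSpec("dt", 8, (), (), False, True),
        ModelSpec("monoexp", 8, ("D",), (), True, True),
        ModelSpec("stretched", 14, ("Ds", "a"), (), False, False),
        ModelSpec("dk", 14, ("D", "K"), (), True, True),
        ModelSpec("biexp", 15, ("Dfast", "Dslow"), ("v",), True, True),
        ModelSpec("truncgauss", 14, ("Dm", "sigma"), (), True, True),
        ModelSpec("gamma", 14, ("theta", "k"), (), True, True),
        ModelSpec("beta", 15, ("alpha", "beta"), ("Dmax",), True, True),
    ]
}


def _check(cond: bool, msg: str):
    if not cond:
        raise ValueError(msg)


def _validate_params(model_id: str, p: dict) -> None:
    if model_id in ("monoexp", "dt"):
        _check(p["D"] >= 0, "monoexp: bound violated: D >= 0")
    elif model_id == "stretched":
        _check(p["Ds"] >= 0, "stretched: bound violated: Ds >= 0")
        _check(0 < p["a"] <= 1, "stretched: bound violated: 0 < a <= 1")
    elif model_id == "dk":
        _check(p["D"] >= 0, "dk: bound violated: D >= 0")
        _check(p["K"] >= 0, "dk: bound violated: K >= 0")
    elif model_id == "biexp":
        _check(0 <= p["v"] <= 1, "biexp: bound violated: v in [0, 1]")
        _check(p["Dfast"] >= 0 and p["Dslow"] >= 0, "biexp: bound violated: diffusivities >= 0")
        _check(p["Dfast"] >= p["Dslow"], "biexp: bound violated: Dfast >= Dslow")
    elif model_id == "truncgauss":
        _check(p["Dm"] >= 0, "truncgauss: bound violated: Dm >= 0")
        _check(p["sigma"] > 0, "truncgauss: bound violated: sigma > 0")
    elif model_id == "gamma":
        _check(p["k"] > 0, "gamma: bound violated: k > 0")
        _check(p["theta"] > 0, "gamma: bound violated: theta > 0")
    elif model_id == "beta":
        _check(p["alpha"] > 0, "beta: bound violated: alpha > 0")
        _check(p["beta"] > 0, "beta: bound violated: beta > 0")
        _check(p["Dmax"] > 0, "beta: bound violated: Dmax > 0")
    else:
        raise ValueError(f"unknown model '{model_id}'")


# ---------------------------------------------------------------------------
# signal attenuations (1-D, per axis)
# ---------------------------------------------------------------------------


def _signal_truncgauss(b, Dm, sigma):
    # S(b) = [1 + erf(Dm/(sqrt2 sigma) - b sigma/sqrt2)] / [1 + erf(Dm/(sqrt2 sigma))]
    #        * exp(-b Dm + b^2 sigma^2 / 2)
    # Evaluated through erfcx for stability at large b:
    # with u = Dm/(sqrt2 sigma), t = b sigma/sqrt2,
    # S = erfcx(t - u) * exp(-u^2) / (1 + erf(u)).
    u = Dm / (np.sqrt(2.0) * sigma)
    t = np.asarray(b, dtype=float) * sigma / np.sqrt(2.0)
    denom = 1.0 + special.erf(u)
    # erfcx(t - u) overflows for t << u (sigma -> 0); split on the sign of
    # t - u using erfcx(-x) = 2 exp(x^2) - erfcx(x):
    #   t >= u: S = erfcx(t-u) exp(-u^2) / denom
    #   t <  u: S = [2 exp(b^2 s^2/2 - b Dm) - erfcx(u-t) exp(-u^2)] / denom
    d = t - u
    with np.errstate(over="ignore", under="ignore"):
        upper = special.erfcx(np.abs(d)) * np.exp(-(u**2))
        lower = 2.0 * np.exp(t**2 - 2.0 * t * u) - upper
    return np.where(d >= 0, upper, lower) / denom


def _signal_beta(b, alpha, beta, Dmax):
    z = -np.asarray(b, dtype=float) * Dmax
    out = special.hyp1f1(alpha, alpha + beta, z)
    if not np.all(np.isfinite(out)):
        bad = np.asarray(z)[~np.isfinite(np.atleast_1d(out))]
        z0 = float(np.atleast_1d(bad).flat[0]) if bad.size else float(np.min(z))
        raise HypergeometricError(alpha, alpha + beta, z0)
    return out


_SIGNALS: dict[str, Callable] = {
    "monoexp": lambda b, p: np.exp(-b * p["D"]),
    "dt": lambda b, p: np.exp(-b * p["D"]),
    "stretched": lambda b, p: np.exp(-(b ** p["a"]) * p["Ds"]),
    # exponent clipped: extreme (D, K) corners explored during bounded
    # optimization must stay finite for the solver
    "dk": lambda b, p: np.exp(
        np.minimum(-b * p["D"] + p["K"] / 6.0 * b**2 * p["D"] ** 2, 200.0)
    ),
    "biexp": lambda b, p: p["v"] * np.exp(-b * p["Dfast"])
    + (1.0 - p["v"]) * np.exp(-b * p["Dslow"]),
    "truncgauss": lambda b, p: _signal_truncgauss(b, p["Dm"], p["sigma"]),
    "gamma": lambda b, p: (1.0 + b * p["theta"]) ** (-p["k"]),
    "beta": lambda b, p: _signal_beta(b, p["alpha"], p["beta"], p["Dmax"]),
}


def evaluate_signal(model_id: str, params: dict, b, *, stretched_form: str = "b^a*Ds"):
    """Normalized signal attenuation S(b)/S(0) of one model along one axis.

    Parameters
    ----------
    model_id : str
        One of :data:`MODEL_IDS`.
    params : dict
        Model parameters; see the module docstring for names.
    b : array_like
        b-values, s/mm^2; must be nonnegative.
    stretched_form : {"b^a*Ds", "(b*Ds)^a"}
        Placement of the stretching exponent.  The default stretches the
        b-value only, with Ds a stretch-adjusted scale; the alternative form
        ``exp(-(b*Ds)**a)`` is common elsewhere in the literature.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    _validate_params(model_id, params)
    if model_id == "stretched" and stretched_form == "(b*Ds)^a":
        return np.exp(-((b * params["Ds"]) ** params["a"]))
    elif model_id == "stretched" and stretched_form != "b^a*Ds":
        raise ValueError(f"unknown stretched_form '{stretched_form}'")
    return _SIGNALS[model_id](b, params)


# ---------------------------------------------------------------------------
# diffusivity PDFs
# ---------------------------------------------------------------------------


@dataclass
class DiffusivityPDF:
    """Distribution of diffusivities within a voxel.

    Continuous models carry a grid of density values plus the analytic
    density callable; the monoexponential and biexponential models are
    atomic (weighted point masses) and carry locations/weights instead.
    """

    model_id: str
    params: dict
    support: tuple[float, float]
    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    density_fn: Callable | None = field(default=None, repr=False)
    point_locations: np.ndarray | None = None
    point_weights: np.ndarray | None = None

    @property
    def is_atomic(self) -> bool:
        return self.point_locations is not None


def _pdf_callable(model_id: str, p: dict) -> tuple[Callable, tuple[float, float]]:
    if model_id == "truncgauss":
        Dm, sigma = p["Dm"], p["sigma"]
        # normalizing coefficient restoring unit mass after truncation at D=0
        A = 2.0 / (sigma * np.sqrt(2 * np.pi) * (1.0 + special.erf(Dm / (sigma * np.sqrt(2)))))

        def fn(D):
            D = np.asarray(D, dtype=float)
            return np.where(D >= 0, A * np.exp(-((D - Dm) ** 2) / (2 * sigma**2)), 0.0)

        hi = Dm + 10 * sigma
        return fn, (0.0, hi)
    if model_id == "gamma":
        k, theta = p["k"], p["theta"]

        def fn(D):
            D = np.asarray(D, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(
                    D > 0,
                    np.exp(
                        (k - 1) * np.log(np.maximum(D, 1e-300))
                        - D / theta
                        - special.gammaln(k)
                        - k * np.log(theta)
                    ),
                    0.0,
                )
            return out

        hi = theta * (k + 20 * np.sqrt(k) + 20)
        return fn, (0.0, hi)
    if model_id == "beta":
        a, b_, Dmax = p["alpha"], p["beta"], p["Dmax"]
        lnB = special.betaln(a, b_)

        def fn(D):
            D = np.asarray(D, dtype=float)
            x = D / Dmax
            inside = (x > 0) & (x < 1)
            xi = np.where(inside, x, 0.5)
            lnf = (a - 1) * np.log(xi) + (b_ - 1) * np.log1p(-xi) - lnB - np.log(Dmax)
            return np.where(inside, np.exp(lnf), 0.0)

        return fn, (0.0, Dmax)
    if model_id == "dk":
        # Gaussian with mean D and variance D^2 K / 3; deliberately NOT
        # truncated at zero, so kurtosis K is exact but negative
        # diffusivities carry mass.
        D, K = p["D"], p["K"]
        var = D**2 * K / 3.0
        if var == 0:
            raise UnsupportedModelOperation("dk with K=0 is a point mass at D")
        sd = np.sqrt(var)

        def fn(x):
            x = np.asarray(x, dtype=float)
            return np.exp(-((x - D) ** 2) / (2 * var)) / (sd * np.sqrt(2 * np.pi))

        return fn, (D - 10 * sd, D + 10 * sd)
    raise UnsupportedModelOperation(f"model '{model_id}' has no analytic continuous PDF")


def point_mass_pdf(model_id: str, params: dict) -> DiffusivityPDF:
    """Atomic diffusivity distribution of the mono/biexponential models."""
    _validate_params(model_id, params)
    if model_id in ("monoexp", "dt"):
        locs, w = np.array([params["D"]]), np.array([1.0])
    elif model_id == "biexp":
        locs = np.array([params["Dfast"], params["Dslow"]])
        w = np.array([params["v"], 1.0 - params["v"]])
    else:
        raise UnsupportedModelOperation(f"model '{model_id}' is not atomic")
    return DiffusivityPDF(
        model_id=model_id,
        params=dict(params),
        support=(float(locs.min()), float(locs.max())),
        point_locations=locs,
        point_weights=w,
    )


def evaluate_pdf(model_id: str, params: dict, D_grid) -> DiffusivityPDF:
    """Diffusivity density P(D) evaluated on a grid.

    The stretched exponential has no analytic diffusivity distribution and
    is refused; the mono- and biexponential models are point masses — use
    :func:`point_mass_pdf` for those.  The dk density is a Gaussian that is
    not truncated at zero, so (alone among the models) its grid may extend
    to negative diffusivities.
    """
    if model_id == "stretched":
        raise UnsupportedModelOperation(
            "stretched exponential: the diffusivity PDF has no analytical form"
        )
    if model_id in ("monoexp", "dt", "biexp"):
        raise UnsupportedModelOperation(
            f"model '{model_id}' has a delta-function PDF; use point_mass_pdf"
        )
    _validate_params(model_id, params)
    D_grid = np.asarray(D_grid, dtype=float)
    if model_id != "dk" and np.any(D_grid < 0):
        raise ValueError("diffusivity grid extends below 0")
    fn, support = _pdf_callable(model_id, params)
    return DiffusivityPDF(
        model_id=model_id,
        params=dict(params),
        support=support,
        grid=D_grid,
        density=fn(D_grid),
        density_fn=fn,
    )


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def derived_moments(model_id: str, params: dict) -> dict:
    """Mean diffusivity, kurtosis and (gamma/beta only) skewness.

    Kurtosis is the normalized variance K = 3 Var[D] / E[D]^2.  Skewness is
    the standardized third moment of the diffusivity distribution; it is
    reported only for the gamma and beta models, the two families whose
    shape admits meaningful asymmetry.
    """
    _validate_params(model_id, params)
    p = params
    if model_id in ("monoexp", "dt"):
        return {"mean_diffusivity": p["D"], "kurtosis": 0.0}
    if model_id == "dk":
        return {"mean_diffusivity": p["D"], "kurtosis": p["K"]}
    if model_id == "biexp":
        mean = p["v"] * p["Dfast"] + (1 - p["v"]) * p["Dslow"]
        K = 3 * p["v"] * (1 - p["v"]) * (p["Dfast"] - p["Dslow"]) ** 2 / mean**2
        return {"mean_diffusivity": mean, "kurtosis": K}
    if model_id == "truncgauss":
        Dm, sigma = p["Dm"], p["sigma"]
        u = Dm / (sigma * np.sqrt(2))
        mean = Dm + sigma * np.sqrt(2 / np.pi) * np.exp(-(u**2)) / (1 + special.erf(u))
        K = 3 * (sigma**2 - mean**2 + mean * Dm) / mean**2
        return {"mean_diffusivity": mean, "kurtosis": K}
    if model_id == "gamma":
        k = p["k"]
        return {
            "mean_diffusivity": k * p["theta"],
            "kurtosis": 3.0 / k,
            "skewness": 2.0 / np.sqrt(k),
        }
    if model_id == "beta":
        a, b_, Dmax = p["alpha"], p["beta"], p["Dmax"]
        s = a + b_
        mean = a / s * Dmax
        K = 3 * b_ / (a * (s + 1))
        skew = 2 * (b_ - a) * np.sqrt(s + 1) / ((s + 2) * np.sqrt(a * b_))
        return {"mean_diffusivity": mean, "kurtosis": K, "skewness": skew}
    raise UnsupportedModelOperation(
        "stretched exponential: neither the mean diffusivity nor the diffusion "
        "kurtosis can be derived from this model"
    )


# ---------------------------------------------------------------------------
# quadrature oracle for spectrum-of-diffusivities signals
# ---------------------------------------------------------------------------


def signal_from_pdf_numeric(pdf: DiffusivityPDF, b) -> np.ndarray | float:
    """Signal attenuation by numerical integration of P(D) exp(-b D).

    This is the independent reference for every closed-form signal: the
    spectrum-of-diffusivities integral is evaluated by adaptive quadrature
    (absolute tolerance 1e-9) on the distribution's analytic density, or by
    exact summation for atomic distributions.
    """
    b = np.asarray(b, dtype=float)
    if pdf.is_atomic:
        w = pdf.point_weights
        if abs(w.sum() - 1.0) > 1e-4:
            raise ValueError("pdf weights do not sum to 1")
        out = np.sum(w * np.exp(-np.multiply.outer(b, pdf.point_locations)), axis=-1)
        return out if b.ndim else float(out)
    fn = pdf.density_fn
    lo, hi = pdf.support
    if fn is None:
        if pdf.grid is None or pdf.density is None:
            raise ValueError("pdf carries neither a density callable nor a grid")
        from scipy.interpolate import interp1d

        fn = interp1d(pdf.grid, pdf.density, kind="cubic", bounds_error=False, fill_value=0.0)
        lo, hi = float(pdf.grid.min()), float(pdf.grid.max())
    mass = integrate.quad(fn, lo, hi, epsabs=1e-9, limit=200, full_output=1)[0]
    if abs(mass - 1.0) > 1e-4:
        raise ValueError(f"pdf is not normalized: integral = {mass:.6g}")

    def one(bi):
        return integrate.quad(
            lambda D: fn(D) * np.exp(-bi * D), lo, hi, epsabs=1e-9, limit=200,
            full_output=1,
        )[0]

    out = np.vectorize(one)(b)
    return out if b.ndim else float(out)


# ---------------------------------------------------------------------------
# displacement propagator
# ---------------------------------------------------------------------------


@dataclass
class Propagator:
    """One-dimensional ensemble-average displacement profile.

    Obtained as the inverse Fourier transform of the q-space signal; the
    full widths at half and tenth maximum summarize the displacement length
    scales (the FWTM tracks the fastest-moving spins).
    """

    displacements: np.ndarray  # mm
    density: np.ndarray  # 1/mm
    fwhm: float
    fwtm: float
    diffusion_time_effective: float


def _full_width(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """Width of y(x) at ``level * max(y)``, linear interpolation at the crossings."""
    thr = level * y.max()
    above = y >= thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0.0
    i0, i1 = idx[0], idx[-1]
    # left crossing
    if i0 == 0:
        left = x[0]
    else:
        x0, x1_, y0, y1_ = x[i0 - 1], x[i0], y[i0 - 1], y[i0]
        left = x0 + (thr - y0) / (y1_ - y0) * (x1_ - x0)
    if i1 == y.size - 1:
        right = x[-1]
    else:
        x0, x1_, y0, y1_ = x[i1], x[i1 + 1], y[i1], y[i1 + 1]
        right = x0 + (thr - y0) / (y1_ - y0) * (x1_ - x0)
    return float(right - left)


def displacement_profile(
    model_id: str,
    params: dict,
    delta: float,
    Delta: float,
    q_grid: np.ndarray,
) -> Propagator:
    """Displacement profile via inverse Fourier transform of the signal.

    The q-grid (1/mm) must be uniform and symmetric about zero.  The signal
    is evaluated at b = 4 pi^2 q^2 (Delta - delta/3) and inverse-transformed;
    because the signal is real and even in q the propagator is real and
    symmetric.
    """
    q = np.asarray(q_grid, dtype=float)
    dq = np.diff(q)
    if not np.allclose(dq, dq[0], rtol=1e-9, atol=0):
        raise ValueError("q grid must be uniform")
    if abs(q[0] + q[-1]) > 1e-9 * max(abs(q[0]), 1e-30):
        raise ValueError("q grid must be symmetric about zero")
    td = Delta - delta / 3.0
    b = 4 * np.pi**2 * q**2 * td
    E = np.asarray(evaluate_signal(model_id, params, b), dtype=float)
    n = q.size
    step = dq[0]
    # continuous inverse FT approximated by a DFT on the shifted grid
    spec = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(E))) * step
    x = np.fft.fftshift(np.fft.fftfreq(n, d=step))
    dens = np.real(spec)
    fwhm = _full_width(x, dens, 0.5)
    fwtm = _full_width(x, dens, 0.1)
    dx = x[1] - x[0]
    if fwhm < 4 * dx:
        raise ValueError(
            f"q grid too coarse: propagator FWHM {fwhm:.3g} mm spans fewer than "
            f"4 displacement steps of {dx:.3g} mm; extend the q range"
        )
    return Propagator(
        displacements=x,
        density=dens,
        fwhm=fwhm,
        fwtm=fwtm,
        diffusion_time_effective=td,
    )
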