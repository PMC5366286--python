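"""Diffusion-tensor estimation, eigenframe utilities and cardiac angle maps.

The diffusion tensor is estimated by linear least squares on the
log-signal.  Scalar maps follow the standard definitions

    mean ADC = (l1 + l2 + l3) / 3
    FA       = sqrt(3/2) * sqrt(sum (l_i - lbar)^2 / sum l_i^2)

Helix, transverse and sheetlet angles are computed from the primary and
tertiary eigenvectors relative to a local wall coordinate system
(longitudinal / circumferential / radial).  For phantoms the generator
supplies the true frame; for real data a cylindrical approximation is
available (:func:`cylindrical_wall_frame`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import AcquisitionScheme

__all__ = [
    "TensorFit",
    "LocalWallFrame",
    "AngleMaps",
    "fit_dt_linear",
    "project_b",
    "compute_angles",
    "cylindrical_wall_frame",
    "fa_from_eigenvalues",
]


@dataclass
class TensorFit:
    """Result of a linear diffusion-tensor fit for one voxel."""

    s0: float
    tensor: np.ndarray  # symmetric 3x3, mm^2/s
    eigenvalues: np.ndarray  # sorted descending, mm^2/s
    eigenvectors: np.ndarray  # columns v1, v2, v3
    mean_adc: float
    fa: float
    residual_mse: float  # on log-signal scale
    n_used: int
    negative_eigenvalues: bool


@dataclass
class LocalWallFrame:
    """Per-voxel orthonormal wall triad (trailing axis holds the 3-vector)."""

    longitudinal: np.ndarray
    circumferential: np.ndarray
    radial: np.ndarray

    def validate(self, atol: float = 1e-6) -> None:
        for a, b in (
            (self.longitudinal, self.circumferential),
            (self.longitudinal, self.radial),
            (self.circumferential, self.radial),
        ):
            if np.max(np.abs(np.sum(a * b, axis=-1))) > atol:
                raise ValueError("wall frame axes are not orthogonal")
        for a in (self.longitudinal, self.circumferential, self.radial):
            if np.max(np.abs(np.linalg.norm(a, axis=-1) - 1)) > atol:
                raise ValueError("wall frame axes are not unit length")


@dataclass
class AngleMaps:
    """Cardiac angle maps in degrees; NaN marks degenerate voxels."""

    helix: np.ndarray
    transverse: np.ndarray
    sheetlet: np.ndarray


def fa_from_eigenvalues(lams: np.ndarray) -> np.ndarray | float:
    """Fractional anisotropy from eigenvalues (last axis of length 3)."""
    lams = np.asarray(lams, dtype=float)
    lbar = lams.mean(axis=-1, keepdims=True)
    num = np.sum((lams - lbar) ** 2, axis=-1)
    den = np.sum(lams**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return fa


def _design_matrix(b: np.ndarray, g: np.ndarray) -> np.ndarray:
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def fit_dt_linear(
    signals: np.ndarray, scheme: AcquisitionScheme, b_max: float = 2000.0
) -> TensorFit:
    """Linear least-squares diffusion-tensor fit on the log-signal.

    Measurements above ``b_max`` (default 2000 s/mm^2, the regime where the
    Gaussian model still describes myocardium well) and nonpositive signals
    are excluded.  Negative eigenvalues are permitted in the output but
    flagged.
    """
    signals = np.asarray(signals, dtype=float)
    keep = scheme.b_values <= b_max
    pos = signals > 0
    n_dropped = int(np.sum(keep & ~pos))
    keep &= pos
    if np.sum(keep) < 7:
        raise ValueError(
            f"need >= 7 usable measurements below b_max={b_max}, have {int(np.sum(keep))} "
            f"({n_dropped} nonpositive signals excluded)"
        )
    b = scheme.b_values[keep]
    g = scheme.directions[keep]
    X = _design_matrix(b, g)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient tensor design: need >= 6 non-collinear gradient directions"
        )
    y = np.log(signals[keep])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    s0 = float(np.exp(coef[0]))
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    lams, vecs = np.linalg.eigh(D)
    order = np.argsort(lams)[::-1]
    lams = lams[order]
    vecs = vecs[:, order]
    return TensorFit(
        s0=s0,
        tensor=D,
        eigenvalues=lams,
        eigenvectors=vecs,
        mean_adc=float(lams.mean()),
        fa=float(fa_from_eigenvalues(lams)),
        residual_mse=float(np.mean(resid**2)),
        n_used=int(np.sum(keep)),
        negative_eigenvalues=bool(np.any(lams < 0)),
    )


def project_b(scheme: AcquisitionScheme, eigenvectors: np.ndarray) -> np.ndarray:
    """Diffusion weighting projected onto each eigenvector.

    Returns an (N, 3) array with ``b_i = b * (g . v_i)^2``; the three
    components of every row sum exactly to the measurement's b-value
    because the eigenvectors are orthonormal.
    """
    V = np.asarray(eigenvectors, dtype=float)
    if V.shape != (3, 3):
        raise ValueError("eigenvectors must be a 3x3 matrix with columns v1, v2, v3")
    if np.max(np.abs(V.T @ V - np.eye(3))) > 1e-6:
        raise ValueError("eigenvectors are not orthonormal")
    g = scheme.directions
    dw = scheme.b_values > 0
    if np.any(np.abs(np.linalg.norm(g[dw], axis=1) - 1) > 1e-6):
        raise ValueError("gradient directions are not unit vectors")
    cos2 = (g @ V) ** 2
    return scheme.b_values[:, None] * cos2


def cylindrical_wall_frame(
    shape: tuple[int, int, int],
    long_axis: np.ndarray = (0.0, 0.0, 1.0),
    center: tuple[float, float] | None = None,
) -> LocalWallFrame:
    """Cylindrical local wall coordinates for a short-axis stack.

    A pragmatic stand-in when no mesh-based wall coordinate system is
    available: the longitudinal axis is global, the radial axis points away
    from the per-slice centroid, and the circumferential axis completes the
    right-handed triad (circ = long x radial).
    """
    long_axis = np.asarray(long_axis, dtype=float)
    long_axis = long_axis / np.linalg.norm(long_axis)
    nx, ny, nz = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rx = xx - center[0]
    ry = yy - center[1]
    r = np.sqrt(rx**2 + ry**2)
    r = np.where(r == 0, 1.0, r)
    radial2d = np.stack([rx / r, ry / r, np.zeros_like(rx)], axis=-1)
    radial = np.broadcast_to(radial2d[:, :, None, :], (nx, ny, nz, 3)).copy()
    longitudinal = np.broadcast_to(long_axis, (nx, ny, nz, 3)).copy()
    circumferential = np.cross(longitudinal, radial)
    norm = np.linalg.norm(circumferential, axis=-1, keepdims=True)
    circumferential = circumferential / np.where(norm == 0, 1.0, norm)
    return LocalWallFrame(longitudinal, circumferential, radial)


def compute_angles(
    v1: np.ndarray, v3: np.ndarray, frame: LocalWallFrame
) -> AngleMaps:
    """Helix, transverse and sheetlet angle maps in degrees.

    * helix: angle between the projection of v1 onto the
      circumferential-longitudinal plane and the short-axis plane
      (0 deg when v1 is circumferential, +/-90 deg when longitudinal);
    * transverse: angle between the projection of v1 onto the short-axis
      plane and the circumferential-longitudinal plane;
    * sheetlet: angle between the projection of v3 onto the
      longitudinal-radial plane and the short-axis plane (0 deg when v3 is
      radial).

    Eigenvector signs are fixed (v1.circ >= 0, v3.radial >= 0) before the
    computation, so the maps are invariant to sign flips.  Voxels with a
    degenerate projection get NaN.
    """
    v1 = np.asarray(v1, dtype=float)
    v3 = np.asarray(v3, dtype=float)
    c = np.sum(v1 * frame.circumferential, axis=-1)
    l = np.sum(v1 * frame.longitudinal, axis=-1)
    r = np.sum(v1 * frame.radial, axis=-1)
    sign = np.where(c < 0, -1.0, 1.0)
    c, l, r = c * sign, l * sign, r * sign
    with np.errstate(invalid="ignore"):
        helix = np.degrees(np.arctan2(l, c))
        transverse = np.degrees(np.arctan2(r, c))
    degen = (np.abs(c) < 1e-12) & (np.abs(l) < 1e-12)
    helix = np.where(degen, np.nan, helix)
    # v1 purely longitudinal: helix is +/-90; arctan2(l, 0) handles it
    degen_t = (np.abs(c) < 1e-12) & (np.abs(r) < 1e-12)
    transverse = np.where(degen_t, np.nan, transverse)

    r3 = np.sum(v3 * frame.radial, axis=-1)
    l3 = np.sum(v3 * frame.longitudinal, axis=-1)
    sign3 = np.where(r3 < 0, -1.0, 1.0)
    r3, l3 = r3 * sign3, l3 * sign3
    with np.errstate(invalid="ignore"):
        sheetlet = np.degrees(np.arctan2(l3, r3))
    degen_s = (np.abs(r3) < 1e-12) & (np.abs(l3) < 1e-12)
    sheetlet = np.where(degen_s, np.nan, sheetlet)
    return AngleMaps(helix=helix, transverse=transverse, sheetlet=sheetlet)
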