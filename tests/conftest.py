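"""Shared fixtures: schemes, phantoms and reference parameter sets."""

import numpy as np
import pytest
from hypothesis import settings

from myodiff import fitting as F
from myodiff import phantom as P

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid_scheme_514():
    """Symmetric Cartesian 514-direction scheme, b up to 10,000 s/mm^2."""
    return P.make_scheme(514, 10000.0, 4, style="grid-full", seed=0)


@pytest.fixture(scope="session")
def grid_scheme_257():
    return P.make_scheme(257, 10000.0, 4, style="grid-half", seed=0)


@pytest.fixture(scope="session")
def random_frame():
    """A fixed random orthonormal eigenframe (columns v1, v2, v3)."""
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    return q


# per-axis parameter sets spanning the myocardial ranges reported for the
# three groups (mean diffusivities ~0.8-1.4e-3 mm^2/s, kurtosis ~0.1-0.7)
MODEL_CASES = {
    "monoexp": ({"D": np.array([1.37e-3, 1.01e-3, 0.92e-3])}, {}),
    "stretched": (
        {"Ds": np.array([1.3e-3, 0.9e-3, 0.8e-3]), "a": np.array([0.95, 0.85, 0.8])},
        {},
    ),
    "dk": (
        {"D": np.array([1.37e-3, 1.01e-3, 0.92e-3]), "K": np.array([0.13, 0.45, 0.55])},
        {},
    ),
    "biexp": (
        {
            "Dfast": np.array([1.51e-3, 1.14e-3, 1.04e-3]),
            "Dslow": np.array([0.48e-3, 0.21e-3, 0.16e-3]),
        },
        {"v": 0.86},
    ),
    "truncgauss": (
        {
            "Dm": np.array([1.37e-3, 1.01e-3, 0.92e-3]),
            "sigma": np.array([2.8e-4, 3.9e-4, 3.9e-4]),
        },
        {},
    ),
    "gamma": (
        {"k": np.array([23.1, 6.67, 5.45]), "theta": np.array([5.9e-5, 1.5e-4, 1.7e-4])},
        {},
    ),
    "beta": (
        {"alpha": np.array([0.84, 2.62, 1.17]), "beta": np.array([0.09, 1.29, 0.76])},
        {"Dmax": 1.52e-3},
    ),
}


def axis_param_dict(model_id, axis):
    ap, gp = MODEL_CASES[model_id]
    p = {k: float(v[axis]) for k, v in ap.items()}
    p.update(gp)
    return p


def forward_signal(model_id, axis_params, global_params, frame, s0, scheme):
    """Noiseless factorized forward model, independent of the fitting code."""
    from myodiff import models as M

    b = scheme.b_values
    bproj = b[:, None] * (scheme.directions @ frame) ** 2
    att = np.ones(len(scheme))
    for ax in range(3):
        p = {k: float(v[ax]) for k, v in axis_params.items()}
        p.update(global_params)
        att = att * M.evaluate_signal(model_id, p, bproj[:, ax])
    return s0 * att


@pytest.fixture(scope="session")
def fit_config():
    return F.FitConfig()
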