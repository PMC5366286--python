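"""Initialization cascade and voxelwise NLS fitting tests."""

import warnings

import numpy as np
import pytest

from conftest import MODEL_CASES, forward_signal
from myodiff import fitting as F
from myodiff import tensor as T
from myodiff import phantom as P

S0 = 2.36e4


@pytest.fixture(autouse=True)
def _quiet_init_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


class TestInitialize:
    def _dt_fit(self, scheme, signal):
        return T.fit_dt_linear(signal, scheme, b_max=2000)

    def test_gamma_init_inverts_dk_moments(self, grid_scheme_514, random_frame):
        sig = forward_signal("gamma", *MODEL_CASES["gamma"], random_frame, S0, grid_scheme_514)
        dtf = self._dt_fit(grid_scheme_514, sig)
        dk_fit = {"s0": S0, "D": np.full(3, 1e-3), "K": np.full(3, 0.5)}
        x0 = F.initialize("gamma", sig, grid_scheme_514, dtf, dk_fit=dk_fit)
        layout = F._Layout("gamma", F.FitConfig(), dtf.s0)
        k = x0[layout.axis_slices["k"]]
        theta = x0[layout.axis_slices["theta"]]
        np.testing.assert_allclose(k, 6.0, rtol=1e-12)
        np.testing.assert_allclose(theta, 1e-3 / 6.0, rtol=1e-12)

    def test_truncgauss_init_inverts_dk_moments(self, grid_scheme_514, random_frame):
        sig = forward_signal("truncgauss", *MODEL_CASES["truncgauss"], random_frame, S0, grid_scheme_514)
        dtf = self._dt_fit(grid_scheme_514, sig)
        dk_fit = {"s0": S0, "D": np.full(3, 1.2e-3), "K": np.full(3, 0.3)}
        x0 = F.initialize("truncgauss", sig, grid_scheme_514, dtf, dk_fit=dk_fit)
        layout = F._Layout("truncgauss", F.FitConfig(), dtf.s0)
        np.testing.assert_allclose(x0[layout.axis_slices["Dm"]], 1.2e-3, rtol=1e-12)
        np.testing.assert_allclose(
            x0[layout.axis_slices["sigma"]], 1.2e-3 * np.sqrt(0.1), rtol=1e-12
        )

    def test_stretched_init_is_dt_with_unit_exponent(self, grid_scheme_514, random_frame):
        sig = forward_signal("stretched", *MODEL_CASES["stretched"], random_frame, S0, grid_scheme_514)
        dtf = self._dt_fit(grid_scheme_514, sig)
        x0 = F.initialize("stretched", sig, grid_scheme_514, dtf)
        layout = F._Layout("stretched", F.FitConfig(), dtf.s0)
        np.testing.assert_allclose(x0[layout.axis_slices["a"]], 1.0)
        np.testing.assert_allclose(
            x0[layout.axis_slices["Ds"]], np.clip(dtf.eigenvalues, 1e-6, None), rtol=1e-10
        )

    def test_beta_dmax_starts_at_free_water(self, grid_scheme_514, random_frame):
        sig = forward_signal("beta", *MODEL_CASES["beta"], random_frame, S0, grid_scheme_514)
        dtf = self._dt_fit(grid_scheme_514, sig)
        dk_fit = {"s0": S0, "D": np.full(3, 1e-3), "K": np.full(3, 0.4)}
        x0 = F.initialize("beta", sig, grid_scheme_514, dtf, dk_fit=dk_fit)
        layout = F._Layout("beta", F.FitConfig(), dtf.s0)
        assert x0[layout.global_idx["Dmax"]] == pytest.approx(2.3e-3)

    def test_nonpositive_kurtosis_falls_back_with_warning(self, grid_scheme_514, random_frame):
        sig = forward_signal("gamma", *MODEL_CASES["gamma"], random_frame, S0, grid_scheme_514)
        dtf = self._dt_fit(grid_scheme_514, sig)
        dk_fit = {"s0": S0, "D": np.full(3, 1e-3), "K": np.array([0.5, -0.2, 0.1])}
        with pytest.warns(UserWarning, match="nonpositive kurtosis"):
            x0 = F.initialize("gamma", sig, grid_scheme_514, dtf, dk_fit=dk_fit)
        layout = F._Layout("gamma", F.FitConfig(), dtf.s0)
        assert x0[layout.axis_slices["k"]][1] == pytest.approx(3.0 / 0.01)

    def test_dk_linear_fit_recovers_noiseless_dk(self, grid_scheme_514):
        ap, gp = MODEL_CASES["dk"]
        sig = forward_signal("dk", ap, gp, np.eye(3), S0, grid_scheme_514)
        out = F.fit_dk_linear(sig, grid_scheme_514, np.eye(3), b_cap=5000)
        np.testing.assert_allclose(out["D"], ap["D"], rtol=1e-10)
        np.testing.assert_allclose(out["K"], ap["K"], rtol=1e-8)


class TestFitVoxel:
    @pytest.mark.parametrize("model_id", ["stretched", "dk", "biexp", "truncgauss", "gamma", "beta"])
    def test_noiseless_self_recovery(self, model_id, grid_scheme_514, random_frame, fit_config):
        ap, gp = MODEL_CASES[model_id]
        sig = forward_signal(model_id, ap, gp, random_frame, S0, grid_scheme_514)
        fr = F.fit_voxel(model_id, sig, grid_scheme_514, fit_config)
        for name, truth in ap.items():
            np.testing.assert_allclose(fr.axis_params[name], truth, rtol=1e-4)
        for name, truth in gp.items():
            assert fr.global_params[name] == pytest.approx(truth, rel=1e-4)
        assert fr.s0 == pytest.approx(S0, rel=1e-6)

    def test_monoexp_data_fit_by_dk_gives_zero_kurtosis(self, grid_scheme_514, random_frame):
        ap = {"D": np.array([1.4e-3, 0.9e-3, 0.7e-3])}
        sig = forward_signal("monoexp", ap, {}, random_frame, S0, grid_scheme_514)
        fr = F.fit_voxel("dk", sig, grid_scheme_514, F.FitConfig())
        np.testing.assert_allclose(fr.axis_params["K"], 0.0, atol=1e-3)

    def test_dk_only_uses_capped_b(self, grid_scheme_514, random_frame):
        ap, gp = MODEL_CASES["dk"]
        sig = forward_signal("dk", ap, gp, random_frame, S0, grid_scheme_514)
        fr = F.fit_voxel("dk", sig, grid_scheme_514, F.FitConfig(dk_b_cap=5000.0))
        assert fr.n_used == int(np.sum(grid_scheme_514.b_values <= 5000.0))

    def test_refit_from_solution_is_fixed_point(self, grid_scheme_514, random_frame):
        ap, gp = MODEL_CASES["gamma"]
        sig = forward_signal("gamma", ap, gp, random_frame, S0, grid_scheme_514)
        cfg = F.FitConfig()
        fr1 = F.fit_voxel("gamma", sig, grid_scheme_514, cfg)
        fr2 = F.fit_voxel("gamma", sig, grid_scheme_514, cfg, x0=fr1.x.copy())
        np.testing.assert_allclose(fr2.x, fr1.x, rtol=1e-8, atol=1e-12)

    def test_residual_never_worse_than_init(self, grid_scheme_514, random_frame):
        # monotone improvement of the trust-region solver vs its start
        ap, gp = MODEL_CASES["truncgauss"]
        sig = forward_signal("truncgauss", ap, gp, random_frame, S0, grid_scheme_514)
        noisy = sig + np.random.default_rng(0).normal(0, 200.0, sig.shape)
        dtf = T.fit_dt_linear(noisy, grid_scheme_514, b_max=2000)
        cfg = F.FitConfig()
        x0 = F.initialize("truncgauss", noisy, grid_scheme_514, dtf, config=cfg)
        fr = F.fit_voxel("truncgauss", noisy, grid_scheme_514, cfg, dt_fit=dtf, x0=x0)
        layout = F._Layout("truncgauss", cfg, dtf.s0)
        r0 = F._forward(
            np.clip(x0, layout.lo, layout.hi), layout,
            grid_scheme_514.b_values, grid_scheme_514.directions,
            dtf.eigenvectors, cfg.stretched_form,
        ) - noisy
        assert fr.eps2 <= np.mean(r0**2) + 1e-12

    def test_biexp_fast_slow_ordering_enforced(self, grid_scheme_514, random_frame):
        ap, gp = MODEL_CASES["biexp"]
        sig = forward_signal("biexp", ap, gp, random_frame, S0, grid_scheme_514)
        fr = F.fit_voxel("biexp", sig, grid_scheme_514, F.FitConfig())
        assert np.all(fr.axis_params["Dfast"] >= fr.axis_params["Dslow"])

    def test_too_few_measurements_rejected(self):
        scheme = P.make_scheme(10, 3000.0, 2, style="shells", seed=0)
        with pytest.raises(ValueError, match="free parameters"):
            sig = np.exp(-scheme.b_values * 1e-3)
            F.fit_voxel("beta", sig, scheme, F.FitConfig(), dt_fit=_fake_dt())


def _fake_dt():
    return T.TensorFit(
        s0=1.0, tensor=np.eye(3) * 1e-3, eigenvalues=np.full(3, 1e-3),
        eigenvectors=np.eye(3), mean_adc=1e-3, fa=0.0, residual_mse=0.0,
        n_used=10, negative_eigenvalues=False,
    )


class TestFitVolume:
    def test_empty_mask_is_empty_output(self, grid_scheme_257):
        vol = np.ones((2, 2, 1, len(grid_scheme_257)))
        out = F.fit_volume(vol, np.zeros((2, 2, 1), bool), ["dt"], grid_scheme_257)
        assert out.voxels.size == 0 and out.results["dt"] == []

    def test_identical_voxels_identical_results(self, grid_scheme_257, random_frame):
        ap, gp = MODEL_CASES["gamma"]
        sig = forward_signal("gamma", ap, gp, random_frame, S0, grid_scheme_257)
        vol = np.broadcast_to(sig, (1, 2, 1, sig.size)).copy()
        out = F.fit_volume(vol, np.ones((1, 2, 1), bool), ["gamma"], grid_scheme_257)
        np.testing.assert_array_equal(out.results["gamma"][0].x, out.results["gamma"][1].x)

    def test_all_zero_voxel_skipped(self, grid_scheme_257, random_frame):
        ap, gp = MODEL_CASES["dk"]
        sig = forward_signal("dk", ap, gp, random_frame, S0, grid_scheme_257)
        vol = np.zeros((2, 1, 1, sig.size))
        vol[0, 0, 0] = sig
        out = F.fit_volume(vol, np.ones((2, 1, 1), bool), ["dk"], grid_scheme_257)
        assert out.n_skipped == 1
        assert out.results["dk"][1] is None
        assert out.results["dk"][0] is not None

    def test_shape_mismatch_reports_dimensions(self, grid_scheme_257):
        vol = np.ones((2, 2, 1, 10))
        with pytest.raises(ValueError, match="incompatible"):
            F.fit_volume(vol, np.ones((2, 2, 1), bool), ["dt"], grid_scheme_257)
        vol = np.ones((2, 2, 1, len(grid_scheme_257)))
        with pytest.raises(ValueError, match="mask shape"):
            F.fit_volume(vol, np.ones((3, 2, 1), bool), ["dt"], grid_scheme_257)
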