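"""Model-zoo tests: closed forms vs quadrature, moments, limits, propagator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myodiff import models as M

B_GRID = np.array([0.0, 500.0, 2000.0, 5000.0, 10000.0])

CONTINUOUS_CASES = [
    ("truncgauss", {"Dm": 1.0e-3, "sigma": 3.0e-4}),
    ("truncgauss", {"Dm": 0.9e-3, "sigma": 4.5e-4}),
    ("gamma", {"k": 2.0, "theta": 0.5e-3}),
    ("gamma", {"k": 6.7, "theta": 1.5e-4}),
    ("beta", {"alpha": 0.84, "beta": 0.09, "Dmax": 1.52e-3}),
    ("beta", {"alpha": 2.6, "beta": 1.3, "Dmax": 1.5e-3}),
    ("dk", {"D": 1.0e-3, "K": 0.5}),
]


class TestSignalQuadratureEquivalence:
    """Every closed-form attenuation equals the Laplace transform of its PDF."""

    @pytest.mark.parametrize("model_id,params", CONTINUOUS_CASES)
    def test_continuous_models(self, model_id, params):
        grid = np.linspace(-5e-3 if model_id == "dk" else 0.0, 5e-3, 64)
        pdf = M.evaluate_pdf(model_id, params, grid)
        closed = M.evaluate_signal(model_id, params, B_GRID)
        quad = M.signal_from_pdf_numeric(pdf, B_GRID)
        np.testing.assert_allclose(quad, closed, rtol=1e-6)

    def test_point_mass_is_exp(self):
        pdf = M.point_mass_pdf("monoexp", {"D": 1.2e-3})
        np.testing.assert_allclose(
            M.signal_from_pdf_numeric(pdf, B_GRID), np.exp(-B_GRID * 1.2e-3), rtol=1e-12
        )

    def test_two_point_masses_match_biexp(self):
        # fast/slow compartments of 1.5/0.5 um^2/ms at fraction 0.9
        params = {"v": 0.9, "Dfast": 1.5e-3, "Dslow": 0.5e-3}
        pdf = M.point_mass_pdf("biexp", params)
        np.testing.assert_allclose(
            M.signal_from_pdf_numeric(pdf, B_GRID),
            M.evaluate_signal("biexp", params, B_GRID),
            rtol=1e-12,
        )

    def test_unnormalized_pdf_rejected(self):
        pdf = M.evaluate_pdf("gamma", {"k": 2.0, "theta": 0.5e-3}, np.linspace(0, 5e-3, 50))
        pdf.density_fn = lambda D: 2.0 * np.exp(-np.asarray(D) / 1e-3) / 1e-3
        with pytest.raises(ValueError, match="not normalized"):
            M.signal_from_pdf_numeric(pdf, 1000.0)


class TestSignalBasics:
    @pytest.mark.parametrize("model_id", ["monoexp", "stretched", "dk", "biexp", "truncgauss", "gamma", "beta"])
    def test_unit_attenuation_at_b0(self, model_id):
        from conftest import axis_param_dict

        assert M.evaluate_signal(model_id, axis_param_dict(model_id, 0), 0.0) == pytest.approx(1.0)

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError, match="negative b"):
            M.evaluate_signal("monoexp", {"D": 1e-3}, -10.0)

    def test_bound_violation_names_parameter(self):
        with pytest.raises(ValueError, match="Dfast >= Dslow"):
            M.evaluate_signal("biexp", {"v": 0.5, "Dfast": 1e-4, "Dslow": 1e-3}, 100.0)
        with pytest.raises(ValueError, match="0 < a <= 1"):
            M.evaluate_signal("stretched", {"Ds": 1e-3, "a": 1.2}, 100.0)

    def test_degenerate_biexp_is_monoexp(self):
        b = np.linspace(0, 10000, 40)
        np.testing.assert_allclose(
            M.evaluate_signal("biexp", {"v": 1.0, "Dfast": 1e-3, "Dslow": 0.2e-3}, b),
            M.evaluate_signal("monoexp", {"D": 1e-3}, b),
            rtol=1e-12,
        )

    def test_stretched_alternative_form(self):
        b = np.array([0.0, 1000.0, 4000.0])
        s = M.evaluate_signal(
            "stretched", {"Ds": 1e-3, "a": 0.8}, b, stretched_form="(b*Ds)^a"
        )
        np.testing.assert_allclose(s, np.exp(-((b * 1e-3) ** 0.8)), rtol=1e-12)

    @given(
        b=st.floats(1.0, 10000.0),
        D=st.floats(1e-4, 3e-3),
        K=st.floats(0.01, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_dk_decreases_below_curve_minimum(self, b, D, K):
        # quadratic log-signal has its minimum at b = 3/(D K)
        b_min = 3.0 / (D * K)
        b2 = min(b * 1.01, b_min)
        if b >= b_min:
            return
        s1 = M.evaluate_signal("dk", {"D": D, "K": K}, b)
        s2 = M.evaluate_signal("dk", {"D": D, "K": K}, b2)
        assert s2 <= s1 + 1e-15

    @given(
        data=st.sampled_from(CONTINUOUS_CASES[:-1]),  # dk excluded (non-monotone)
        b=st.floats(0.0, 9000.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_signals_strictly_decreasing(self, data, b):
        model_id, params = data
        s1 = M.evaluate_signal(model_id, params, b)
        s2 = M.evaluate_signal(model_id, params, b + 100.0)
        assert 0 < s2 < s1 <= 1.0 + 1e-12


class TestPDFs:
    def test_truncgauss_negligible_truncation(self):
        params = {"Dm": 1e-3, "sigma": 1e-4}
        grid = np.linspace(0, 2.5e-3, 2001)
        pdf = M.evaluate_pdf("truncgauss", params, grid)
        untrunc = np.exp(-((grid - 1e-3) ** 2) / (2e-8)) / (1e-4 * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(pdf.density, untrunc, rtol=1e-6, atol=1e-3)
        from scipy.integrate import quad

        mass = quad(pdf.density_fn, 0, 3e-3)[0]
        assert mass == pytest.approx(1.0, abs=1e-6)

    def test_beta_symmetric_when_shapes_equal(self):
        params = {"alpha": 2.0, "beta": 2.0, "Dmax": 2e-3}
        x = np.linspace(1e-4, 1.9e-3, 101)
        pdf = M.evaluate_pdf("beta", params, x)
        np.testing.assert_allclose(pdf.density, pdf.density[::-1], rtol=1e-10)

    def test_gamma_mode(self):
        # mode of the gamma density is (k-1) theta
        params = {"k": 2.0, "theta": 0.5e-3}
        grid = np.linspace(1e-6, 5e-3, 20001)
        pdf = M.evaluate_pdf("gamma", params, grid)
        assert grid[np.argmax(pdf.density)] == pytest.approx(0.5e-3, rel=1e-3)

    def test_stretched_pdf_unsupported(self):
        with pytest.raises(M.UnsupportedModelOperation, match="no analytical form"):
            M.evaluate_pdf("stretched", {"Ds": 1e-3, "a": 0.8}, np.linspace(0, 1e-3, 10))

    def test_negative_grid_rejected_for_nonnegative_support(self):
        with pytest.raises(ValueError, match="below 0"):
            M.evaluate_pdf("gamma", {"k": 2.0, "theta": 5e-4}, np.linspace(-1e-3, 1e-3, 10))

    def test_beta_zero_outside_support(self):
        pdf = M.evaluate_pdf("beta", {"alpha": 2.0, "beta": 3.0, "Dmax": 1e-3}, np.array([1.5e-3, 2e-3]))
        assert np.all(pdf.density == 0)


class TestMoments:
    def test_biexp_reference_values(self):
        # 0.9/0.1 mixture of 1.5 and 0.5 um^2/ms: mean 1.4e-3, K = 27/196
        m = M.derived_moments("biexp", {"v": 0.9, "Dfast": 1.5e-3, "Dslow": 0.5e-3})
        assert m["mean_diffusivity"] == pytest.approx(1.4e-3, rel=1e-12)
        assert m["kurtosis"] == pytest.approx(3 * 0.09 * 1e-6 / 1.96e-6, rel=1e-12)
        assert m["kurtosis"] == pytest.approx(0.138, abs=5e-4)

    def test_gamma_kurtosis_and_skewness(self):
        m = M.derived_moments("gamma", {"k": 3.0, "theta": 4e-4})
        assert m["kurtosis"] == pytest.approx(1.0)
        assert m["skewness"] == pytest.approx(2 / np.sqrt(3.0))

    @pytest.mark.parametrize("model_id,params", CONTINUOUS_CASES)
    def test_moments_match_quadrature(self, model_id, params):
        from scipy.integrate import quad

        pdf = M.evaluate_pdf(model_id, params, np.linspace(0, 1e-3, 5))
        lo, hi = pdf.support
        m0 = quad(pdf.density_fn, lo, hi, epsabs=1e-12)[0]
        m1 = quad(lambda D: D * pdf.density_fn(D), lo, hi, epsabs=1e-14)[0]
        m2 = quad(lambda D: D**2 * pdf.density_fn(D), lo, hi, epsabs=1e-16)[0]
        mean_q = m1 / m0
        kurt_q = 3 * (m2 / m0 - mean_q**2) / mean_q**2
        m = M.derived_moments(model_id, params)
        assert m["mean_diffusivity"] == pytest.approx(mean_q, rel=1e-6)
        assert m["kurtosis"] == pytest.approx(kurt_q, rel=1e-6, abs=1e-9)
        if "skewness" in m:
            m3 = quad(lambda D: D**3 * pdf.density_fn(D), lo, hi, epsabs=1e-18)[0]
            var = m2 / m0 - mean_q**2
            skew_q = (m3 / m0 - 3 * mean_q * var - mean_q**3) / var**1.5
            assert m["skewness"] == pytest.approx(skew_q, rel=1e-6)

    def test_stretched_moments_unsupported(self):
        with pytest.raises(M.UnsupportedModelOperation, match="[Nn]either the mean"):
            M.derived_moments("stretched", {"Ds": 1e-3, "a": 0.8})


class TestNestedLimits:
    """Each non-Gaussian model collapses to the monoexponential in its limit."""

    B = np.linspace(0.0, 10000.0, 26)
    MONO = np.exp(-B * 1e-3)

    @pytest.mark.parametrize(
        "model_id,params",
        [
            ("dk", {"D": 1e-3, "K": 0.0}),
            ("biexp", {"v": 1.0, "Dfast": 1e-3, "Dslow": 0.1e-3}),
            ("biexp", {"v": 0.0, "Dfast": 2e-3, "Dslow": 1e-3}),
            ("stretched", {"Ds": 1e-3, "a": 1.0}),
            ("truncgauss", {"Dm": 1e-3, "sigma": 1e-9}),
        ],
    )
    def test_exact_limits(self, model_id, params):
        np.testing.assert_allclose(
            M.evaluate_signal(model_id, params, self.B), self.MONO, rtol=1e-6
        )

    def test_gamma_large_k_limit(self):
        k = 1e6
        s = M.evaluate_signal("gamma", {"k": k, "theta": 1e-3 / k}, self.B)
        np.testing.assert_allclose(s, self.MONO, rtol=1e-4)


class TestPropagator:
    TD = 9e-3 - 5e-3 / 3.0

    def test_monoexp_gaussian_widths(self):
        q = np.linspace(-400, 400, 4097)
        prop = M.displacement_profile("monoexp", {"D": 1e-3}, 5e-3, 9e-3, q)
        var = 2 * 1e-3 * self.TD
        assert prop.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2) * var), rel=0.01)
        assert prop.fwtm == pytest.approx(2 * np.sqrt(2 * np.log(10) * var), rel=0.01)
        np.testing.assert_allclose(
            np.trapezoid(prop.density, prop.displacements), 1.0, atol=1e-4
        )

    def test_biexp_has_heavier_tails_than_matched_monoexp(self):
        # Tail heaviness shows in the FWTM/FWHM ratio: the Gaussian ratio is
        # sqrt(ln 10 / ln 2) ~ 1.8226, and a two-compartment mixture exceeds
        # it.  (The absolute FWTM is not a reliable comparator because the
        # narrow slow compartment raises the mixture's peak height.)
        q = np.linspace(-400, 400, 4097)
        params = {"v": 0.9, "Dfast": 1.5e-3, "Dslow": 0.5e-3}
        mean_d = M.derived_moments("biexp", params)["mean_diffusivity"]
        bi = M.displacement_profile("biexp", params, 5e-3, 9e-3, q)
        mono = M.displacement_profile("monoexp", {"D": mean_d}, 5e-3, 9e-3, q)
        gauss_ratio = np.sqrt(np.log(10) / np.log(2))
        assert mono.fwtm / mono.fwhm == pytest.approx(gauss_ratio, rel=5e-3)
        assert bi.fwtm / bi.fwhm > gauss_ratio * 1.01
        assert bi.fwtm >= bi.fwhm > 0

    def test_symmetric_and_normalized(self):
        q = np.linspace(-400, 400, 2049)
        prop = M.displacement_profile("gamma", {"k": 5.0, "theta": 2e-4}, 5e-3, 9e-3, q)
        np.testing.assert_allclose(prop.density, prop.density[::-1], atol=1e-10)
        np.testing.assert_allclose(
            np.trapezoid(prop.density, prop.displacements), 1.0, atol=1e-4
        )

    def test_coarse_grid_rejected(self):
        q = np.linspace(-30, 30, 257)
        with pytest.raises(ValueError, match="too coarse"):
            M.displacement_profile("monoexp", {"D": 1e-3}, 5e-3, 9e-3, q)


class TestBValueArithmetic:
    def test_reference_value(self):
        # gamma 2.675e8 rad/s/T, delta 5 ms, Delta 9 ms, G = 1 T/m
        b = M.b_value_from_gradient(2.675e8, 5e-3, 1.0, 9e-3)
        assert b == pytest.approx((2.675e8 * 5e-3) ** 2 * (9e-3 - 5e-3 / 3) * 1e-6, rel=1e-12)
        assert b == pytest.approx(1.31e4, rel=2e-3)

    def test_zero_gradient_and_quadratic_scaling(self):
        assert M.b_value_from_gradient(2.675e8, 5e-3, 0.0, 9e-3) == 0.0
        b1 = M.b_value_from_gradient(2.675e8, 5e-3, 0.3, 9e-3)
        b2 = M.b_value_from_gradient(2.675e8, 5e-3, 0.6, 9e-3)
        assert b2 == pytest.approx(4 * b1, rel=1e-12)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            M.b_value_from_gradient(2.675e8, 9e-3, 1.0, 5e-3)


class TestAcquisitionScheme:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="unit norm"):
            M.AcquisitionScheme(
                b_values=np.array([0.0, 1000.0]),
                directions=np.array([[0, 0, 0], [1.0, 1.0, 0]]),
                delta=5e-3,
                Delta=9e-3,
            )
        with pytest.raises(ValueError, match="delta"):
            M.AcquisitionScheme(
                b_values=np.array([0.0]),
                directions=np.zeros((1, 3)),
                delta=9e-3,
                Delta=5e-3,
            )

    def test_gradient_consistency_check(self):
        g_amp = np.array([0.0, 0.5])
        b = M.b_value_from_gradient(2.675e8, 5e-3, g_amp, 9e-3)
        M.AcquisitionScheme(
            b_values=b,
            directions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            delta=5e-3,
            Delta=9e-3,
            G=g_amp,
        )
        with pytest.raises(ValueError, match="inconsistent"):
            M.AcquisitionScheme(
                b_values=b * 1.5,
                directions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
                delta=5e-3,
                Delta=9e-3,
                G=g_amp,
            )
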