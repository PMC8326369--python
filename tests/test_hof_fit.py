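import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import poisson

from ecohof import hof_fit as hf

PH_RANGE = (3.63, 8.75)


def g(t):
    """Independent logistic kernel for oracle computations."""
    return 1.0 / (1.0 + math.exp(t))


class TestScaleGradient:
    def test_endpoints_of_survey_range(self):
        assert hf.scale_gradient(3.63, *PH_RANGE) == 0.0
        assert hf.scale_gradient(8.75, *PH_RANGE) == 1.0

    def test_midpoint(self):
        assert hf.scale_gradient(6.19, *PH_RANGE) == pytest.approx(0.5)

    def test_affine_extension_outside_range(self):
        assert hf.scale_gradient(2.0, 3.0, 5.0) == pytest.approx(-0.5)
        assert hf.unscale_gradient(-0.5, 3.0, 5.0) == pytest.approx(2.0)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            hf.scale_gradient(5.0, 7.0, 7.0)


class TestHofResponse:
    def test_flat_model_is_half_max_at_a_zero(self):
        assert hf.hof_response(0.3, "I", (0.0,), 10.0) == pytest.approx(5.0)
        assert hf.hof_response(0.9, "I", (0.0,), 10.0) == pytest.approx(5.0)

    def test_type_ii_with_zero_slope_equals_type_i(self):
        x = np.linspace(0, 1, 7)
        np.testing.assert_allclose(
            hf.hof_response(x, "II", (1.3, 0.0), 50.0),
            hf.hof_response(x, "I", (1.3,), 50.0),
        )

    def test_type_iv_matches_logistic_product_oracle(self):
        a, b, c, M, x = -2.0, 4.0, 2.0, 1.0, 0.5
        expected = M * g(a + b * x) * g(c - b * x)
        assert hf.hof_response(x, "IV", (a, b, c), M) == pytest.approx(expected)

    def test_type_v_matches_logistic_product_oracle(self):
        a, b, c, d, M, x = -1.0, 8.0, 3.0, -5.0, 7.0, 0.25
        expected = M * g(a + b * x) * g(c + d * x)
        assert hf.hof_response(x, "V", (a, b, c, d), M) == pytest.approx(expected)

    @given(
        st.sampled_from(hf.MODEL_TYPES),
        st.floats(-50, 50),
        st.floats(0, 200),
        st.floats(-50, 50),
        st.floats(-200, 200),
        st.floats(0, 1),
    )
    def test_response_bounded_by_scaling_constant(self, mt, a, b, c, d, x):
        params = (a, b, c, d)[: hf.N_FREE_PARAMS[mt]]
        mu = hf.hof_response(x, mt, params, 100.0)
        assert 0.0 <= mu <= 100.0

    def test_non_finite_params_rejected(self):
        with pytest.raises(ValueError):
            hf.hof_response(0.5, "II", (np.nan, 1.0), 10.0)


class TestPoissonNLL:
    def test_known_values(self):
        assert hf.poisson_nll([1], [1]) == pytest.approx(1.0)
        assert hf.poisson_nll([0], [2]) == pytest.approx(2.0)

    def test_matches_scipy_logpmf(self):
        y = np.array([2, 0, 5, 1])
        mu = np.array([2.0, 0.5, 4.0, 1.5])
        expected = -poisson.logpmf(y, mu).sum()
        assert hf.poisson_nll(y, mu) == pytest.approx(expected, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hf.poisson_nll([-1], [1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hf.poisson_nll([1, 2], [1.0])


@pytest.fixture(scope="module")
def iv_dataset():
    """Poisson counts from a symmetric unimodal response over the survey range."""
    rng = np.random.default_rng(10)
    ph = rng.uniform(*PH_RANGE, 400)
    x = hf.scale_gradient(ph, *PH_RANGE)
    mu = hf.hof_response(x, "IV", (-2.0, 12.0, 4.0), 80.0)
    return rng.poisson(mu), ph


class TestFitSingleModel:
    def test_flat_fit_recovers_constant_poisson_mean(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(*PH_RANGE, 500)
        y = rng.poisson(10.0, size=500)  # type I with M*g(a) = 10
        fit = hf.fit_single_model(y, ph, "I", gradient_range=PH_RANGE)
        mu_hat = hf.response_at(fit, 6.0)
        assert mu_hat == pytest.approx(10.0, rel=0.05)
        # the ML constant mean is exactly the sample mean
        assert mu_hat == pytest.approx(y.mean(), rel=1e-6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hf.fit_single_model(np.zeros(10), np.linspace(4, 8, 10), "II")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            hf.fit_single_model([1, 2], [4.0, 5.0], "III")

    def test_aic_identity(self, iv_dataset):
        y, ph = iv_dataset
        fit = hf.fit_single_model(y, ph, "IV", gradient_range=PH_RANGE)
        assert fit.AIC == pytest.approx(2 * fit.k - 2 * fit.logLik, abs=1e-9)
        assert fit.k == 3


class TestNesting:
    def test_loglik_non_decreasing_along_hierarchy(self, iv_dataset):
        y, ph = iv_dataset
        fits = hf.fit_all_models(y, ph, gradient_range=PH_RANGE)
        tol = 1e-6
        assert fits["II"].logLik >= fits["I"].logLik - tol
        assert fits["III"].logLik >= fits["II"].logLik - tol
        assert fits["IV"].logLik >= fits["II"].logLik - tol
        assert fits["V"].logLik >= fits["III"].logLik - tol
        assert fits["V"].logLik >= fits["IV"].logLik - tol


class TestSelectModel:
    def _dummy(self, mt, aic):
        return hf.HOFFit(
            otu_id="x", model_type=mt, params=(0.0,) * hf.N_FREE_PARAMS[mt],
            M=1.0, logLik=0.0, k=hf.N_FREE_PARAMS[mt], AIC=aic,
        )

    def test_argmin_aic(self):
        assert hf.select_model([self._dummy("II", 100.0), self._dummy("V", 98.0)]) == "V"

    def test_single_candidate(self):
        assert hf.select_model([self._dummy("III", 5.0)]) == "III"

    def test_tie_goes_to_fewer_parameters(self):
        assert hf.select_model([self._dummy("III", 100.0), self._dummy("V", 100.0)]) == "III"

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            hf.select_model([])


class TestBootstrapRule:
    def test_mode_overrides_initial_choice(self):
        assert hf.resolve_bootstrap_choice("V", {"IV": 60, "V": 40}) == "IV"

    def test_initial_kept_when_it_is_the_mode(self):
        assert hf.resolve_bootstrap_choice("II", {"II": 90, "III": 10}) == "II"

    def test_tally_tie_goes_to_fewer_parameters(self):
        assert hf.resolve_bootstrap_choice("V", {"IV": 50, "V": 50}) == "IV"

    def test_empty_tally_keeps_initial(self):
        assert hf.resolve_bootstrap_choice("III", {}) == "III"


class TestBootstrapSelect:
    def test_deterministic_under_seed(self, iv_dataset):
        y, ph = iv_dataset
        f1 = hf.bootstrap_select(y, ph, n_boot=20, seed=3, gradient_range=PH_RANGE)
        f2 = hf.bootstrap_select(y, ph, n_boot=20, seed=3, gradient_range=PH_RANGE)
        assert f1.model_type == f2.model_type
        assert f1.params == f2.params
        assert f1.bootstrap_tally == f2.bootstrap_tally

    def test_tally_plus_failures_accounts_for_all_resamples(self, iv_dataset):
        y, ph = iv_dataset
        fit = hf.bootstrap_select(y, ph, n_boot=20, seed=3, gradient_range=PH_RANGE)
        assert sum(fit.bootstrap_tally.values()) + fit.n_boot_failed == 20
        assert fit.initial_choice in hf.MODEL_TYPES


class TestOptima:
    def test_type_iv_closed_form(self):
        # d(log mu)/dx = 0 at x = (c - a) / (2b)
        fit = hf.HOFFit(
            otu_id="x", model_type="IV", params=(-2.0, 4.0, 2.0), M=1.0,
            logLik=0.0, k=3, AIC=0.0, gradient_range=PH_RANGE,
        )
        (opt,) = hf.extract_optima(fit)
        assert opt == pytest.approx(hf.unscale_gradient(0.5, *PH_RANGE), abs=1e-3)
        assert opt == pytest.approx(6.19, abs=1e-2)

    def test_type_iv_symmetry_when_c_equals_a_plus_b(self):
        a, b = -3.0, 10.0
        fit = hf.HOFFit(
            otu_id="x", model_type="IV", params=(a, b, a + b), M=1.0,
            logLik=0.0, k=3, AIC=0.0, gradient_range=PH_RANGE,
        )
        (opt,) = hf.extract_optima(fit)
        assert hf.scale_gradient(opt, *PH_RANGE) == pytest.approx(0.5, abs=2e-3)

    def test_grid_agrees_with_closed_form_across_random_params(self):
        rng = np.random.default_rng(42)
        n = 0
        while n < 200:
            b = rng.uniform(4, 60)
            a = rng.uniform(-10, 5)
            c = a + 2 * b * rng.uniform(0.05, 0.95)  # interior optimum
            if c > 50:  # stay inside the valid fitting box
                continue
            n += 1
            got = hf.model_optima("IV", (a, b, c), 1.0, (0.0, 1.0))
            assert abs(got[0] - (c - a) / (2 * b)) <= 2e-3

    def test_flat_model_has_no_optimum(self):
        fit = hf.HOFFit(
            otu_id="x", model_type="I", params=(0.0,), M=1.0, logLik=0.0, k=1,
            AIC=0.0, gradient_range=PH_RANGE,
        )
        assert hf.extract_optima(fit) == ()

    def test_monotone_model_optimum_at_favored_endpoint(self):
        # b > 0 makes the response decreasing in x; on the reversed gradient
        # the same parameters describe a response increasing toward high pH
        fit = hf.HOFFit(
            otu_id="x", model_type="II", params=(0.0, 10.0), M=1.0,
            logLik=0.0, k=2, AIC=0.0, gradient_range=PH_RANGE,
        )
        assert hf.extract_optima(fit) == (3.63,)
        rev = hf.HOFFit(
            otu_id="x", model_type="II", params=(0.0, 10.0), M=1.0,
            logLik=0.0, k=2, AIC=0.0, reversed_gradient=True, gradient_range=PH_RANGE,
        )
        assert hf.extract_optima(rev) == (8.75,)

    def test_plateau_optima_span_the_plateau(self):
        # saturated rise then fall: plateau on the low-x side
        fit = hf.HOFFit(
            otu_id="x", model_type="III", params=(-10.0, 20.0, 0.0), M=1.0,
            logLik=0.0, k=3, AIC=0.0, gradient_range=PH_RANGE,
        )
        lo, hi = hf.extract_optima(fit)
        assert lo < hi
        # responses at the reported edges are >= 95% of the maximum
        for p in (lo, hi):
            assert hf.response_at(fit, p) >= 0.95 * hf.response_at(fit, 3.63) - 1e-9

    def test_optima_inside_gradient_range(self, iv_dataset):
        y, ph = iv_dataset
        fit = hf.bootstrap_select(y, ph, n_boot=10, seed=0, gradient_range=PH_RANGE)
        for o in fit.optima_pH:
            assert PH_RANGE[0] <= o <= PH_RANGE[1]
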