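"""Closed forms, Jacobians and asymptotes of the five kinetic families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaskinetics import MODEL_IDS, asymptote, evaluate, get_model, jacobian
from gaskinetics.models import validate_params

from conftest import EXAMPLE_PARAMS


class TestEvaluate:
    @pytest.mark.parametrize(
        "model_id, params, t, expected",
        [
            # A·exp(−B) at t = 0 for the Gompertz family
            ("gompertz", (5.03, 3.89, 0.19), 0.0, 5.03 * np.exp(-3.89)),
            # the Ørskov–McDonald intercept is A itself
            ("orskov_mcdonald", (-0.50, 7.48, 0.06), 0.0, -0.50),
            # Brody with B = 1 starts exactly at zero
            ("brody", (6.98, 1.0, 0.06), 0.0, 0.0),
        ],
    )
    def test_closed_form_points(self, model_id, params, t, expected):
        got = evaluate(model_id, params, [t])[0]
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_richards_approaches_asymptote(self):
        p = EXAMPLE_PARAMS["richards"]
        assert evaluate("richards", p, [1e4])[0] == pytest.approx(p[0], rel=1e-10)

    def test_dual_pool_closed_form(self):
        a, b, c, d, e = EXAMPLE_PARAMS["dual_pool_logistic"]
        t = np.array([0.0, 4.0, 12.0])
        want = a / (1 + np.exp(2 - 4 * b * (t - c))) + d / (
            1 + np.exp(2 - 4 * e * (t - c))
        )
        np.testing.assert_allclose(
            evaluate("dual_pool_logistic", (a, b, c, d, e), t), want, rtol=1e-12
        )

    def test_lag_clamp_for_b_above_one(self):
        # B > 1 implies zero gas until t = ln(B)/C, then a real positive curve
        a, b, c, d = 4.87, 1.09, 0.10, 2.05
        t_lag = np.log(b) / c
        t = np.array([0.0, t_lag / 2, t_lag + 0.5, 24.0])
        p = evaluate("richards", (a, b, c, d), t)
        assert p[0] == 0.0 and p[1] == 0.0
        assert p[2] > 0 and p[3] > p[2]

    def test_overflow_guarded(self):
        # extreme rate: exponent argument far beyond float range, no NaN/inf
        p = evaluate("gompertz", (5.0, 2.0, 500.0), np.array([0.0, 10.0, 1e6]))
        assert np.all(np.isfinite(p))
        assert p[-1] == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "model_id, bad",
        [
            ("gompertz", (5.0, 2.0, -0.1)),  # rate must be positive
            ("richards", (5.0, 1.0, 0.1, -1.0)),  # exponent must be positive
            ("brody", (-5.0, 1.0, 0.1)),  # asymptote must be positive
            ("dual_pool_logistic", (1.0, -0.2, 3.5, 3.7, 0.07)),
        ],
    )
    def test_domain_errors(self, model_id, bad):
        with pytest.raises(ValueError):
            evaluate(model_id, bad, [0.0, 1.0])

    def test_orskov_negative_intercept_is_valid(self):
        validate_params("orskov_mcdonald", (-0.50, 7.48, 0.06))

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            evaluate("brody", (5.0, 1.0, 0.1), [0.0, 2.0, 1.0])


class TestJacobian:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_matches_central_differences(self, model_id):
        theta = np.asarray(EXAMPLE_PARAMS[model_id], dtype=float)
        t = np.linspace(0.5, 23.5, 31)
        jac = jacobian(model_id, theta, t)
        for j in range(theta.size):
            h = 1e-6 * max(abs(theta[j]), 1.0)
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            fd = (evaluate(model_id, up, t) - evaluate(model_id, dn, t)) / (2 * h)
            # atol floor absorbs central-difference truncation error on
            # near-zero sensitivities
            np.testing.assert_allclose(jac[:, j], fd, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("model_id", ["gompertz", "brody", "richards"])
    def test_linear_in_asymptote(self, model_id):
        theta = np.asarray(EXAMPLE_PARAMS[model_id], dtype=float)
        t = np.linspace(0.5, 24.0, 20)
        jac = jacobian(model_id, theta, t)
        np.testing.assert_allclose(
            jac[:, 0], evaluate(model_id, theta, t) / theta[0], rtol=1e-10
        )

    def test_dual_pool_fiber_volume_sensitivity_saturates(self):
        # far past the lag both pools are fully open: dP/dD -> 1
        theta = EXAMPLE_PARAMS["dual_pool_logistic"]
        jac = jacobian("dual_pool_logistic", theta, [500.0])
        assert jac[0, 3] == pytest.approx(1.0, abs=1e-6)


class TestAsymptote:
    @pytest.mark.parametrize(
        "model_id, expected",
        [
            ("richards", 5.36),
            ("gompertz", 5.03),
            ("brody", 6.98),
            ("orskov_mcdonald", -0.50 + 7.48),
            ("dual_pool_logistic", 1.20 + 3.76),
        ],
    )
    def test_total_potential_gas(self, model_id, expected):
        assert asymptote(model_id, EXAMPLE_PARAMS[model_id]) == pytest.approx(expected)

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_curve_converges_to_asymptote(self, model_id):
        theta = EXAMPLE_PARAMS[model_id]
        assert evaluate(model_id, theta, [1e5])[0] == pytest.approx(
            asymptote(model_id, theta), rel=1e-8
        )


class TestStructuralIdentities:
    def test_richards_with_unit_exponent_is_brody(self):
        t = np.linspace(0.0, 24.0, 289)
        a, b, c = 6.98, 0.9, 0.06
        np.testing.assert_array_equal(
            evaluate("richards", (a, b, c, 1.0), t), evaluate("brody", (a, b, c), t)
        )

    def test_dual_pool_with_empty_fiber_pool_is_single_logistic(self):
        t = np.linspace(0.0, 24.0, 50)
        a, b, c = 4.0, 0.2, 3.0
        got = evaluate("dual_pool_logistic", (a, b, c, 0.0, 0.05), t)
        single = a / (1 + np.exp(2 - 4 * b * (t - c)))
        np.testing.assert_allclose(got, single, rtol=1e-12, atol=1e-12)

    def test_dual_pool_with_equal_rates_is_logistic_with_summed_asymptote(self):
        t = np.linspace(0.0, 24.0, 50)
        a, d, b, c = 1.5, 3.0, 0.15, 3.0
        got = evaluate("dual_pool_logistic", (a, b, c, d, b), t)
        single = (a + d) / (1 + np.exp(2 - 4 * b * (t - c)))
        np.testing.assert_allclose(got, single, rtol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    model_id=st.sampled_from(sorted(MODEL_IDS)),
    data=st.data(),
)
def test_curves_are_nondecreasing_and_finite(model_id, data):
    """On the valid monotone domain every family is a non-decreasing,
    finite, continuous gas accumulation curve."""
    pos = st.floats(0.01, 10.0)
    if model_id == "gompertz":
        theta = (data.draw(pos), data.draw(pos), data.draw(st.floats(0.01, 2.0)))
    elif model_id == "orskov_mcdonald":
        theta = (
            data.draw(st.floats(-1.0, 10.0)),
            data.draw(pos),
            data.draw(st.floats(0.01, 2.0)),
        )
    elif model_id == "brody":
        theta = (data.draw(pos), data.draw(st.floats(0.01, 1.0)), data.draw(st.floats(0.01, 2.0)))
    elif model_id == "richards":
        theta = (
            data.draw(pos),
            data.draw(st.floats(0.01, 1.0)),
            data.draw(st.floats(0.01, 2.0)),
            data.draw(st.floats(0.1, 5.0)),
        )
    else:
        theta = (
            data.draw(pos),
            data.draw(st.floats(0.01, 2.0)),
            data.draw(st.floats(0.01, 10.0)),
            data.draw(pos),
            data.draw(st.floats(0.01, 2.0)),
        )
    t = np.linspace(0.0, 48.0, 400)
    p = evaluate(model_id, theta, t)
    assert np.all(np.isfinite(p))
    assert np.all(np.diff(p) >= -1e-10)
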