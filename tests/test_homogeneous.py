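"""Steady homogeneous-flow solutions: algebraic systems, oracle, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vwfflow.core import (
    ConfTensor2D,
    VWFParams,
    relaxation_time,
    rotation_gradient,
    shear_gradient,
    vwf_length,
)
from vwfflow.homogeneous import (
    SolverError,
    elongation_residual,
    half_unfolding_threshold,
    shear_residual,
    steady_general,
    steady_pure_elongation,
    steady_pure_shear,
    unfolding_curve,
)

HALF = 22.6 / (2 * np.sqrt(2))  # half of the saturated normalised length


class TestSteadyShear:
    def test_zero_rate_is_identity(self, table1_params):
        A = steady_pure_shear(0.0, table1_params)
        assert (A.a_11, A.a_12, A.a_22) == (1.0, 0.0, 1.0)

    @pytest.mark.parametrize("gd", [10.0, 1e3, 5096.0, 2e4, 1e6])
    def test_residuals_vanish(self, gd, table1_params):
        A = steady_pure_shear(gd, table1_params)
        res, scale = shear_residual(A, gd, table1_params, with_scale=True)
        assert np.all(np.abs(res) <= 1e-10 * scale)
        assert A.is_spd()
        assert A.trace < table1_params.L_max**2

    def test_half_unfolded_near_published_rate(self, table1_params):
        # the fitted model reports 50% of maximum length at 5096 1/s
        A = steady_pure_shear(5096.0, table1_params)
        assert vwf_length(A) == pytest.approx(HALF, rel=0.02)

    def test_oldroyd_b_closed_form(self):
        # L -> infinity (f = a = 1): A_yy = 1, A_xy = s, A_xx = 1 + 2 s^2
        p = VWFParams(L_max=1e8)
        gd = 2000.0
        s = gd * relaxation_time(gd, p)
        A = steady_pure_shear(gd, p)
        assert A.a_22 == pytest.approx(1.0, rel=1e-6)
        assert A.a_12 == pytest.approx(s, rel=1e-6)
        assert A.a_11 == pytest.approx(1.0 + 2 * s**2, rel=1e-6)

    def test_streamwise_contraction_at_large_rate(self, table1_params):
        # A_yy decreases toward zero as the rate grows (finite length)
        rates = [5e3, 1e4, 5e4, 1e5]
        ayy = [steady_pure_shear(g, table1_params).a_22 for g in rates]
        assert all(b < a for a, b in zip(ayy, ayy[1:]))
        assert ayy[-1] < 0.05

    def test_negative_rate_rejected(self, table1_params):
        with pytest.raises(ValueError):
            steady_pure_shear(-1.0, table1_params)


class TestSteadyElongation:
    def test_zero_rate_is_identity(self, table1_params):
        A = steady_pure_elongation(0.0, table1_params)
        assert (A.a_11, A.a_12, A.a_22) == (1.0, 0.0, 1.0)

    @pytest.mark.parametrize("gd", [10.0, 500.0, 1947.0, 1e4, 1e6])
    def test_residuals_vanish_and_diagonal(self, gd, table1_params):
        A = steady_pure_elongation(gd, table1_params)
        assert A.a_12 == 0.0
        res, scale = elongation_residual(A, gd, table1_params, with_scale=True)
        assert np.all(np.abs(res) <= 1e-10 * scale)
        assert A.trace < table1_params.L_max**2

    def test_half_unfolded_near_published_rate(self, table1_params):
        A = steady_pure_elongation(1947.0, table1_params)
        assert vwf_length(A) == pytest.approx(HALF, rel=0.02)

    def test_oldroyd_b_closed_form_subcritical(self):
        # f = a = 1 and 2 s < 1: principal components 1/(1 -+ 2s)
        p = VWFParams(L_max=1e8)
        gd = 3.0
        s = gd * relaxation_time(gd, p)
        assert 2 * s < 1
        A = steady_pure_elongation(gd, p)
        assert A.a_11 == pytest.approx(1.0 / (1.0 - 2 * s), rel=1e-8)
        assert A.a_22 == pytest.approx(1.0 / (1.0 + 2 * s), rel=1e-8)


class TestTimeMarchOracle:
    def test_rotation_stays_at_identity(self, table1_params):
        A = steady_general(rotation_gradient(500.0), table1_params)
        assert A.as_matrix() == pytest.approx(np.eye(2), abs=1e-8)

    def test_zero_gradient_identity(self, table1_params):
        from vwfflow.core import FlowGradient2D

        A = steady_general(FlowGradient2D(0, 0, 0, 0), table1_params)
        assert A.as_matrix() == pytest.approx(np.eye(2), abs=1e-12)

    @pytest.mark.parametrize("gd", [100.0, 5e3, 3e4])
    def test_matches_algebraic_shear_solution(self, gd, table1_params):
        A_ode = steady_general(shear_gradient(gd), table1_params)
        A_alg = steady_pure_shear(gd, table1_params)
        scale = max(1.0, abs(A_alg.a_11))
        assert abs(A_ode.a_11 - A_alg.a_11) <= 1e-6 * scale
        assert abs(A_ode.a_12 - A_alg.a_12) <= 1e-6 * scale
        assert abs(A_ode.a_22 - A_alg.a_22) <= 1e-6 * scale

    def test_timeout_reports_last_state(self, table1_params):
        with pytest.raises(SolverError) as err:
            steady_general(shear_gradient(1e4), table1_params, t_max=1e-9, tol=1e-14)
        assert err.value.last_state is not None


class TestUnfoldingCurve:
    def test_low_rate_is_globular(self, table1_params):
        c = unfolding_curve("shear", [10.0], table1_params)
        assert c.length_values[0] == pytest.approx(1.0, abs=1e-3)

    def test_monotone_and_saturating(self, table1_params):
        grid = np.logspace(1, 6, 40)
        c = unfolding_curve("shear", grid, table1_params)
        assert np.all(np.diff(c.length_values) >= -1e-12)
        assert np.all((c.normalized_extension >= 0) & (c.normalized_extension <= 1))
        assert c.normalized_extension[-1] > 0.99

    def test_elongation_unfolds_before_shear(self, table1_params):
        grid = np.linspace(500.0, 5000.0, 12)
        sh = unfolding_curve("shear", grid, table1_params)
        el = unfolding_curve("elongation", grid, table1_params)
        assert np.all(el.extension_values >= sh.extension_values)

    def test_even_in_shear_sign(self, table1_params):
        from vwfflow.homogeneous import shear_components_from_weissenberg

        s = 1.7
        Ap = shear_components_from_weissenberg(s, 22.6)
        Am = shear_components_from_weissenberg(-s, 22.6)
        assert Ap.trace == pytest.approx(Am.trace, rel=1e-12)
        assert Ap.a_12 == pytest.approx(-Am.a_12, rel=1e-12)

    def test_bad_flow_type(self, table1_params):
        with pytest.raises(ValueError):
            unfolding_curve("squeeze", [1.0, 2.0], table1_params)


class TestHalfUnfoldingThreshold:
    def test_shear_threshold_near_published(self, table1_params):
        th = half_unfolding_threshold("shear", table1_params)
        assert th == pytest.approx(5096.0, rel=0.02)
        # frozen value of this implementation, for regression
        assert th == pytest.approx(5117.4, rel=1e-3)

    def test_elongation_threshold_near_published(self, table1_params):
        th = half_unfolding_threshold("elongation", table1_params)
        assert th == pytest.approx(1947.0, rel=0.02)

    def test_rotation_has_no_threshold(self, table1_params):
        with pytest.raises(ValueError, match="rotation"):
            half_unfolding_threshold("rotation", table1_params)

    def test_bad_bracket_reported(self, table1_params):
        with pytest.raises(SolverError, match="bracket"):
            half_unfolding_threshold("shear", table1_params, bracket=(1.0, 10.0))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.02, 0.2),
        beta=st.floats(1e-4, 8e-4),
        delta=st.floats(3e-4, 5e-3),
        gamma_star=st.floats(4e3, 2.5e4),
        L=st.floats(4.0, 30.0),
    )
    def test_elongation_below_shear_for_random_params(
        self, alpha, beta, delta, gamma_star, L
    ):
        # rotation relieves stretching in shear flow, so elongational flow
        # always unfolds at a lower rate, whatever the parameters
        p = VWFParams(alpha, beta, delta, gamma_star, L)
        bracket = (1e-1, 1e8)
        th_e = half_unfolding_threshold("elongation", p, bracket)
        th_s = half_unfolding_threshold("shear", p, bracket)
        assert th_e < th_s
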