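"""Constitutive building blocks: relaxation law, FENE factors, rates, scales."""

import numpy as np
import pytest

from vwfflow.core import (
    ConfTensor2D,
    FlowGradient2D,
    VWFParams,
    elongation_gradient,
    fene_factor,
    natural_constant,
    nondimensionalize,
    redimensionalize,
    relaxation_time,
    rotation_gradient,
    scalar_rates,
    shear_gradient,
    vwf_extension,
    vwf_length,
)


class TestRelaxationTime:
    def test_limits_and_centre(self, table1_params):
        p = table1_params
        # saturation plateau alpha*(1+delta); published values give ~0.069067 s
        assert relaxation_time(1e9, p) == pytest.approx(p.alpha * (1 + p.delta), rel=1e-9)
        assert relaxation_time(1e9, p) == pytest.approx(0.069067, rel=1e-4)
        # tanh vanishes at its centre gamma*
        assert relaxation_time(p.gamma_star, p) == pytest.approx(
            p.alpha * (0.5 + p.delta), rel=1e-12
        )
        # zero-shear floor, evaluated independently beforehand
        assert relaxation_time(0.0, p) == pytest.approx(1.37799e-4, rel=1e-4)

    def test_bounded_and_strictly_increasing(self, table1_params):
        g = np.logspace(-1, 7, 200)
        tau = relaxation_time(g, table1_params)
        lo = table1_params.alpha * table1_params.delta
        hi = table1_params.alpha * (1 + table1_params.delta)
        assert np.all(tau > lo) and np.all(tau <= hi)
        assert np.all(np.diff(tau) >= 0)
        # strictly increasing wherever tanh has not saturated in floats
        g = np.logspace(-1, 4.7, 150)
        assert np.all(np.diff(relaxation_time(g, table1_params)) > 0)

    def test_negative_rate_rejected(self, table1_params):
        with pytest.raises(ValueError):
            relaxation_time(-1.0, table1_params)


class TestFene:
    def test_identity_equals_natural_constant(self):
        # f(I) = a exactly makes A = I the flow-free equilibrium
        a = natural_constant(22.6)
        assert fene_factor(ConfTensor2D.identity(), 22.6) == a
        assert a == pytest.approx(510.76 / 508.76, rel=1e-12)

    def test_pole_guarded(self):
        A = ConfTensor2D(300.0, 0.0, 300.0)
        with pytest.raises(ValueError, match="extensibility"):
            fene_factor(A, 22.6)

    def test_infinite_extensibility_limit(self):
        assert fene_factor(ConfTensor2D.identity(), 1e9) == pytest.approx(1.0, abs=1e-12)
        assert natural_constant(1e9) == pytest.approx(1.0, abs=1e-12)

    def test_small_L_rejected(self):
        with pytest.raises(ValueError):
            natural_constant(1.0)


class TestLengthExtension:
    def test_natural_length(self):
        assert vwf_length(ConfTensor2D.identity()) == 1.0
        assert vwf_extension(ConfTensor2D.identity()) == 0.0

    def test_scaling(self):
        assert vwf_length(ConfTensor2D(4.0, 0.0, 4.0)) == pytest.approx(2.0)

    def test_saturation_value(self):
        # at the FENE bound the length is L/sqrt(2): ~15.98 for L=22.6,
        # i.e. the maximum extension ~14.98 that the model rounds to "15"
        L = 22.6
        assert np.sqrt(L**2 / 2.0) == pytest.approx(15.98, abs=0.01)
        assert vwf_length(np.array(L**2)) == pytest.approx(L / np.sqrt(2))

    def test_rotation_invariance(self, rng):
        A = ConfTensor2D(3.0, 0.7, 1.2)
        for theta in rng.uniform(0, 2 * np.pi, 10):
            Q = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            Arot = ConfTensor2D.from_matrix(Q @ A.as_matrix() @ Q.T)
            assert vwf_length(Arot) == pytest.approx(vwf_length(A), rel=1e-12)

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            vwf_length(ConfTensor2D(1.0, 2.0, 1.0))


class TestScalarRates:
    @pytest.mark.parametrize(
        "grad,expected",
        [
            (shear_gradient(3.0), (3.0, 3.0)),
            (elongation_gradient(3.0), (3.0, 0.0)),
            (rotation_gradient(1.5), (0.0, 3.0)),
        ],
    )
    def test_canonical_flows(self, grad, expected):
        got = scalar_rates(grad)
        assert got == pytest.approx(expected, abs=1e-14)

    def test_random_gradient_decomposition(self, rng):
        # brute-force check against the D + W split for arbitrary gradients
        for _ in range(25):
            m = rng.standard_normal((2, 2))
            D = 0.5 * (m + m.T)
            W = 0.5 * (m - m.T)
            gd, od = scalar_rates(FlowGradient2D(m[0, 0], m[0, 1], m[1, 0], m[1, 1]))
            assert gd == pytest.approx(np.sqrt(2 * np.sum(D * D)))
            assert od == pytest.approx(np.sqrt(2 * np.sum(W * W)))
            assert gd >= 0 and od >= 0


class TestNondimensionalisation:
    def test_round_trip_identity(self, table1_params):
        groups = nondimensionalize(table1_params, d=1.95e-3, U=0.5)
        back = redimensionalize(groups)
        for name in ("alpha", "beta", "delta", "gamma_star", "L_max"):
            assert getattr(back, name) == pytest.approx(
                getattr(table1_params, name), rel=1e-14
            )

    def test_reynolds_definition(self, table1_params):
        groups = nondimensionalize(table1_params, d=2e-3, U=0.4, rho=1050.0, mu=0.0025)
        assert groups.Re == pytest.approx(1050.0 * 0.4 * 2e-3 / 0.0025, rel=1e-12)
        assert groups.deborah == pytest.approx(groups.xi * groups.Re, rel=1e-15)

    def test_implied_radius_from_deborah_parameter(self, table1_params):
        # xi = alpha*mu/(d^2 rho) = 0.043 implies d ~ 1.95 mm for blood
        d = np.sqrt(table1_params.alpha * 0.0025 / (0.043 * 1050.0))
        assert d == pytest.approx(1.9547e-3, rel=1e-3)
        groups = nondimensionalize(table1_params, d=d, U=0.5)
        assert groups.xi == pytest.approx(0.043, rel=1e-12)
        assert groups.delta == table1_params.delta
        assert groups.L_max == table1_params.L_max

    def test_tau_hat_matches_dimensional_law(self, table1_params):
        groups = nondimensionalize(table1_params, d=1.9547e-3, U=0.5)
        for gd_hat in (0.1, 1.0, 30.0, 80.0):
            gd = gd_hat * groups.U / groups.d
            assert table1_params.alpha * groups.tau_hat(gd_hat) == pytest.approx(
                relaxation_time(gd, table1_params), rel=1e-12
            )

    def test_bad_scales_rejected(self, table1_params):
        with pytest.raises(ValueError):
            nondimensionalize(table1_params, d=-1.0, U=0.5)
        with pytest.raises(ValueError):
            nondimensionalize(table1_params, d=1e-3, U=0.0)


class TestParamValidation:
    def test_positive_parameters_required(self):
        with pytest.raises(ValueError):
            VWFParams(alpha=-0.1)
        with pytest.raises(ValueError):
            VWFParams(L_max=1.2)
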