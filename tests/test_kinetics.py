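"""Closed-form kinetics: rate law, sigmoid, Einstein map, Laplace/Kelvin."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gelkin.errors import DegenerateInputError, DomainError, NoEquilibriumError
from gelkin.kinetics import (
    BOLTZMANN,
    EinsteinMap,
    FluidProperties,
    LogisticParams,
    equilibrium_fraction,
    first_order_solution,
    fraction_from_viscosity,
    inflection_time,
    kelvin_concentration,
    laplace_pressure,
    logistic_rate,
    logistic_solution,
    viscosity_from_fraction,
)

from conftest import random_logistic_params


def rk4_logistic(p: LogisticParams, t_end: float, dt: float = 0.1) -> float:
    """Independent oracle: classic 4th-order Runge-Kutta on dB/dt = k1 B - k- B^2."""
    f = lambda b: p.k1 * b - p.k_minus * b * b
    b = p.B0
    n = max(int(np.ceil(t_end / dt)), 1)
    dt = t_end / n  # land exactly on t_end
    for _ in range(n):
        s1 = f(b)
        s2 = f(b + 0.5 * dt * s1)
        s3 = f(b + 0.5 * dt * s2)
        s4 = f(b + dt * s3)
        b += dt * (s1 + 2 * s2 + 2 * s3 + s4) / 6.0
    return b


class TestLogisticRate:
    def test_fixed_points_and_midpoint(self, undersat_params):
        p = undersat_params
        assert logistic_rate(0.0, p) == 0.0
        assert logistic_rate(p.B_inf, p) == pytest.approx(0.0, abs=1e-18)
        assert logistic_rate(p.B_inf / 2, p) == pytest.approx(
            p.k1 * p.B_inf / 4, rel=1e-12
        )

    def test_sign_tracks_saturation(self, undersat_params):
        p = undersat_params
        assert logistic_rate(0.5 * p.B_inf, p) > 0
        assert logistic_rate(2.0 * p.B_inf, p) < 0

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_domain_error(self, bad, undersat_params):
        with pytest.raises(DomainError):
            logistic_rate(bad, undersat_params)


class TestLogisticSolution:
    def test_initial_condition(self, undersat_params):
        assert logistic_solution(0.0, undersat_params) == pytest.approx(
            undersat_params.B0, rel=1e-14
        )

    def test_equilibrium_start_is_constant(self):
        p = LogisticParams.from_equilibrium(k1=1e-2, B_inf=0.1, B0=0.1)
        t = np.linspace(0, 5000, 11)
        assert logistic_solution(t, p) == pytest.approx(0.1, rel=1e-14)

    def test_matches_rk4_oracle_single(self):
        p = LogisticParams(k1=0.01, k_minus=0.1, B0=0.01)
        assert p.B_inf == pytest.approx(0.1)
        expected = rk4_logistic(p, 300.0, dt=0.1)
        assert abs(logistic_solution(300.0, p) - expected) < 1e-8

    def test_matches_rk4_oracle_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = random_logistic_params(rng)
            t_end = float(rng.uniform(50, 500))
            assert abs(logistic_solution(t_end, p) - rk4_logistic(p, t_end)) < 1e-8

    def test_b0_zero_is_degenerate(self):
        p = LogisticParams(k1=1e-2, k_minus=0.1, B0=0.0)
        with pytest.raises(DegenerateInputError):
            logistic_solution(10.0, p)

    def test_negative_time_rejected(self, undersat_params):
        with pytest.raises(DomainError):
            logistic_solution(-1.0, undersat_params)

    def test_satisfies_ode_pointwise(self):
        """Analytic derivative of the sigmoid equals the rate law."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = random_logistic_params(rng)
            t = float(rng.uniform(0, 3.0 / p.k1))
            B = logistic_solution(t, p)
            # dB/dt of the closed form, written independently of the rate law
            ratio = (p.B_inf - p.B0) / p.B0
            E = np.exp(-p.k1 * t)
            dBdt = p.B_inf * ratio * p.k1 * E / (1.0 + ratio * E) ** 2
            assert dBdt == pytest.approx(logistic_rate(B, p), rel=1e-8, abs=1e-16)

    def test_bounded_between_b0_and_binf(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1e5, 300)
        for _ in range(50):
            p = random_logistic_params(rng)
            B = logistic_solution(t, p)
            lo, hi = sorted((p.B0, p.B_inf))
            assert np.all(B >= lo - 1e-15) and np.all(B <= hi + 1e-15)

    def test_shape_dichotomy(self):
        """Undersaturated starts rise strictly; supersaturated decay strictly."""
        t = np.linspace(0, 2000, 200)
        rising = logistic_solution(
            t, LogisticParams.from_equilibrium(1e-2, 0.2, 0.02)
        )
        falling = logistic_solution(
            t, LogisticParams.from_equilibrium(1e-2, 0.2, 0.45)
        )
        assert np.all(np.diff(rising) > 0)
        assert np.all(np.diff(falling) < 0)

    def test_long_time_limit_is_equilibrium(self, undersat_params):
        p = undersat_params
        t_long = 1e4 / p.k1
        assert logistic_solution(t_long, p) == pytest.approx(
            equilibrium_fraction(p.k1, p.k_minus), rel=1e-6
        )

    def test_inflection_at_half_equilibrium(self):
        """The sigmoid's second derivative changes sign once, at B = B_inf/2."""
        from scipy.optimize import brentq

        p = LogisticParams.from_equilibrium(k1=5e-3, B_inf=0.3, B0=0.03)
        t_star = inflection_time(p)
        assert t_star == pytest.approx(np.log(9.0) / 5e-3, rel=1e-12)
        h = 0.5  # wide enough that the second difference beats round-off

        def second_diff(t):
            return (
                logistic_solution(t + h, p)
                - 2 * logistic_solution(t, p)
                + logistic_solution(max(t - h, 0.0), p)
            )

        root = brentq(second_diff, 0.5 * t_star, 1.5 * t_star, xtol=1e-9)
        assert abs(root - t_star) < 1e-6 / p.k1
        assert logistic_solution(root, p) == pytest.approx(p.B_inf / 2, rel=1e-6)
        # sign change is unique: second difference positive before, negative after
        assert second_diff(0.5 * t_star) > 0 > second_diff(1.5 * t_star)

    def test_inflection_absent_for_late_start(self):
        assert inflection_time(LogisticParams.from_equilibrium(1e-2, 0.2, 0.15)) is None


class TestFirstOrder:
    def test_initial_and_zero_rate(self):
        assert first_order_solution(0.0, 0.05, 1e-2) == 0.05
        t = np.linspace(0, 1000, 5)
        assert first_order_solution(t, 0.05, 0.0) == pytest.approx(0.05)

    def test_logistic_converges_to_first_order_as_feedback_vanishes(self):
        """On a fixed horizon, shrinking k_minus brings the sigmoid pointwise
        to the pure exponential, monotonically."""
        k1, B0 = 1e-4, 1e-4
        t = np.linspace(0, 3600, 25)
        exact = first_order_solution(t, B0, k1)
        errs = []
        for k_minus in (1e-1, 1e-2, 1e-3):
            p = LogisticParams(k1=k1, k_minus=k_minus, B0=B0)
            errs.append(np.max(np.abs(logistic_solution(t, p) - exact)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-7


class TestEinsteinMap:
    def test_endpoints_and_arithmetic(self):
        m = EinsteinMap(eta0=10.0, kE=2.5)
        assert viscosity_from_fraction(0.0, m) == 10.0
        assert viscosity_from_fraction(0.2, m) == pytest.approx(15.0)
        assert fraction_from_viscosity(10.0, m) == 0.0
        assert fraction_from_viscosity(10.0 * 3.5, m) == pytest.approx(1.0)

    def test_roundtrip_identity(self):
        m = EinsteinMap(eta0=23.0, kE=2.5)
        B = np.random.default_rng(3).uniform(0, 1, 100)
        back = fraction_from_viscosity(viscosity_from_fraction(B, m), m)
        assert back == pytest.approx(B, abs=1e-12)

    def test_sub_baseline_is_flagged_not_fatal(self):
        m = EinsteinMap(eta0=10.0)
        assert fraction_from_viscosity(9.0, m) < 0

    def test_strictly_increasing(self):
        m = EinsteinMap(eta0=10.0)
        B = np.linspace(0, 1, 50)
        assert np.all(np.diff(viscosity_from_fraction(B, m)) > 0)


class TestLaplaceKelvin:
    def test_laplace_values_and_scaling(self):
        assert laplace_pressure(1e-6, 0.0) == 0.0
        assert laplace_pressure(1e-6, 0.05) == pytest.approx(1e5)
        assert laplace_pressure(2e-6, 0.05) == pytest.approx(0.5e5)
        with pytest.raises(DomainError):
            laplace_pressure(0.0, 0.05)

    def test_kelvin_unit_exponent_and_asymptote(self, fluid):
        lc = fluid.kelvin_length
        assert lc == pytest.approx(
            2 * fluid.gamma * fluid.mu / (BOLTZMANN * fluid.T), rel=1e-14
        )
        assert kelvin_concentration(lc, fluid, 0.02) == pytest.approx(
            0.02 * np.e, rel=1e-12
        )
        assert kelvin_concentration(1e6 * lc, fluid, 0.02) == pytest.approx(
            0.02, rel=1e-5
        )

    def test_kelvin_strictly_decreasing(self, fluid):
        R = np.logspace(-9, -5, 50)
        Bs = kelvin_concentration(R, fluid, 0.02)
        assert np.all(np.diff(Bs) < 0)


class TestEquilibriumFraction:
    def test_values(self):
        assert equilibrium_fraction(0.0, 0.1) == 0.0
        assert equilibrium_fraction(0.1, 0.1) == pytest.approx(1.0)

    def test_no_equilibrium_when_irreversible(self):
        with pytest.raises(NoEquilibriumError):
            equilibrium_fraction(1e-2, 0.0)


class TestParamValidation:
    def test_consistency_enforced(self):
        with pytest.raises(DomainError):
            LogisticParams(k1=1e-2, k_minus=0.1, B0=0.01, B_inf=0.5)

    def test_derived_equilibrium(self):
        p = LogisticParams(k1=1e-2, k_minus=0.05, B0=0.01)
        assert p.B_inf == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k1=-1e-2, k_minus=0.1, B0=0.01),
            dict(k1=1e-2, k_minus=0.1, B0=-0.1),
            dict(k1=1e-2, k_minus=0.1, B0=1.0),
            dict(k1=0.2, k_minus=0.1, B0=0.01),  # B_inf = 2 > 1
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(DomainError):
            LogisticParams(**kwargs)

    def test_fluid_positivity(self):
        with pytest.raises(DomainError):
            FluidProperties(eta0=0.0, gamma=1e-7, D=1e-16, mu=1e-22, T=300.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    k1=st.floats(1e-4, 1e-1),
    b_inf=st.floats(0.02, 0.95),
    s0=st.floats(0.02, 1.9),
    t=st.floats(0, 1e5),
)
def test_sigmoid_stays_physical(k1, b_inf, s0, t):
    """Property: the sigmoid never leaves the band spanned by B0 and B_inf."""
    b0 = min(s0 * b_inf, 0.99)
    p = LogisticParams.from_equilibrium(k1=k1, B_inf=b_inf, B0=b0)
    B = logistic_solution(t, p)
    lo, hi = sorted((b0, b_inf))
    assert lo - 1e-12 <= B <= hi + 1e-12
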