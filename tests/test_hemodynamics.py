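import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from ataa.hemodynamics import (
    CarreauYasudaParams,
    FieldSummary,
    FlowWaveform,
    WindkesselParams,
    WSSTimeSeries,
    carreau_yasuda_viscosity,
    equivalent_windkessel,
    field_summary,
    osi,
    reynolds_max,
    robin_traction,
    tawss,
    windkessel_pressure,
    womersley,
)


def make_series(times, tau, n_nodes=None):
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 2:  # (n_times, 3) single node
        tau = tau[:, None, :]
    n_nodes = tau.shape[1]
    pts = np.zeros((n_nodes, 3))
    pts[:, 2] = np.arange(n_nodes)
    return WSSTimeSeries(points=pts, times=times, tau=tau)


class TestCarreauYasuda:
    def test_zero_shear_plateau(self):
        assert carreau_yasuda_viscosity(0.0) == pytest.approx(11e-3)

    def test_infinite_shear_plateau(self):
        assert carreau_yasuda_viscosity(1e9) == pytest.approx(2e-3, rel=0.01)

    def test_near_wall_rate_against_symbolic_oracle(self):
        g = sp.Integer(350)
        eta = sp.Float("0.002") + (sp.Float("0.011") - sp.Float("0.002")) * (
            1 + (sp.Float("1.5") * g) ** sp.Float("0.2")
        ) ** ((sp.Float("0.71") - 1) / sp.Float("0.2"))
        oracle = float(sp.N(eta, 30))
        assert carreau_yasuda_viscosity(350.0) == pytest.approx(
            oracle, rel=1e-12)

    def test_negative_shear_rate_raises(self):
        with pytest.raises(ValueError):
            carreau_yasuda_viscosity(-1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=0, max_value=1e6))
    def test_monotone_and_bounded(self, g1, g2):
        lo, hi = sorted((g1, g2))
        e_lo = carreau_yasuda_viscosity(lo)
        e_hi = carreau_yasuda_viscosity(hi)
        assert e_hi <= e_lo + 1e-15
        assert 2e-3 - 1e-12 <= e_hi <= 11e-3 + 1e-12

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            CarreauYasudaParams(eta_inf=0.011, eta_0=0.002)
        with pytest.raises(ValueError):
            CarreauYasudaParams(n=1.5)


def constant_waveform(q0, period=0.1, n=101):
    t = np.linspace(0, period, n)
    return FlowWaveform(times=t, q=np.full(n, float(q0)), period=period)


class TestWindkessel:
    # left-subclavian outlet parameters
    WK = WindkesselParams(r_p=19.58, c_wk=5.5e-4, r_d=286.2,
                          outlet_name="left subclavian artery")

    def test_constant_flow_steady_state(self):
        res = windkessel_pressure(constant_waveform(1.0), self.WK,
                                  n_cycles=200, tol_pa=1e-10)
        assert res.pressure[-1] == pytest.approx(305.78, rel=1e-4)

    def test_zero_flow_exponential_decay(self):
        p0 = 1000.0
        res = windkessel_pressure(constant_waveform(0.0), self.WK,
                                  n_cycles=1, p_init=p0, tol_pa=0.0)
        expected = p0 * np.exp(-res.times / (self.WK.r_d * self.WK.c_wk))
        assert np.allclose(res.pressure, expected, rtol=1e-5)

    def test_sinusoidal_flow_matches_phasor_solution(self):
        period = 0.1
        q0, qa = 500.0, 200.0
        n = 257
        t = np.linspace(0, period, n)
        omega = 2 * np.pi / period
        wf = FlowWaveform(times=t, q=q0 + qa * np.sin(omega * t),
                          period=period)
        res = windkessel_pressure(wf, self.WK, n_cycles=100,
                                  n_steps_per_cycle=4000, tol_pa=1e-8)
        # phasor oracle for the linear ODE
        rp, rd, c = self.WK.r_p, self.WK.r_d, self.WK.c_wk
        h = ((1 + rp / rd) / c + 1j * omega * rp) / (1j * omega + 1 / (rd * c))
        expected = q0 * (rp + rd) + np.imag(h * qa * np.exp(1j * omega
                                                            * res.times))
        assert np.allclose(res.pressure, expected, rtol=1e-3)

    def test_cycle_mean_equals_total_resistance_times_mean_flow(self):
        # capacitor carries no net charge over a closed cycle
        period = 0.1
        t = np.linspace(0, period, 201)
        q = 300 + 150 * np.sin(2 * np.pi * t / period) \
            + 80 * np.cos(4 * np.pi * t / period) - 80
        q = q - (q[0] - q[-1])  # already periodic, defensive
        wf = FlowWaveform(times=t, q=q, period=period)
        res = windkessel_pressure(wf, self.WK, n_cycles=200, tol_pa=1e-9)
        expected = wf.mean_flow * (self.WK.r_p + self.WK.r_d)
        assert res.p_mean == pytest.approx(expected, rel=5e-3)

    def test_non_periodic_waveform_rejected(self):
        t = np.linspace(0, 0.1, 50)
        with pytest.raises(ValueError, match="periodic"):
            FlowWaveform(times=t, q=np.linspace(0, 1, 50), period=0.1)

    def test_equivalent_windkessel_parallel(self):
        a = WindkesselParams(10.0, 1e-4, 100.0)
        b = WindkesselParams(10.0, 1e-4, 100.0)
        eq = equivalent_windkessel([a, b])
        assert eq.r_p == pytest.approx(5.0)
        assert eq.r_d == pytest.approx(50.0)
        assert eq.c_wk == pytest.approx(2e-4)


class TestRobinTraction:
    def test_zero_state(self):
        t = robin_traction([0, 0, 0], [0, 0, 0], [0, 0, 1])
        assert np.allclose(t, 0)

    def test_displacement_only(self):
        t = robin_traction([1e-4, 0, 0], [0, 0, 0], [0, 0, 1])
        assert np.allclose(t, [-1e3, 0, 0])

    def test_pure_external_pressure(self):
        n = np.array([0.0, 1.0, 0.0])
        t = robin_traction([0, 0, 0], [0, 0, 0], n, p_0=500.0)
        assert np.allclose(t, -500.0 * n)

    def test_non_unit_normal_raises(self):
        with pytest.raises(ValueError, match="unit"):
            robin_traction([0, 0, 0], [0, 0, 0], [0, 0, 2.0])


class TestTAWSS:
    def test_constant_field(self):
        t = np.linspace(0, 0.1, 16)
        tau = np.tile([3.0, 0.0, 0.0], (16, 1))
        assert tawss(make_series(t, tau)) == pytest.approx(3.0)

    def test_rectified_cosine_analytic(self):
        tau0, period = 2.5, 0.1
        t = np.linspace(0, period, 512)
        tau = np.outer(tau0 * np.cos(2 * np.pi * t / period), [1.0, 0, 0])
        got = tawss(make_series(t, tau))[0]
        assert got == pytest.approx(2 * tau0 / np.pi, rel=1e-3)

    def test_matches_refined_quadrature_oracle(self):
        period = 0.1

        def signal(tt):
            return np.stack([1.0 + 0.8 * np.cos(2 * np.pi * tt / period),
                             0.5 * np.sin(4 * np.pi * tt / period),
                             np.zeros_like(tt)], axis=-1)

        t = np.linspace(0, period, 256)
        got = tawss(make_series(t, signal(t)))[0]
        tt = np.linspace(0, period, 200_001)
        oracle = np.trapezoid(np.linalg.norm(signal(tt), axis=-1), tt) / period
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_second_order_convergence(self):
        tau0, period = 1.0, 0.1
        exact = 2 * tau0 / np.pi

        def err(n):
            t = np.linspace(0, period, n)
            tau = np.outer(tau0 * np.cos(2 * np.pi * t / period), [1.0, 0, 0])
            return abs(tawss(make_series(t, tau))[0] - exact)

        # |cos| has kinks, but the grid hits them symmetrically: ~2nd order
        assert err(1024) < err(256) / 3.0

    def test_unsorted_times_rejected(self):
        t = np.array([0.0, 0.05, 0.04, 0.1])
        with pytest.raises(ValueError):
            make_series(t, np.ones((4, 3)))

    def test_too_few_samples_rejected(self):
        t = np.array([0.0, 0.1])
        with pytest.raises(ValueError):
            tawss(make_series(t, np.ones((2, 3))))


class TestOSI:
    def test_constant_direction_zero(self):
        t = np.linspace(0, 0.1, 64)
        mag = 2.0 + np.sin(2 * np.pi * t / 0.1) ** 2  # varying, no reversal
        tau = np.outer(mag, [0, 1.0, 0])
        assert osi(make_series(t, tau))[0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_reversal_half(self):
        t = np.linspace(0, 0.1, 512)
        tau = np.outer(np.cos(2 * np.pi * t / 0.1), [1.0, 0, 0])
        assert osi(make_series(t, tau))[0] == pytest.approx(0.5, abs=1e-6)

    def test_zero_field_convention(self):
        t = np.linspace(0, 0.1, 16)
        assert osi(make_series(t, np.zeros((16, 3))))[0] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_n = 32, 5
        t = np.linspace(0, 0.1, n_t)
        tau = rng.normal(size=(n_t, n_n, 3))
        series = make_series(t, tau)
        o = osi(series)
        assert np.all((o >= 0) & (o <= 0.5))
        # TAWSS >= |mean WSS vector| per node
        mean_vec = np.trapezoid(tau, t, axis=0) / (t[-1] - t[0])
        assert np.all(tawss(series) >= np.linalg.norm(mean_vec, axis=1)
                      - 1e-12)


class TestFieldSummary:
    def test_uniform_field(self):
        v = np.full(10, 4.2)
        for stat in ("min", "mean", "max"):
            assert field_summary(v, stat).value == pytest.approx(4.2)

    def test_region_masks(self):
        v = np.array([1.0, 1.0, 5.0, 5.0])
        mask = np.array([True, True, False, False])
        assert field_summary(v, "mean", region_mask=mask).value == 1.0
        assert field_summary(v, "mean", region_mask=~mask).value == 5.0

    def test_matches_brute_force(self, rng):
        v = rng.normal(size=100)
        assert field_summary(v, "min").value == pytest.approx(sorted(v)[0])
        assert field_summary(v, "max").value == pytest.approx(sorted(v)[-1])
        assert field_summary(v, "mean").value == pytest.approx(sum(v) / 100)

    def test_weighted_mean(self):
        v = np.array([1.0, 3.0])
        w = np.array([3.0, 1.0])
        assert field_summary(v, "mean", weights=w).value == pytest.approx(1.5)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            field_summary(np.array([1.0]), "mean",
                          region_mask=np.array([False]))


class TestDimensionlessNumbers:
    def test_reynolds_reference_value(self):
        # 1027 * 0.35 * 0.002 / 0.00335
        got = reynolds_max(0.35, 0.002)
        assert got == pytest.approx(1027 * 0.35 * 0.002 / 0.00335, rel=1e-12)
        assert 143 <= got <= 227  # observed cohort range

    def test_reynolds_linearity(self):
        assert reynolds_max(0.7, 0.002) == pytest.approx(
            2 * reynolds_max(0.35, 0.002))

    def test_reynolds_unit_round_trip(self):
        si = reynolds_max(0.35, 0.002)
        mm = 1027.0 * (0.35e3 * 1e-3) * (2.0 * 1e-3) / 0.00335
        assert si == pytest.approx(mm)

    def test_reynolds_nonpositive_raises(self):
        with pytest.raises(ValueError):
            reynolds_max(0.0, 0.002)

    def test_womersley_independent_arithmetic(self):
        got = womersley(0.002, 0.1)
        oracle = 0.001 * math.sqrt(2 * math.pi * 1027 / (0.1 * 0.00335))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_womersley_viscosity_scaling(self):
        assert womersley(0.002, 0.1, mu=4 * 0.00335) == pytest.approx(
            womersley(0.002, 0.1) / 2)

    def test_womersley_diameter_scaling(self):
        assert womersley(0.004, 0.1) == pytest.approx(2 * womersley(0.002, 0.1))

    def test_womersley_nonpositive_raises(self):
        with pytest.raises(ValueError):
            womersley(0.002, 0.0)
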