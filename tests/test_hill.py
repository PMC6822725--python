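"""Hill fiber curves and cyclic-contraction analytics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from undulate.hill import (
    CyclicLoad,
    FiberParams,
    activation_fraction,
    cycle_metrics,
    eta_m_cyclic,
    fiber_consumption_rel,
    fiber_efficiency,
    fiber_force_rel,
    force_loop,
    max_eta_m,
    max_psi,
    max_theta,
    peak_cyclic_power,
    peak_fiber_efficiency,
    peak_power_point,
)

PARAMS = FiberParams()


class TestFiberCurves:
    @pytest.mark.parametrize(
        "vr, expected",
        [
            (0.0, 1.0),            # isometric
            (1.0, 0.0),            # concentric limit: no force at vmax
            (-1.0, 1.8),           # eccentric plateau
            (0.31, 0.69 / 2.24),   # direct substitution, G = 4
        ],
    )
    def test_force_values(self, vr, expected):
        assert fiber_force_rel(vr, PARAMS) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "vr, expected",
        [
            (0.0, 0.07),
            (-1.0, 0.01 + 0.11 + 0.06 * math.exp(-23.0)),
            (0.23, 0.23 - 0.16 * math.exp(-1.84)),
        ],
    )
    def test_consumption_values(self, vr, expected):
        assert fiber_consumption_rel(vr, PARAMS) == pytest.approx(expected, abs=1e-12)

    def test_branch_continuity_at_zero(self):
        eps = 1e-12
        assert fiber_force_rel(-eps) == pytest.approx(fiber_force_rel(eps), abs=1e-9)
        assert fiber_consumption_rel(-eps) == pytest.approx(
            fiber_consumption_rel(eps), abs=1e-9
        )

    def test_force_decreasing_concentric(self):
        vr = np.linspace(0.0, 1.0, 200)
        assert np.all(np.diff(fiber_force_rel(vr, PARAMS)) < 0)

    def test_consumption_positive(self):
        vr = np.linspace(-1.0, 1.0, 400)
        assert np.all(fiber_consumption_rel(vr, PARAMS) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fiber_force_rel(1.5)
        with pytest.raises(ValueError):
            fiber_consumption_rel(-1.5)
        with pytest.raises(ValueError):
            fiber_efficiency(-0.1)


class TestFiberOptima:
    def test_peak_efficiency(self):
        vr, eta = peak_fiber_efficiency(PARAMS)
        assert round(vr, 2) == 0.23
        assert eta == pytest.approx(0.451, abs=5e-4)

    def test_efficiency_vanishes_at_ends(self):
        assert fiber_efficiency(1.0, PARAMS) == 0.0
        assert fiber_efficiency(1e-9, PARAMS) < 1e-7

    def test_peak_power_closed_form(self):
        vr, p = peak_power_point(PARAMS)
        assert vr == pytest.approx((math.sqrt(5) - 1) / 4, abs=1e-14)
        assert round(vr, 2) == 0.31
        assert p == pytest.approx(0.09549, abs=5e-6)
        # constant-rate peak in W/kg with the standard constants
        assert p * PARAMS.specific_power_scale == pytest.approx(71.6, abs=0.05)

    def test_peak_power_other_shape_constant(self):
        # general closed form (sqrt(1+G)-1)/G against a grid search
        params = FiberParams(G=2.5)
        vr, _ = peak_power_point(params)
        grid = np.linspace(1e-6, 1.0, 200001)
        brute = grid[np.argmax(grid * fiber_force_rel(grid, params))]
        assert vr == pytest.approx(brute, abs=1e-5)


class TestActivation:
    def test_zero_force(self):
        assert activation_fraction(0.0, 0.5) == 0.0

    def test_full_isometric(self):
        assert activation_fraction(1.0, 0.0) == pytest.approx(1.0)

    def test_exceeds_capacity(self):
        mu = activation_fraction(0.5, 0.31)
        assert mu == pytest.approx(0.5 / (0.69 / 2.24), rel=1e-12)
        assert mu > 1.0  # infeasible but not an error

    def test_rate_domain_error(self):
        with pytest.raises(ValueError):
            activation_fraction(0.5, 1.2)


class TestCycleMetrics:
    def test_worked_example(self):
        m = cycle_metrics(CyclicLoad(0.35, 0.20, 60.0), PARAMS, n_quad=4096)
        assert m.p_bar == pytest.approx(0.0175, rel=1e-10)
        assert m.eta_m == pytest.approx(0.336, abs=5e-4)
        assert m.feasible and m.mu_hat < 1.0
        assert 0.0 < m.braking_fraction < 0.5  # Phi < 90 deg: minority braking

    def test_quadrature_phi_90_gives_zero_power(self):
        m = cycle_metrics(CyclicLoad(0.4, 0.3, 90.0), PARAMS)
        assert abs(m.p_bar) < 1e-15
        assert m.eta_m < 1e-12
        assert m.q_bar > 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        F=st.floats(0.01, 1.5),
        v=st.floats(0.01, 0.95),
        phi=st.floats(0.0, 180.0),
    )
    def test_pbar_matches_closed_form(self, F, v, phi):
        m = cycle_metrics(CyclicLoad(F, v, phi), PARAMS, n_quad=2048)
        closed = 0.5 * F * v * math.cos(math.radians(phi))
        assert m.p_bar == pytest.approx(closed, abs=1e-9 + 1e-6 * abs(closed))
        assert m.q_bar >= 0.0
        if F > 0:
            assert m.q_bar > 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        F1=st.floats(0.05, 0.5),
        k=st.floats(0.1, 4.0),
        v=st.floats(0.01, 0.9),
        phi=st.floats(0.0, 180.0),
    )
    def test_eta_m_scale_invariant_in_force(self, F1, k, v, phi):
        m1 = cycle_metrics(CyclicLoad(F1, v, phi), PARAMS)
        m2 = cycle_metrics(CyclicLoad(k * F1, v, phi), PARAMS)
        assert m2.eta_m == pytest.approx(m1.eta_m, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        F=st.floats(0.01, 1.5),
        v=st.floats(0.01, 0.95),
        phi=st.floats(0.0, 180.0),
    )
    def test_eta_m_below_cyclic_maximum(self, F, v, phi):
        m = cycle_metrics(CyclicLoad(F, v, phi), PARAMS)
        assert m.eta_m <= 0.445 + 1e-4


class TestCyclicEnvelopes:
    def test_max_psi_zero_at_rest(self):
        assert max_psi(0.0, PARAMS) == 0.0

    def test_peak_cyclic_power_is_half_constant_rate(self):
        vr_c, psi = peak_cyclic_power(PARAMS)
        vr_p, p_star = peak_power_point(PARAMS)
        assert vr_c == pytest.approx(vr_p, abs=1e-6)
        assert psi / (p_star * PARAMS.specific_power_scale) == pytest.approx(0.5, abs=1e-9)
        assert psi == pytest.approx(35.8, abs=0.05)

    def test_max_psi_unimodal(self):
        vr = np.linspace(0.01, 0.98, 300)
        vals = max_psi(vr, PARAMS)
        peak = np.argmax(vals)
        assert np.all(np.diff(vals[: peak + 1]) > 0)
        assert np.all(np.diff(vals[peak:]) < 0)
        assert vr[peak] == pytest.approx((math.sqrt(5) - 1) / 4, abs=0.01)

    def test_max_theta_zero_amplitude_limit(self):
        # fully activated muscle at rest: theta = (2/pi) Q_f(0)
        expected = (2.0 / math.pi) * 0.07 * PARAMS.specific_power_scale
        assert max_theta(0.0, PARAMS, n_quad=8192) == pytest.approx(expected, rel=1e-6)

    def test_max_eta_m(self):
        vr, eta = max_eta_m(PARAMS)
        assert round(vr, 2) == 0.27
        assert eta == pytest.approx(0.445, abs=5e-4)
        # cyclic maximum marginally below the constant-rate fiber maximum
        _, eta_f = peak_fiber_efficiency(PARAMS)
        assert eta < eta_f

    def test_eta_m_cyclic_vanishes_at_small_amplitude(self):
        # eta_m ~ (pi/4) vhat / Q_f(0)-ish for small amplitudes
        assert eta_m_cyclic(1e-4, PARAMS) < 2e-3
        assert eta_m_cyclic(1e-4, PARAMS) < eta_m_cyclic(1e-2, PARAMS)


class TestForceLoop:
    def test_degenerate_line_at_zero_phase(self):
        fl = force_loop(CyclicLoad(0.3, 0.2, 0.0), PARAMS)
        # v and F are proportional: the ellipse collapses to a line
        corr = np.corrcoef(fl["v_r"], fl["Fm_rel"])[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)

    def test_envelope_binding_at_peak(self):
        vhat = 0.25
        F_env = float(np.asarray(fiber_force_rel(vhat, PARAMS)))
        fl = force_loop(CyclicLoad(F_env, vhat, 0.0), PARAMS)
        assert fl["feasible"]
        assert fl["mu_hat"] == pytest.approx(1.0, abs=1e-4)

    def test_worked_example_feasible(self):
        fl = force_loop(CyclicLoad(0.35, 0.20, 60.0), PARAMS)
        assert fl["feasible"] and fl["mu_hat"] < 1.0
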