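"""Slender-body hydrodynamics: lateral forces, recoil, thrust, drag, speed."""

import numpy as np
import pytest

from undulate.body import MotionSpec, ShapeParams, build_geometry, build_motion
from undulate.hydro import (
    NoSteadySpeedError,
    RecoilSolution,
    drag_coefficient,
    hydro_power_and_efficiency,
    lateral_force_field,
    mean_thrust,
    solve_recoil,
    solve_speed,
)

SHAPE = ShapeParams(DL=0.20, BL=0.15, c_d1=0.05, c_d2=0.02, c_b1=1.2)


@pytest.fixture(scope="module")
def geom():
    return build_geometry(SHAPE, m=1.0)


@pytest.fixture(scope="module")
def motion(geom):
    return build_motion(geom, omega=8.0, env_coeffs=(0.03, 0.03, 0.012))


def _no_recoil(motion):
    return RecoilSolution(Y0=0j, Phi_r=0j, H_hat=motion.H,
                          residual_force=0.0, residual_moment=0.0)


class TestLateralForce:
    def test_zero_motion_zero_force(self, geom):
        FL = lateral_force_field(geom, 8.0, 0.5, np.zeros(geom.n, dtype=complex))
        assert np.all(FL == 0)

    def test_rigid_heave_added_mass_inertia(self, geom):
        # U = 0, H_hat = Y0 const: F_L amplitude = m_a omega^2 Y0
        Y0 = 0.01 + 0.0j
        omega = 8.0
        FL = lateral_force_field(geom, omega, 0.0, np.full(geom.n, Y0))
        assert np.allclose(FL, -(omega**2) * geom.m_a * Y0, rtol=1e-12)

    def test_traveling_wave_at_wave_speed_kills_material_derivative(self, geom):
        # uniform m_a would give F_L = 0 exactly; with varying m_a the first
        # material derivative already vanishes: (-i w + U ik) e^{ikx} = 0
        k = 2 * np.pi / geom.L
        omega = 8.0
        U = omega / k
        H = np.exp(1j * k * geom.x)
        w = -1j * omega * H + U * (geom.D1 @ H)
        assert np.max(np.abs(w)) < 1e-6 * omega


class TestRecoil:
    def test_zero_motion_zero_recoil(self, geom):
        mot_zero = build_motion(geom, omega=8.0, env_coeffs=(0.0,))
        rec = solve_recoil(geom, mot_zero, 0.3)
        assert abs(rec.Y0) == 0.0 and abs(rec.Phi_r) == 0.0

    def test_plugback_residuals(self, geom, motion):
        for U in (0.0, 0.2, 0.6):
            rec = solve_recoil(geom, motion, U)
            assert rec.residual_force < 1e-10
            assert rec.residual_moment < 1e-10

    def test_recoil_grid_invariance(self):
        vals = []
        for n in (256, 512):
            g = build_geometry(SHAPE, m=1.0, n=n)
            mo = build_motion(g, omega=8.0, env_coeffs=(0.03, 0.03, 0.012))
            rec = solve_recoil(g, mo, 0.4)
            vals.append((rec.Y0, rec.Phi_r))
        assert abs(vals[1][0] - vals[0][0]) < 1e-3 * abs(vals[0][0])
        assert abs(vals[1][1] - vals[0][1]) < 1e-3 * abs(vals[0][1])


class TestThrust:
    def test_zero_at_wave_speed_uniform_envelope(self, geom):
        omega = 8.0
        k = 2 * np.pi / geom.L
        mot = build_motion(geom, omega=omega, env_coeffs=(0.04,))
        F_T = mean_thrust(geom, mot, _no_recoil(mot), U=omega / k)
        scale = 0.25 * geom.m_a[-1] * (omega * mot.r[-1]) ** 2
        assert abs(F_T) < 1e-5 * scale

    def test_stationary_closed_form(self, geom):
        omega = 8.0
        mot = build_motion(geom, omega=omega, env_coeffs=(0.04,))
        F_T = mean_thrust(geom, mot, _no_recoil(mot), U=0.0)
        expected = geom.m_a[-1] * omega**2 * mot.r[-1] ** 2 / 4.0
        assert F_T == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_speed(self, geom):
        omega = 8.0
        mot = build_motion(geom, omega=omega, env_coeffs=(0.04,))
        rec = _no_recoil(mot)
        speeds = np.linspace(0.0, 1.5, 12)
        thrusts = [mean_thrust(geom, mot, rec, U) for U in speeds]
        assert np.all(np.diff(thrusts) < 0)


class TestDrag:
    def test_laminar_value(self):
        Cf, CD = drag_coefficient(1e4, 0.0)
        assert Cf == pytest.approx(0.0133, rel=1e-12)
        assert CD == Cf  # no shape factor at DL = 0

    def test_shape_factor(self):
        DL = 0.2
        Cf, CD = drag_coefficient(1e4, DL)
        assert CD / Cf == pytest.approx(1.0 + 1.5 * DL**1.5 + 7.0 * DL**3, rel=1e-12)

    def test_transition_jump_ratio(self):
        below = drag_coefficient(5e5, 0.0)[0]
        above = drag_coefficient(5e5 * (1 + 1e-12), 0.0)[0]
        assert above / below == pytest.approx(2.774, abs=5e-3)
        assert above > below


class TestSpeedSolve:
    def test_solution_balances_forces(self, geom, motion):
        sol = solve_speed(geom, motion)[0]
        # consistency of branch and Reynolds number
        assert (sol.Re <= 5e5) == (sol.branch == "laminar")
        Cf, CD = drag_coefficient(sol.Re, SHAPE.DL)
        F_D = 0.5 * 1000.0 * sol.U**2 * geom.S * CD
        assert sol.F_T == pytest.approx(F_D, rel=1e-6)

    def test_manufactured_root_matches_bisection(self, geom):
        # closed-form thrust (no recoil) against the packaged root for a
        # manufactured drag balance, on the laminar branch
        from scipy.optimize import brentq

        omega = 8.0
        mot = build_motion(geom, omega=omega, env_coeffs=(0.04,))
        rec = _no_recoil(mot)

        def net(U):
            Re = U * geom.L / 1e-6
            Cf = 1.33 * Re**-0.5
            CD = Cf * (1 + 1.5 * SHAPE.DL**1.5 + 7 * SHAPE.DL**3)
            return mean_thrust(geom, mot, rec, U) - 0.5 * 1000 * U**2 * geom.S * CD

        U_manual = brentq(net, 1e-3, 2.0, rtol=1e-12)
        assert net(U_manual) == pytest.approx(0.0, abs=1e-8)

    def test_zero_amplitude_no_speed(self, geom):
        mot = build_motion(geom, omega=8.0, env_coeffs=(0.0,))
        with pytest.raises(NoSteadySpeedError):
            solve_speed(geom, mot)


class TestHydroPower:
    def test_efficiency_in_unit_interval(self, geom, motion):
        sol = solve_speed(geom, motion)[0]
        assert 0.0 < sol.eta_H < 1.0

    def test_wake_energy_flux_nonnegative(self, geom, motion):
        # Lighthill energy identity: P_H - F_T U >= 0 (energy shed to wake),
        # including speeds above equilibrium where F_T and P_H go negative
        for U in (0.1, 0.3, 0.6, 1.0):
            rec = solve_recoil(geom, motion, U)
            P_H, _ = hydro_power_and_efficiency(geom, motion, rec, U)
            F_T = mean_thrust(geom, motion, rec, U)
            assert P_H - F_T * U > 0

    def test_zero_speed_zero_efficiency(self, geom, motion):
        # at U = 0 the reactive forces do no net cycle work: P_H ~ 0, and
        # with no useful propulsion work the efficiency is zero
        rec = solve_recoil(geom, motion, 0.0)
        P_H, eta_H = hydro_power_and_efficiency(geom, motion, rec, 0.0)
        assert eta_H == 0.0
        scale = abs(mean_thrust(geom, motion, rec, 0.0)) * 1.0
        assert abs(P_H) < 1e-12 * max(scale, 1.0)
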