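"""Slender-body (Lighthill) hydrodynamics of steady undulatory swimming.

The lateral reactive force per unit length on a slender body moving with
total deflection h^(x, t) at forward speed U is

    F_L = (d/dt + U d/dx) [ m_a(x) (d/dt + U d/dx) h^ ],

with m_a(x) = rho pi d(x)^2 / 4 the added mass of an elliptical section
translating perpendicular to its vertical axis.  The total deflection
h^ = h + y0 + x phi includes the rigid lateral and angular recoil, fixed by
whole-body lateral force and moment balance.  Mean thrust follows from
Lighthill's tail formula; drag from an empirical friction coefficient with a
laminar-turbulent jump at Re_cr and a shape factor in the tail-height ratio.
The steady speed U solves mean thrust = mean drag on each drag branch.

All operators act on complex amplitudes of the single time harmonic;
time averages of products are (1/2) Re[A conj(B)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._grid import cumtrapz, trapz
from .body import BodyGeometry, MotionSpec

__all__ = [
    "RecoilSolution",
    "HydroResult",
    "NoSteadySpeedError",
    "lateral_force_field",
    "solve_recoil",
    "mean_thrust",
    "drag_coefficient",
    "solve_speed",
    "hydro_power_and_efficiency",
]


class NoSteadySpeedError(RuntimeError):
    """Thrust never balances drag at a positive speed."""


@dataclass(frozen=True)
class RecoilSolution:
    """Rigid-body recoil amplitudes and the total deflection field.

    Y0 : complex lateral recoil amplitude (m); Phi_r : complex angular recoil
    amplitude (rad); H_hat : H + Y0 + x Phi_r on the grid; residuals :
    relative force/moment balance residuals after the solve.
    """

    Y0: complex
    Phi_r: complex
    H_hat: np.ndarray
    residual_force: float
    residual_moment: float


@dataclass(frozen=True)
class HydroResult:
    """Steady-swimming solution on one drag branch."""

    U: float
    Re: float
    branch: str  # "laminar" | "turbulent"
    F_T: float
    F_D: float
    P_H: float
    eta_H: float
    recoil: RecoilSolution


def _material_operator(geom: BodyGeometry, omega: float, U: float, f: np.ndarray) -> np.ndarray:
    """(d/dt + U d/dx) applied to a complex amplitude: -i omega f + U f'."""
    return -1j * omega * f + U * (geom.D1 @ f)


def lateral_force_field(
    geom: BodyGeometry,
    omega: float,
    U: float,
    H_hat: np.ndarray,
) -> np.ndarray:
    """Complex amplitude of F_L(x) for a given total deflection amplitude."""
    w = _material_operator(geom, omega, U, H_hat)
    return _material_operator(geom, omega, U, geom.m_a * w)


class _RecoilOperator:
    """Precomputed recoil balance for one (geometry, motion) pair.

    The load on a deflection basis field g is quadratic in U:

        load[g](U) = -omega^2 (rho A + m_a) g
                     - i omega U [ (m_a g)' + m_a g' ]
                     + U^2 (m_a g')',

    so both balance functionals (force: int load dx; moment: the tail value
    of the double integral, int (L - x) load dx, in the same nested
    trapezoids as the bending-moment extraction so the free-tail closure
    M(L) = M'(L) = 0 holds to machine precision) reduce to degree-2
    polynomials in U whose coefficients are integrated once.  Solving the
    recoil at any U is then a 2x2 complex solve with no grid work, which is
    what makes the speed root-find and the evolutionary optimizer cheap.
    """

    def __init__(self, geom: BodyGeometry, motion: MotionSpec):
        self.geom = geom
        self.motion = motion
        omega = motion.omega
        x = geom.x
        rhoA = geom.constants.rho * geom.A
        m_a = geom.m_a
        D1 = geom.D1
        self._coef = {}
        for name, g in (
            ("H", motion.H.astype(complex)),
            ("1", np.ones_like(x, dtype=complex)),
            ("x", x.astype(complex)),
        ):
            gp = D1 @ g
            P0 = -(omega**2) * (rhoA + m_a) * g
            P1 = -1j * omega * (D1 @ (m_a * g) + m_a * gp)
            P2 = D1 @ (m_a * gp)
            self._coef[name] = (
                np.array([trapz(P, x) for P in (P0, P1, P2)]),
                np.array([trapz(cumtrapz(P, x), x) for P in (P0, P1, P2)]),
            )
        self._H_tail = motion.H[-1]
        self._dH_tail = (D1 @ motion.H)[-1]

    def _balance(self, name: str, U: float) -> tuple[complex, complex]:
        f, m = self._coef[name]
        u = np.array([1.0, U, U * U])
        return f @ u, m @ u

    def solve(self, U: float) -> RecoilSolution:
        fH, mH = self._balance("H", U)
        f1, m1 = self._balance("1", U)
        fx, mx = self._balance("x", U)
        Amat = np.array([[f1, fx], [m1, mx]])
        Y0, Phi_r = np.linalg.solve(Amat, -np.array([fH, mH]))
        H_hat = self.motion.H + Y0 + Phi_r * self.geom.x
        fr = fH + f1 * Y0 + fx * Phi_r
        mr = mH + m1 * Y0 + mx * Phi_r
        scale_f = max(abs(fH), abs(f1 * Y0), abs(fx * Phi_r), 1e-300)
        scale_m = max(abs(mH), abs(m1 * Y0), abs(mx * Phi_r), 1e-300)
        return RecoilSolution(
            Y0=complex(Y0),
            Phi_r=complex(Phi_r),
            H_hat=H_hat,
            residual_force=float(abs(fr) / scale_f),
            residual_moment=float(abs(mr) / scale_m),
        )

    def thrust(self, rec: RecoilSolution, U: float) -> float:
        ma_tail = self.geom.m_a[-1]
        if ma_tail == 0.0:
            return 0.0
        Ht = self.motion.omega * abs(self._H_tail + rec.Y0 + rec.Phi_r * self.geom.L)
        Hx = abs(self._dH_tail + rec.Phi_r)
        return 0.25 * ma_tail * (Ht**2 - U**2 * Hx**2)


def solve_recoil(geom: BodyGeometry, motion: MotionSpec, U: float) -> RecoilSolution:
    """Solve the whole-body lateral force and moment balance for (Y0, Phi_r).

    Everything is linear in the deflection, so the residual of each balance
    is expanded on the basis {H, 1, x} and the rigid amplitudes solved for
    directly; the plug-back residuals are recorded on the solution.
    """
    return _RecoilOperator(geom, motion).solve(U)


def mean_thrust(geom: BodyGeometry, motion: MotionSpec, recoil: RecoilSolution, U: float) -> float:
    """Lighthill's mean thrust from the tail section:

    F_T = (1/2) m_a(L) [ <h^_t^2> - U^2 <h^_x^2> ]  at x = L,
    with <.> = (1/2)|amplitude|^2 for the single harmonic.
    """
    ma_tail = geom.m_a[-1]
    if ma_tail == 0.0:
        return 0.0
    Ht = motion.omega * abs(recoil.H_hat[-1])
    Hx = abs((geom.D1 @ recoil.H_hat)[-1])
    return 0.5 * ma_tail * 0.5 * (Ht**2 - U**2 * Hx**2)


def drag_coefficient(Re: float, DL: float) -> tuple[float, float]:
    """Friction and total drag coefficients (C_f, C_D) at Reynolds number Re.

    C_f = 1.33 Re^-1/2 (laminar, Re <= Re_cr) or 0.072 Re^-1/5 (turbulent);
    C_D = C_f (1 + 1.5 DL^1.5 + 7.0 DL^3) with DL = D/L.  The jump at Re_cr
    (ratio ~2.77) is the mechanism behind the optimal-swimmer transition
    ranges in body mass.
    """
    if Re <= 0:
        raise ValueError("Re must be positive")
    Re_cr = 5e5
    Cf = 1.33 * Re**-0.5 if Re <= Re_cr else 0.072 * Re**-0.2
    return Cf, Cf * (1.0 + 1.5 * DL**1.5 + 7.0 * DL**3)


def _branch_cf(Re: float, branch: str) -> float:
    return 1.33 * Re**-0.5 if branch == "laminar" else 0.072 * Re**-0.2


def _net_force(op: _RecoilOperator, U: float, branch: str) -> float:
    geom = op.geom
    rec = op.solve(U)
    F_T = op.thrust(rec, U)
    Re = U * geom.L / geom.constants.nu
    DL = geom.shape.DL
    Cf = _branch_cf(Re, branch)
    CD = Cf * (1.0 + 1.5 * DL**1.5 + 7.0 * DL**3)
    F_D = 0.5 * geom.constants.rho * U**2 * geom.S * CD
    return F_T - F_D


def solve_speed(
    geom: BodyGeometry,
    motion: MotionSpec,
    U_min: float = 1e-4,
    U_max: float = 1e3,
    rtol: float = 1e-10,
) -> list[HydroResult]:
    """Find steady speeds where mean thrust balances mean drag.

    The laminar (Re <= Re_cr) and turbulent branches are searched separately
    on a log grid in U with bracketed root refinement; a root is kept only if
    its Reynolds number is consistent with its branch.  Both branches can be
    simultaneously self-consistent near the transition; results are returned
    fastest first.
    """
    if not np.any(motion.r > 0):
        raise NoSteadySpeedError("zero-amplitude motion produces no thrust")
    op = _RecoilOperator(geom, motion)
    U_cr = geom.constants.Re_cr * geom.constants.nu / geom.L
    results: list[HydroResult] = []
    for branch, lo, hi in (
        ("laminar", U_min, min(U_cr, U_max)),
        ("turbulent", U_cr, U_max),
    ):
        if hi <= lo:
            continue
        grid = np.geomspace(lo, hi, 60)
        vals = [_net_force(op, u, branch) for u in grid]
        for i in range(len(grid) - 1):
            if vals[i] > 0.0 >= vals[i + 1]:
                U = brentq(
                    lambda u: _net_force(op, u, branch),
                    grid[i], grid[i + 1], rtol=rtol,
                )
                Re = U * geom.L / geom.constants.nu
                ok = Re <= geom.constants.Re_cr if branch == "laminar" else Re >= geom.constants.Re_cr
                if not ok:
                    continue
                rec = op.solve(U)
                F_T = op.thrust(rec, U)
                P_H, eta_H = hydro_power_and_efficiency(geom, motion, rec, U)
                results.append(
                    HydroResult(
                        U=U, Re=Re, branch=branch,
                        F_T=F_T, F_D=F_T, P_H=P_H, eta_H=eta_H, recoil=rec,
                    )
                )
                break
    if not results:
        raise NoSteadySpeedError("no steady speed: thrust insufficient to reach balance")
    results.sort(key=lambda r: -r.U)
    return results


def hydro_power_and_efficiency(
    geom: BodyGeometry,
    motion: MotionSpec,
    recoil: RecoilSolution,
    U: float,
) -> tuple[float, float]:
    """Mean power delivered to the fluid and the Froude efficiency.

    P_H = int <F_L h^_t> dx; eta_H = F_T U / P_H (zero at U = 0).  The excess
    P_H - F_T U is the kinetic energy flux shed into the wake, non-negative
    for any motion; at a steady solution (F_T > 0) this makes P_H > 0 and
    0 < eta_H < 1.  Away from equilibrium F_T (and hence P_H) may be
    negative; eta_H is then reported as 0.  A positive useful power with
    non-positive total power would break the energy identity and raises.
    """
    FL = lateral_force_field(geom, motion.omega, U, recoil.H_hat)
    ht = -1j * motion.omega * recoil.H_hat
    P_H = float(trapz(0.5 * np.real(FL * np.conj(ht)), geom.x))
    F_T = mean_thrust(geom, motion, recoil, U)
    if P_H <= 0.0 and F_T * U > 0.0:
        raise RuntimeError("non-positive hydrodynamic power: model inconsistency")
    eta_H = F_T * U / P_H if (U > 0 and P_H > 0) else 0.0
    return P_H, eta_H
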