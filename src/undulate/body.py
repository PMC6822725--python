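"""Body geometry and undulatory kinematics.

The swimmer is a neutrally buoyant slender body with elliptical cross
sections, described by smooth height and width profiles d(x), b(x) on
x in [0, L].  The locomotory (red) muscle forms a thin superficial strip on
each side at distance b/2 from the midline, with one-side section area
A_m = 0.5 mu0 A.  The undulatory motion is a single-harmonic traveling wave
h(x, t) = r(x) cos(2 pi x / lambda_b - omega t) with body wavelength
lambda_b = L.

Shape basis (5 parameters)
--------------------------
With xi = x/L:

    d(xi)/L = DL + c_d1 sin(pi xi) + c_d2 sin(2 pi xi)
    b(xi)/L = BL * sin(pi xi)**c_b1

The height equals the tail height D at both ends (nonzero tail added mass);
c_d1 sets the mid-body bulge and c_d2 skews it fore/aft, so both fusiform
and peduncled outlines are representable.  The width tapers to zero at the
snout and tail, which sends the bending stiffness I = (pi/64) d b^3 to zero
cubically at the ends: the free-end boundary conditions of the structural
beam are then satisfied for any smooth envelope.

Motion basis (4 parameters)
---------------------------
omega plus three Chebyshev coefficients of the envelope,
r(xi)/L = e0 T0 + e1 T1(2 xi - 1) + e2 T2(2 xi - 1), with non-negativity of
r required on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as cheb

from ._grid import deriv_matrix, second_deriv_matrix, trapz
from .constants import Constants, DEFAULT_CONSTANTS

__all__ = ["ShapeParams", "BodyGeometry", "MotionSpec", "build_geometry", "build_motion",
           "contraction_field"]


class InvalidShapeError(ValueError):
    """Shape parameters yield a non-positive profile."""


class InfeasibleMotionError(ValueError):
    """Motion parameters violate a kinematic constraint (e.g. r < 0)."""


@dataclass(frozen=True)
class ShapeParams:
    """Dimensionless shape coefficients: tail-height ratio DL = D/L, max-width
    ratio BL = B/L, height-profile coefficients c_d1, c_d2, width exponent c_b1."""

    DL: float
    BL: float
    c_d1: float
    c_d2: float
    c_b1: float

    def profiles(self, xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Normalized profiles (d/L, b/L) on xi in [0, 1]."""
        if self.DL <= 0 or self.BL <= 0:
            raise InvalidShapeError("DL and BL must be positive")
        if self.c_b1 <= 0:
            raise InvalidShapeError("width exponent c_b1 must be positive")
        s = np.sin(np.pi * xi)
        s[np.abs(s) < 1e-12] = 0.0  # sin(pi) round-off: the ends are exact zeros
        d = self.DL + self.c_d1 * s + self.c_d2 * np.sin(2.0 * np.pi * xi)
        b = self.BL * np.clip(s, 0.0, None) ** self.c_b1
        if np.any(d <= 0.0):
            raise InvalidShapeError("height profile non-positive somewhere on the body")
        return d, b


@dataclass(frozen=True)
class BodyGeometry:
    """Discretized body: grids and section fields (SI units).

    x : N positions on [0, L]; d, b : height/width; A : section area;
    A_m : one-side muscle section 0.5 mu0 A; I : lateral-bending second
    moment (pi/64) d b^3; m_a : added mass per length rho pi d^2 / 4;
    L, m, S : length, mass, wetted surface; m_M = 0.5 mu0 m.
    """

    x: np.ndarray
    d: np.ndarray
    b: np.ndarray
    A: np.ndarray
    A_m: np.ndarray
    I: np.ndarray
    m_a: np.ndarray
    L: float
    m: float
    m_M: float
    S: float
    shape: ShapeParams
    constants: Constants = DEFAULT_CONSTANTS
    # dense 4th-order derivative operators on this grid
    D1: np.ndarray = field(repr=False, default=None)
    D2: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def dx(self) -> float:
        return self.x[1] - self.x[0]


def _ellipse_perimeter(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Ramanujan's approximation for an ellipse with semi-axes a, b."""
    h = np.zeros_like(a)
    s = a + b
    np.divide((a - b) ** 2, s**2, out=h, where=s > 0)
    return np.pi * s * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))


def build_geometry(
    shape: ShapeParams,
    m: float,
    constants: Constants = DEFAULT_CONSTANTS,
    n: int = 256,
) -> BodyGeometry:
    """Build a mass-constrained body: solve L from m = rho (pi/4) L^3 int d~ b~ dxi.

    Neutral buoyancy (body density = water density rho) maps mass to volume;
    doubling the mass at fixed shape scales every length by 2^(1/3).
    """
    if m <= 0:
        raise ValueError("mass must be positive")
    xi = np.linspace(0.0, 1.0, n)
    d_n, b_n = shape.profiles(xi)
    vol_coeff = (np.pi / 4.0) * trapz(d_n * b_n, xi)
    L = (m / (constants.rho * vol_coeff)) ** (1.0 / 3.0)
    x = xi * L
    d = d_n * L
    b = b_n * L
    A = np.pi * d * b / 4.0
    A_m = 0.5 * constants.mu0 * A
    I = (np.pi / 64.0) * d * b**3
    m_a = constants.rho * np.pi * d**2 / 4.0
    S = trapz(_ellipse_perimeter(d / 2.0, b / 2.0), x)
    dx = x[1] - x[0]
    return BodyGeometry(
        x=x, d=d, b=b, A=A, A_m=A_m, I=I, m_a=m_a,
        L=L, m=m, m_M=0.5 * constants.mu0 * m, S=S,
        shape=shape, constants=constants,
        D1=deriv_matrix(n, dx), D2=second_deriv_matrix(n, dx),
    )


@dataclass(frozen=True)
class MotionSpec:
    """Single-harmonic undulation on a given body grid.

    H(x) = r(x) exp(i 2 pi x / lambda_b) is the complex deflection amplitude;
    the physical motion is h(x, t) = Re[H(x) exp(-i omega t)].
    """

    omega: float
    lambda_b: float
    r: np.ndarray
    H: np.ndarray
    env_coeffs: tuple

    @property
    def T(self) -> float:
        return 2.0 * np.pi / self.omega

    @property
    def h_T(self) -> float:
        """Tail-beat amplitude r(L)."""
        return float(self.r[-1])


def build_motion(
    geom: BodyGeometry,
    omega: float,
    env_coeffs,
    lambda_b: float | None = None,
) -> MotionSpec:
    """Construct the traveling-wave kinematics from omega and the Chebyshev
    envelope coefficients of r(x)/L.  lambda_b defaults to L."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    lam = geom.L if lambda_b is None else lambda_b
    xi = geom.x / geom.L
    r = geom.L * cheb.chebval(2.0 * xi - 1.0, list(env_coeffs))
    if np.any(r < -1e-12 * geom.L):
        raise InfeasibleMotionError("envelope r(x) must be non-negative")
    r = np.clip(r, 0.0, None)
    H = r * np.exp(2j * np.pi * geom.x / lam)
    return MotionSpec(omega=omega, lambda_b=lam, r=r, H=H, env_coeffs=tuple(env_coeffs))


def contraction_field(geom: BodyGeometry, motion: MotionSpec) -> np.ndarray:
    """Complex amplitude V(x) of the right-side muscle strain rate (s^-1).

    v(x, t) = (1/2) b(x) d/dt (d^2 h / dx^2) for the right side; in the
    frequency domain V = (1/2) b (-i omega) H''.  The rigid recoil adds no
    curvature, so V is the same for h and for the total deflection.
    The envelope is |V| and the relative envelope |V|/vmax.
    """
    H2 = geom.D2 @ motion.H
    return 0.5 * geom.b * (-1j * motion.omega) * H2
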