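"""Structural (Euler-Bernoulli) model: bending moment and visco-elastic losses.

The internal forces that sustain the undulation satisfy the beam balance

    rho A h^_tt + (E I h^'')'' + (nu_b I h^_t'')'' + F_L = -M'',

where M(x, t) is the bending moment supplied by the muscles and the passive
tissue carries aggregate elastic (E) and visco-elastic (nu_b) properties.
With the recoil solved, the load field has zero net force and moment, so
integrating M'' = -load twice from the snout with M(0) = M'(0) = 0
automatically closes at the free tail (M(L), M'(L) ~ 0); the closure is
checked, not imposed.  The visco-elastic dissipation is
P_V = nu_b int I <(h^_xxt)^2> dx and the internal efficiency
eta_I = 1 / (1 + P_V / P_H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grid import cumtrapz, trapz
from .body import BodyGeometry, MotionSpec
from .hydro import RecoilSolution, lateral_force_field

__all__ = ["StructuralResult", "bending_moment", "visco_power", "internal_efficiency"]


@dataclass(frozen=True)
class StructuralResult:
    """Complex bending-moment amplitude field and derived quantities.

    M : bending moment amplitude (N m); Fm : muscle-force amplitude
    -M / (0.5 b) (N), signed so that net muscle work is positive; P_V :
    mean visco-elastic dissipation (W); tail_closure : |M(L)| / max|M|.
    """

    M: np.ndarray
    Fm: np.ndarray
    P_V: float
    tail_closure: float


def bending_moment(
    geom: BodyGeometry,
    motion: MotionSpec,
    recoil: RecoilSolution,
    U: float,
    closure_tol: float = 1e-6,
) -> StructuralResult:
    """Extract the muscle bending moment M(x) from the beam balance.

    The load (inertial + elastic + visco-elastic + hydrodynamic terms) is
    double-integrated with cumulative trapezoids from the snout.  A tail
    residual |M(L)| exceeding ``closure_tol * max|M|`` signals an
    inconsistent recoil/boundary state and raises.

    The muscle force is F_m = -M / (0.5 b): the sign convention is fixed so
    that the length-integrated mean muscle power equals P_H + P_V (energy
    closure) rather than its negative.  At the ends, where the muscle strip
    width vanishes, F_m -> 0 smoothly because M vanishes quadratically.
    """
    c = geom.constants
    omega = motion.omega
    H_hat = recoil.H_hat
    H2 = geom.D2 @ H_hat
    # inertial + hydrodynamic load, integrated twice from the snout
    load_ih = (
        -(omega**2) * c.rho * geom.A * H_hat
        + lateral_force_field(geom, omega, U, H_hat)
    )
    Mp = -cumtrapz(load_ih, geom.x)
    M = cumtrapz(Mp, geom.x)
    # the elastic and visco-elastic terms integrate exactly:
    # int int (E I h'')'' = E I h'' because I and I' vanish at the snout
    # (the width taper sends I -> 0 cubically at both ends)
    M = M - (c.E + c.nu_b * (-1j * omega)) * geom.I * H2
    Mmax = float(np.max(np.abs(M)))
    closure = float(abs(M[-1]) / Mmax) if Mmax > 0 else 0.0
    if closure > closure_tol:
        raise RuntimeError(
            f"bending-moment tail closure {closure:.2e} exceeds {closure_tol:.0e}: "
            "recoil or boundary conditions inconsistent"
        )
    half_b = 0.5 * geom.b
    Fm = np.zeros_like(M)
    np.divide(-M, half_b, out=Fm, where=half_b > half_b.max() * 1e-12)
    P_V = visco_power(geom, motion, recoil)
    return StructuralResult(M=M, Fm=Fm, P_V=P_V, tail_closure=closure)


def visco_power(geom: BodyGeometry, motion: MotionSpec, recoil: RecoilSolution) -> float:
    """Mean visco-elastic dissipation P_V = nu_b int I <(h^_xxt)^2> dx >= 0.

    For the single harmonic <(h^_xxt)^2> = (1/2) omega^2 |H^''|^2; P_V scales
    as omega^2 at a fixed envelope.
    """
    H2 = geom.D2 @ recoil.H_hat
    integrand = geom.I * 0.5 * motion.omega**2 * np.abs(H2) ** 2
    return float(geom.constants.nu_b * trapz(integrand, geom.x))


def internal_efficiency(P_H: float, P_V: float) -> float:
    """eta_I = 1 / (1 + P_V / P_H): fraction of muscle output reaching the fluid."""
    if P_H <= 0:
        raise ValueError("P_H must be positive")
    if P_V < 0:
        raise ValueError("P_V must be non-negative")
    return 1.0 / (1.0 + P_V / P_H)
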