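"""Longitudinal and integral energetic measures of a swimming body.

Each cross section is a sinusoidally loaded muscle (see :mod:`undulate.hill`)
characterized by the relative force amplitude |F_m|/(F0 A_m), the relative
contraction-rate amplitude |V|/vmax, and the force-to-rate phase lag Phi(x).
Cycle averaging per section yields the longitudinal profiles p_bar(x),
q_bar(x) (W/m), eta_m(x), the activation envelope mu^(x) and the braking
regions (Phi > 90 deg).  Length integration gives the whole-body power
output P, metabolic consumption Q, the efficiencies

    eta_M = P/Q,   eta_I = 1/(1 + P_V/P_H),   eta_H = F_T U / P_H,
    eta_T = eta_H eta_M eta_I,   eta_M* = eta_M eta_I,

the per-muscle-mass powers Psi = P/m_M, Theta = Q/m_M, and the cost of
transport COT = (P_s + Q)/(m g U).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._grid import trapz
from .body import BodyGeometry, MotionSpec, contraction_field
from .constants import Constants
from .hill import FiberParams, fiber_consumption_rel, fiber_force_rel
from .hydro import HydroResult
from .structure import StructuralResult

__all__ = ["Profiles", "SwimmerReport", "longitudinal_profiles", "integral_report"]


@dataclass(frozen=True)
class Profiles:
    """Per-section cycle-averaged quantities on the body grid.

    p_bar, q_bar in W/m; eta_m dimensionless; Phi in degrees in [0, 180];
    mu_hat and vhat_r dimensionless envelopes.
    """

    x: np.ndarray
    p_bar: np.ndarray
    q_bar: np.ndarray
    eta_m: np.ndarray
    Phi: np.ndarray
    mu_hat: np.ndarray
    vhat_r: np.ndarray
    Fhat_rel: np.ndarray
    feasible: bool


@dataclass(frozen=True)
class SwimmerReport:
    """Full energetic evaluation of one swimmer at steady speed."""

    U: float
    Re: float
    branch: str
    COT: float
    P: float
    Q: float
    P_s: float
    P_H: float
    P_V: float
    F_T: float
    eta_H: float
    eta_I: float
    eta_M: float
    eta_M_star: float
    eta_T: float
    Psi: float
    Theta: float
    m: float
    m_M: float
    L: float
    feasible: bool
    mu_hat_max: float
    vhat_r_max: float
    profiles: Profiles = field(repr=False, default=None)

    def to_dict(self, include_profiles: bool = False) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "profiles"}
        if include_profiles and self.profiles is not None:
            d["profiles"] = {
                k: np.asarray(v).tolist()
                for k, v in asdict(self.profiles).items()
                if isinstance(v, np.ndarray)
            }
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(**kw), indent=2)


def longitudinal_profiles(
    geom: BodyGeometry,
    motion: MotionSpec,
    structural: StructuralResult,
    n_quad: int = 1024,
) -> Profiles:
    """Cycle-average every cross section of the body (vectorized in x and t).

    The complex fields F_m(x) and V(x) fix, per section, the amplitudes and
    the relative phase; the cycle integrals then follow the same quadrature
    as :func:`undulate.hill.cycle_metrics`.  Sections whose muscle strip
    vanishes (A_m ~ 0 at the ends) carry zero power by construction.
    """
    c = geom.constants
    params = FiberParams.from_constants(c)
    V = contraction_field(geom, motion)
    Fm = structural.Fm

    cap = c.F0 * geom.A_m  # full-activation force capacity (N)
    cap_floor = cap.max() * 1e-12
    Fhat_rel = np.zeros_like(cap)
    np.divide(np.abs(Fm), cap, out=Fhat_rel, where=cap > cap_floor)
    vhat_r = np.abs(V) / c.vmax
    # phase lag between force and contraction rate, folded to [0, 180]
    delta = np.angle(Fm * np.conj(V))
    Phi = np.degrees(np.abs(delta))

    # vectorized cycle quadrature over (t, x)
    th = (np.arange(n_quad) + 0.5) * 2.0 * np.pi / n_quad
    sin_t = np.sin(th)[:, None]
    F_t = Fhat_rel[None, :] * sin_t
    v_t = vhat_r[None, :] * np.sin(th[:, None] - np.radians(Phi)[None, :])
    va = np.sign(F_t) * v_t
    # rates at/above vmax only occur on infeasible candidates (vhat_r >= 1
    # is flagged below); clip just inside the domain so mu stays finite
    va = np.clip(va, -1.0, 1.0 - 1e-12)
    p = F_t * v_t
    mu = np.abs(F_t) / fiber_force_rel(va, params)
    q = mu * fiber_consumption_rel(va, params)

    p_bar_rel = p.mean(axis=0)
    q_bar_rel = q.mean(axis=0)
    mu_hat = mu.max(axis=0)
    eta_m = np.where(
        (p_bar_rel > 0) & (q_bar_rel > 0),
        p_bar_rel / np.where(q_bar_rel > 0, q_bar_rel, 1.0),
        0.0,
    )
    scale = c.F0 * geom.A_m * c.vmax  # W/m per relative unit
    feasible = bool(np.all(mu_hat <= 1.0) and np.all(vhat_r < 1.0))
    return Profiles(
        x=geom.x,
        p_bar=p_bar_rel * scale,
        q_bar=q_bar_rel * scale,
        eta_m=eta_m,
        Phi=Phi,
        mu_hat=mu_hat,
        vhat_r=vhat_r,
        Fhat_rel=Fhat_rel,
        feasible=feasible,
    )


def integral_report(
    geom: BodyGeometry,
    motion: MotionSpec,
    hydro: HydroResult,
    structural: StructuralResult,
    profiles: Profiles,
) -> SwimmerReport:
    """Assemble the whole-body energetic report.

    P is the signed net output (caudal braking subtracts), consistent with
    the P = P_H + P_V closure; Q integrates the always-positive consumption,
    eccentric (braking) sections included.
    """
    c = geom.constants
    if hydro.U <= 0:
        raise ValueError("steady speed must be positive")
    P = float(trapz(profiles.p_bar, geom.x))
    Q = float(trapz(profiles.q_bar, geom.x))
    if Q <= 0:
        raise RuntimeError("non-positive total consumption: internal error")
    P_s = c.standard_metabolic_rate(geom.m)
    COT = (P_s + Q) / (geom.m * c.g * hydro.U)
    eta_M = P / Q
    eta_I = 1.0 / (1.0 + structural.P_V / hydro.P_H)
    eta_T = hydro.eta_H * eta_M * eta_I
    return SwimmerReport(
        U=hydro.U,
        Re=hydro.Re,
        branch=hydro.branch,
        COT=COT,
        P=P,
        Q=Q,
        P_s=P_s,
        P_H=hydro.P_H,
        P_V=structural.P_V,
        F_T=hydro.F_T,
        eta_H=hydro.eta_H,
        eta_I=eta_I,
        eta_M=eta_M,
        eta_M_star=eta_M * eta_I,
        eta_T=eta_T,
        Psi=P / geom.m_M,
        Theta=Q / geom.m_M,
        m=geom.m,
        m_M=geom.m_M,
        L=geom.L,
        feasible=profiles.feasible,
        mu_hat_max=float(profiles.mu_hat.max()),
        vhat_r_max=float(profiles.vhat_r.max()),
        profiles=profiles,
    )
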