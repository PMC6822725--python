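"""Physical and physiological constants of the swimmer model.

All swimmers share one set of muscle, tissue and fluid properties,
characteristic of fish red (aerobic) muscle swimming in fresh water.
Only the body shape, size and motion vary between swimmers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class Constants:
    """Muscle, tissue and fluid properties shared by all model swimmers.

    Attributes
    ----------
    F0 : float
        Isometric stress of red muscle fibers (N/m^2).
    vmax : float
        Maximum fiber contraction strain rate (fiber-lengths/s, i.e. s^-1).
    G : float
        Hill force-velocity shape constant (dimensionless).
    rho_m : float
        Muscle density (kg/m^3); used to convert volumetric powers to W/kg.
    E : float
        Aggregate Young's modulus of passive tissue (N/m^2).
    nu_b : float
        Aggregate visco-elastic damping coefficient of passive tissue (m^2/s).
    mu0 : float
        Total muscle fraction of the body cross section; the one-side muscle
        section is A_m = 0.5 * mu0 * A.
    rho : float
        Water (and body, by neutral buoyancy) density (kg/m^3).
    nu : float
        Kinematic viscosity of water (m^2/s).
    Re_cr : float
        Critical Reynolds number of the laminar-turbulent drag transition.
    Ps_coeff, Ps_exp : float
        Standard metabolic rate allometry P_s = Ps_coeff * m**Ps_exp (W, kg).
    g : float
        Gravitational acceleration (m/s^2); used only to nondimensionalize
        the cost of transport.
    """

    F0: float = 150e3
    vmax: float = 5.0
    G: float = 4.0
    rho_m: float = 1000.0
    E: float = 1e5
    nu_b: float = 1e4
    mu0: float = 0.1
    rho: float = 1000.0
    nu: float = 1e-6
    Re_cr: float = 5e5
    Ps_coeff: float = 0.1327
    Ps_exp: float = 0.80
    g: float = 9.81

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValueError(f"constant {f.name!r} must be positive, got {v!r}")

    def standard_metabolic_rate(self, mass: float) -> float:
        """Speed-independent baseline metabolic power P_s (W) for mass in kg."""
        return self.Ps_coeff * mass**self.Ps_exp


DEFAULT_CONSTANTS = Constants()
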