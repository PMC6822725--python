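"""Deterministic reference swimmers.

The reference swimmer is a fusiform body (tail height 0.20 L, maximum width
0.15 L) driven by a tail-amplified envelope.  Frequency and envelope
amplitude follow a simple allometry, calibrated so that the swimmer is
physiologically feasible (activation mu <= 1, contraction rate below vmax)
at every mass decade from 1 g to 1000 t:

    omega = 8 m^(-1/3) rad/s, amplitude factor 1      for m >= 1 kg,
    omega = 8 m^(-1/4) rad/s, amplitude factor m^0.23 for m <  1 kg.

Larger swimmers beat slower (as real fish do) and the relative contraction
rate decreases with size; the smallest swimmers also reduce amplitude to
stay within the muscle force envelope.  There is no randomness: fixtures are
identical across calls.
"""

from __future__ import annotations

from .config import RunConfig, RunSettings, SwimmerSpec
from .constants import Constants

__all__ = ["generate_fixture"]

_BASE_ENV = (0.05, 0.05, 0.02)  # Chebyshev envelope of r/L before scaling


def generate_fixture(mass: float, style: str = "reference") -> RunConfig:
    """Reference swimmer configuration at the given mass (kg, in [1e-3, 1e6])."""
    if not 1e-3 <= mass <= 1e6:
        raise ValueError("fixture mass must lie in [1e-3, 1e6] kg")
    if style != "reference":
        raise ValueError(f"unknown fixture style {style!r}")
    if mass >= 1.0:
        omega = 8.0 * mass ** (-1.0 / 3.0)
        amp = 0.6
    else:
        omega = 8.0 * mass ** (-0.25)
        amp = 0.6 * mass**0.23
    e0, e1, e2 = (amp * c for c in _BASE_ENV)
    return RunConfig(
        constants=Constants(),
        swimmer=SwimmerSpec(
            mass=mass, DL=0.20, BL=0.15, c_d1=0.05, c_d2=0.02, c_b1=1.2,
            omega=omega, e0=e0, e1=e1, e2=e2,
        ),
        run=RunSettings(),
    )
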