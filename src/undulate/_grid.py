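"""Finite-difference operators and quadrature helpers on the body grid."""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["deriv_matrix", "second_deriv_matrix", "trapz", "cumtrapz"]

# 4th-order one-sided first-derivative stencils (5 points), rows for the two
# nodes nearest each boundary; interior rows use the 4th-order central stencil.
_FWD0 = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / 12.0
_FWD1 = np.array([-3.0, -10.0, 18.0, -6.0, 1.0]) / 12.0


def deriv_matrix(n: int, dx: float) -> np.ndarray:
    """Dense 4th-order first-derivative matrix on a uniform n-point grid."""
    if n < 6:
        raise ValueError("grid too small for 4th-order differences")
    D = np.zeros((n, n))
    for i in range(2, n - 2):
        D[i, i - 2 : i + 3] = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0
    D[0, :5] = _FWD0
    D[1, :5] = _FWD1
    D[-1, -5:] = -_FWD0[::-1]
    D[-2, -5:] = -_FWD1[::-1]
    return D / dx


def second_deriv_matrix(n: int, dx: float) -> np.ndarray:
    """4th-order second derivative, built as the square of the first derivative.

    Squaring keeps the discrete operators exactly compatible with the nested
    products (e.g. (E I h'')'') used by the beam balance.
    """
    D = deriv_matrix(n, dx)
    return D @ D


def trapz(y: np.ndarray, x: np.ndarray):
    return np.trapezoid(y, x)


def cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    return cumulative_trapezoid(y, x, initial=0.0)
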