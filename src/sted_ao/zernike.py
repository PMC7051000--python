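"""Zernike polynomials over the unit disk, Noll-indexed, RMS-normalized.

Normalization follows the adaptive-optics convention: each mode has unit
root-mean-square over the unit disk, so a coefficient of ``c`` radians
contributes ``c`` radians RMS of wavefront error.
"""

from __future__ import annotations

from math import factorial, sqrt

import numpy as np

__all__ = ["noll_to_nm", "zernike_nm", "zernike_noll"]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll single index ``j`` (>= 1) to (n, m).

    m carries sign: negative m denotes the sin() mode, positive the cos().
    """
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial polynomial R_n^|m|(rho)."""
    m = abs(m)
    if (n - m) % 2:
        return np.zeros_like(rho)
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_nm(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """RMS-normalized Zernike mode Z_n^m sampled at (rho, theta)."""
    if n < 0 or abs(m) > n or (n - abs(m)) % 2:
        raise ValueError(f"invalid Zernike order (n={n}, m={m})")
    r = _radial(n, m, rho)
    if m == 0:
        return sqrt(n + 1) * r
    norm = sqrt(2 * (n + 1))
    if m > 0:
        return norm * r * np.cos(m * theta)
    return norm * r * np.sin(-m * theta)


def zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-indexed Zernike mode j evaluated at (rho, theta)."""
    n, m = noll_to_nm(j)
    return zernike_nm(n, m, rho, theta)
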