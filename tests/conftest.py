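"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the package's FFT/propagation code paths:
``direct_dft_intensity`` is a literal four-nested-sum DFT, and
``dense_line_intensity`` evaluates the focal field on an arbitrary line by
direct summation over a dense pupil grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from sted_ao.optics import PupilGrid


@pytest.fixture(scope="session")
def grid32() -> PupilGrid:
    return PupilGrid(32, 1.4, 760.0)


@pytest.fixture(scope="session")
def grid64() -> PupilGrid:
    return PupilGrid(64, 1.4, 760.0)


@pytest.fixture(scope="session")
def grid128() -> PupilGrid:
    return PupilGrid(128, 1.4, 760.0)


def direct_dft_intensity(pupil: np.ndarray, n_fft: int) -> np.ndarray:
    """Brute-force DFT |sum P exp(-2pi i (uy+vx)/N)|^2, fftshift-centred."""
    n = pupil.shape[0]
    y = np.arange(n)
    out = np.zeros((n_fft, n_fft), dtype=complex)
    for u in range(n_fft):
        row_phase = np.exp(-2j * np.pi * u * y / n_fft)
        collapsed = row_phase @ pupil  # sum over rows for this u
        for v in range(n_fft):
            out[u, v] = collapsed @ np.exp(-2j * np.pi * v * y / n_fft)
    return np.abs(np.fft.fftshift(out)) ** 2


def dense_line_intensity(
    wavelength_nm: float,
    na: float,
    x_nm: np.ndarray,
    n_pupil: int = 512,
) -> np.ndarray:
    """Focal intensity along the x axis by direct summation on a dense pupil.

    The pupil is a unit disk sampled on an ``n_pupil``-point grid; spatial
    frequency spans [-NA/lambda, NA/lambda].  Independent of any FFT.
    """
    xi = np.linspace(-1, 1, n_pupil)
    fx = xi * na / wavelength_nm
    disk = np.add.outer(xi**2, xi**2) <= 1.0
    column_weight = disk.sum(axis=0).astype(float)  # collapse over eta (y=0 line)
    phases = np.exp(-2j * np.pi * np.outer(x_nm, fx))
    field = phases @ column_weight
    return np.abs(field) ** 2 / column_weight.sum() ** 2


def fwhm_of_profile(x: np.ndarray, y: np.ndarray) -> float:
    """Half-max crossing width of a single-peaked profile (linear interp)."""
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = right = None
    for j in range(i, 0, -1):
        if y[j - 1] < half:
            frac = (y[j] - half) / (y[j] - y[j - 1])
            left = x[j] - frac * (x[j] - x[j - 1])
            break
    for j in range(i, len(y) - 1):
        if y[j + 1] < half:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            right = x[j] + frac * (x[j + 1] - x[j])
            break
    if left is None or right is None:
        raise ValueError("no half-max crossings found")
    return float(right - left)
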