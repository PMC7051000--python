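"""Pupil-plane phase representations and scalar focal-field computation.

The pupil is a square grid with the aperture disk inscribed according to
``pupil_fill``; phases are stored in radians and wrapped to [0, 2*pi) when
composed or quantized to the 256 levels of an 8-bit SLM.  The focal
intensity is the squared modulus of the Fourier transform of the complex
pupil function (scalar diffraction), normalized so the unaberrated
flat-mask peak equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .zernike import zernike_noll

TWO_PI = 2.0 * np.pi
LEVELS_PER_2PI = 256

__all__ = [
    "PupilGrid",
    "PhaseMask",
    "QuantizedMask",
    "ZernikeSpec",
    "SegmentLayout",
    "IntensityPSF",
    "wrap_phase",
    "zernike_phase",
    "spiral_phase",
    "blazed_grating",
    "segment_phase",
    "quantize",
    "dequantize",
    "compose",
    "defocus_phase",
    "focal_psf",
    "focal_field_patch",
]


def wrap_phase(values: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to the half-open interval [0, 2*pi).

    ``np.mod`` can round a result up to exactly 2*pi for tiny negative
    inputs; those are folded back to 0 to keep the interval half-open (and
    wrapping idempotent).
    """
    out = np.mod(values, TWO_PI)
    return np.where(out >= TWO_PI, 0.0, out)


@dataclass(frozen=True)
class PupilGrid:
    """Discretized pupil plane.

    Parameters
    ----------
    n_pixels:
        Side of the square grid; must be even and >= 16 so the centre
        convention (pixel ``n/2``) is well defined.
    na:
        Numerical aperture of the objective.
    wavelength_nm:
        Vacuum wavelength of the beam.
    medium_index:
        Refractive index of the immersion medium.
    pupil_fill:
        Fraction of the grid diameter occupied by the aperture, in (0, 1].
    """

    n_pixels: int = 128
    na: float = 1.4
    wavelength_nm: float = 760.0
    medium_index: float = 1.518
    pupil_fill: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pixels < 16 or self.n_pixels % 2:
            raise ValueError(f"n_pixels must be even and >= 16, got {self.n_pixels}")
        if not 0 < self.na <= self.medium_index:
            raise ValueError(
                f"need 0 < na <= medium_index, got na={self.na}, "
                f"medium_index={self.medium_index}"
            )
        if not 0 < self.pupil_fill <= 1:
            raise ValueError(f"pupil_fill must be in (0, 1], got {self.pupil_fill}")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_pixels, self.n_pixels)

    @property
    def aperture_radius_px(self) -> float:
        return self.n_pixels * self.pupil_fill / 2.0

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) pixel offsets from the grid centre at (n/2, n/2)."""
        n = self.n_pixels
        idx = np.arange(n) - n // 2
        return np.meshgrid(idx, idx, indexing="ij")

    def unit_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rho, theta) polar coordinates normalized to the aperture radius."""
        y, x = self.pixel_coords()
        rho = np.hypot(y, x) / self.aperture_radius_px
        theta = np.arctan2(y, x)
        return rho, theta

    def aperture(self) -> np.ndarray:
        """Binary aperture mask: 1 strictly inside the unit pupil disk.

        Strict inequality keeps the mask point-symmetric about the centre
        on even grids (the boundary has zero measure).
        """
        rho, _ = self.unit_coords()
        return (rho < 1.0).astype(float)

    def with_wavelength(self, wavelength_nm: float) -> "PupilGrid":
        return PupilGrid(
            self.n_pixels, self.na, wavelength_nm, self.medium_index, self.pupil_fill
        )


@dataclass
class PhaseMask:
    """A 2-D phase map in radians.

    Values are stored as given (possibly outside [0, 2*pi)); ``wrapped()``
    returns the canonical representative.  Composition is addition followed
    by wrapping.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"phase mask must be square 2-D, got {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def wrapped(self) -> "PhaseMask":
        return PhaseMask(wrap_phase(self.values))

    @classmethod
    def zero(cls, grid: PupilGrid) -> "PhaseMask":
        return cls(np.zeros(grid.shape))


@dataclass
class QuantizedMask:
    """8-bit SLM representation: integer levels 0..255, 256 levels per 2*pi."""

    levels: np.ndarray
    levels_per_2pi: int = LEVELS_PER_2PI

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.levels.min(initial=0) < 0 or self.levels.max(initial=0) > 255:
            raise ValueError("quantized levels must lie in [0, 255]")


@dataclass(frozen=True)
class ZernikeSpec:
    """Noll-indexed Zernike expansion; coefficients in radians RMS."""

    coefficients: dict[int, float] = field(default_factory=dict)
    indexing: str = "noll"

    def __post_init__(self) -> None:
        if self.indexing != "noll":
            raise ValueError(f"unsupported Zernike indexing {self.indexing!r}")
        for j in self.coefficients:
            if not isinstance(j, (int, np.integer)) or j < 1:
                raise ValueError(f"invalid Noll mode index {j!r}")


@dataclass(frozen=True)
class SegmentLayout:
    """Square tiling of the SLM control region into (3n)^2 = 9*n^2 segments.

    ``control_px`` is the side of the physical control region the layout
    describes; when rendered onto a simulation grid the block edges are
    mapped proportionally (rounded), so blocks still tile exactly.
    """

    n: int = 3
    control_px: int = 1080

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")

    @property
    def segments_per_side(self) -> int:
        return 3 * self.n

    @property
    def n_segments(self) -> int:
        return 9 * self.n * self.n

    def block_edges(self, side_px: int | None = None) -> np.ndarray:
        """Pixel edges of the blocks along one axis of a ``side_px`` region."""
        side = self.control_px if side_px is None else side_px
        s = self.segments_per_side
        if side < s:
            raise ValueError(f"region of {side} px cannot hold {s} blocks per side")
        return np.rint(np.linspace(0, side, s + 1)).astype(int)

    def pixel_block(self, k: int, side_px: int | None = None) -> tuple[slice, slice]:
        """Row/column slices of segment ``k`` (row-major)."""
        s = self.segments_per_side
        if not 0 <= k < self.n_segments:
            raise ValueError(f"segment index {k} out of range [0, {self.n_segments})")
        e = self.block_edges(side_px)
        r, c = divmod(k, s)
        return slice(e[r], e[r + 1]), slice(e[c], e[c + 1])


@dataclass
class IntensityPSF:
    """Focal-plane intensity with calibrated pixel size.

    ``intensity`` is centred (DC at pixel ``N//2, N//2``) and normalized so
    the unaberrated flat-mask peak of the same grid equals 1.
    """

    intensity: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def centre(self) -> tuple[int, int]:
        return (self.intensity.shape[0] // 2, self.intensity.shape[1] // 2)

    @property
    def peak(self) -> float:
        return float(self.intensity.max())


# ---------------------------------------------------------------------------
# mask constructors
# ---------------------------------------------------------------------------


def zernike_phase(spec: ZernikeSpec, grid: PupilGrid) -> PhaseMask:
    """Sum of Zernike modes on the aperture (zero outside), unwrapped.

    A unit coefficient contributes unit RMS over the aperture (up to
    discretization error).
    """
    rho, theta = grid.unit_coords()
    ap = grid.aperture()
    values = np.zeros(grid.shape)
    for j, coeff in spec.coefficients.items():
        values += coeff * zernike_noll(int(j), rho, theta)
    return PhaseMask(values * ap)


def spiral_phase(grid: PupilGrid, charge: int = 1) -> PhaseMask:
    """Azimuthal phase ramp (vortex): wrap(charge * theta) about the centre."""
    if charge == 0:
        raise ValueError("charge must be nonzero; use a zero mask explicitly")
    _, theta = grid.unit_coords()
    return PhaseMask(wrap_phase(charge * theta))


def blazed_grating(
    grid: PupilGrid, period_px: float, direction: tuple[float, float] = (1.0, 0.0)
) -> PhaseMask:
    """Linear phase ramp wrap(2*pi * (r . direction) / period_px).

    ``direction`` is (dx, dy) in pixel axes and is normalized internally.
    """
    if period_px < 2:
        raise ValueError(f"period_px must be >= 2 (Nyquist), got {period_px}")
    dx, dy = direction
    norm = np.hypot(dx, dy)
    if norm == 0:
        raise ValueError("direction must be a nonzero vector")
    y, x = grid.pixel_coords()
    ramp = TWO_PI * (x * dx / norm + y * dy / norm) / period_px
    return PhaseMask(wrap_phase(ramp))


def segment_phase(
    levels: np.ndarray, layout: SegmentLayout, grid: PupilGrid
) -> PhaseMask:
    """Piecewise-constant mask: level L in [0,255] maps to phase 2*pi*L/256."""
    levels = np.asarray(levels)
    if levels.size != layout.n_segments:
        raise ValueError(
            f"expected {layout.n_segments} levels for layout n={layout.n}, "
            f"got {levels.size}"
        )
    if levels.min() < 0 or levels.max() > 255:
        raise ValueError("segment levels must lie in [0, 255]")
    s = layout.segments_per_side
    edges = layout.block_edges(grid.n_pixels)
    phase_block = TWO_PI * levels.reshape(s, s).astype(float) / LEVELS_PER_2PI
    counts = np.diff(edges)
    values = np.repeat(np.repeat(phase_block, counts, axis=0), counts, axis=1)
    return PhaseMask(values)


def quantize(mask: PhaseMask) -> QuantizedMask:
    """Phase -> 8-bit level: floor(wrap(phase)/(2*pi) * 256) mod 256.

    A guard of 1e-9 level keeps exactly representable phases (level*2*pi/256)
    from falling one level short through floating-point rounding.
    """
    scaled = wrap_phase(mask.values) / TWO_PI * LEVELS_PER_2PI
    levels = np.floor(scaled + 1e-9).astype(int)
    return QuantizedMask(np.mod(levels, LEVELS_PER_2PI).astype(np.uint8))


def dequantize(q: QuantizedMask) -> PhaseMask:
    """Level -> phase 2*pi*level/256."""
    return PhaseMask(q.levels.astype(float) * TWO_PI / q.levels_per_2pi)


def compose(masks: list[PhaseMask]) -> PhaseMask:
    """Wrapped pixelwise sum of phase masks (order-independent)."""
    if not masks:
        raise ValueError("compose needs at least one mask")
    shape = masks[0].shape
    total = np.zeros(shape)
    for m in masks:
        if m.shape != shape:
            raise ValueError(f"shape mismatch in compose: {m.shape} vs {shape}")
        total = total + m.values
    return PhaseMask(wrap_phase(total))


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def defocus_phase(grid: PupilGrid, defocus_um: float) -> np.ndarray:
    """Spherical-cap pupil phase for an axial offset z in the medium.

    phi(rho) = (2*pi/lambda) * z * sqrt(n_med^2 - NA^2 rho^2); odd in z, so
    the +z and -z phases are exact negatives.  Reduces to the paraxial
    quadratic at low NA.
    """
    rho, _ = grid.unit_coords()
    ap = grid.aperture()
    z_nm = defocus_um * 1e3
    arg = np.clip(grid.medium_index**2 - (grid.na * rho) ** 2, 0.0, None)
    return TWO_PI / grid.wavelength_nm * z_nm * np.sqrt(arg) * ap


def focal_pixel_size_nm(grid: PupilGrid, oversample: int) -> float:
    """Focal-plane sampling of the padded FFT in nanometres."""
    n_fft = grid.n_pixels * oversample
    return grid.aperture_radius_px * grid.wavelength_nm / (n_fft * grid.na)


def _pupil_field(grid: PupilGrid, mask: PhaseMask, defocus_um: float) -> np.ndarray:
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    phase = mask.values + defocus_phase(grid, defocus_um)
    if not np.all(np.isfinite(phase)):
        raise ValueError("phase mask contains non-finite values")
    return grid.aperture() * np.exp(1j * phase)


def _flat_peak(grid: PupilGrid) -> float:
    # DC value of the flat-mask focal field is the aperture pixel count
    return float(grid.aperture().sum()) ** 2


def focal_psf(
    grid: PupilGrid,
    mask: PhaseMask | None = None,
    defocus_um: float = 0.0,
    oversample: int = 4,
) -> IntensityPSF:
    """Scalar focal-plane intensity |FT{A exp(i phi)}|^2, flat-peak normalized.

    The pupil is zero-padded by ``oversample`` (>= 2 to prevent aliasing of
    the intensity); the result is centred with ``fftshift``.
    """
    if oversample < 2:
        raise ValueError(f"oversample must be >= 2, got {oversample}")
    if mask is None:
        mask = PhaseMask.zero(grid)
    pupil = _pupil_field(grid, mask, defocus_um)
    n_fft = grid.n_pixels * oversample
    padded = np.zeros((n_fft, n_fft), dtype=complex)
    padded[: grid.n_pixels, : grid.n_pixels] = pupil
    field = np.fft.fftshift(np.fft.fft2(padded))
    intensity = np.abs(field) ** 2 / _flat_peak(grid)
    return IntensityPSF(intensity, focal_pixel_size_nm(grid, oversample))


def focal_field_patch(
    grid: PupilGrid,
    mask: PhaseMask,
    rows: np.ndarray,
    cols: np.ndarray,
    oversample: int = 2,
    defocus_um: float = 0.0,
) -> np.ndarray:
    """Complex focal field at selected output pixels of the padded FFT.

    ``rows``/``cols`` are indices into the fftshifted ``n_pixels*oversample``
    output grid; values equal the corresponding entries of the full FFT in
    :func:`focal_psf` exactly (same DFT, evaluated by matrix products).
    Intended for fast fitness evaluation over a small pinhole window.
    """
    pupil = _pupil_field(grid, mask, defocus_um)
    n_fft = grid.n_pixels * oversample
    # fftshifted index r corresponds to DFT frequency (r - n_fft//2) mod n_fft
    u = (np.asarray(rows) - n_fft // 2) % n_fft
    v = (np.asarray(cols) - n_fft // 2) % n_fft
    y = np.arange(grid.n_pixels)
    wr = np.exp(-2j * np.pi * np.outer(u, y) / n_fft)
    wc = np.exp(-2j * np.pi * np.outer(y, v) / n_fft)
    return wr @ pupil @ wc
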