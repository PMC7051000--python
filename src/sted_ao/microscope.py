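"""Microscope observables built on the pupil physics.

The guide-star signal — the genetic algorithm's fitness — models the
back-scattered light of a sub-resolution gold particle: the focal intensity
of the (Gaussian) depletion beam integrated over a pinhole at the particle
position, normalized so the unaberrated system scores 1.  Aberration
screens are applied inside the propagation and are never readable by the
optimizer (black-box constraint).

The always-on blazed-grating carrier of the physical system is selected by
a pinhole in the first diffraction order, which amounts to an ideal
pass-through; fitness functions therefore accept and ignore an optional
``carrier`` mask, making the signal invariant to piston and to the grating
tilt by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve

from .optics import (
    IntensityPSF,
    PhaseMask,
    PupilGrid,
    compose,
    focal_field_patch,
    focal_pixel_size_nm,
    focal_psf,
)

__all__ = [
    "AberrationScreen",
    "GuideStar",
    "DepletionParams",
    "ImageStack",
    "airy_radius_px",
    "guide_star_signal",
    "GuideStarFitness",
    "effective_sted_psf",
    "resample_psf",
    "scan_image",
    "axial_stack",
]


@dataclass
class AberrationScreen:
    """A hidden pupil-plane phase distortion (system, sample or artificial)."""

    phase: PhaseMask
    source: str = "system"
    description: str = ""

    _SOURCES = ("system", "sample", "artificial_defocus")

    def __post_init__(self) -> None:
        if self.source not in self._SOURCES:
            raise ValueError(f"source must be one of {self._SOURCES}, got {self.source!r}")

    @classmethod
    def none(cls, grid: PupilGrid) -> "AberrationScreen":
        return cls(PhaseMask.zero(grid), "system", "no aberration")


@dataclass(frozen=True)
class GuideStar:
    """Point scatterer used as correction feedback.

    ``position_px`` is the lateral offset (row, col) of the scatterer from
    the scan centre, in focal pixels of the fitness computation;
    ``pinhole_radius_px`` the radius over which intensity is integrated.
    """

    position_px: tuple[float, float] = (0.0, 0.0)
    pinhole_radius_px: float = 2.0

    def __post_init__(self) -> None:
        if self.pinhole_radius_px < 0:
            raise ValueError("pinhole_radius_px must be >= 0")


@dataclass
class DepletionParams:
    """Saturation factor zeta = peak depletion intensity / saturation intensity.

    ``peak_reference`` fixes the intensity scale that "peak depletion
    intensity" refers to.  ``None`` (default) normalizes each depletion PSF
    to its own maximum; passing the ring peak of the *unaberrated* donut
    instead makes zeta track the constant laser power, so an aberrated
    donut is correctly weaker — the physically consistent choice when
    comparing corrected and uncorrected imaging.
    """

    saturation_factor: float
    depletion_mask: PhaseMask | None = None
    peak_reference: float | None = None

    def __post_init__(self) -> None:
        if self.saturation_factor < 0:
            raise ValueError("saturation_factor must be >= 0")
        if self.peak_reference is not None and self.peak_reference <= 0:
            raise ValueError("peak_reference must be positive")


@dataclass
class ImageStack:
    """Scanned image(s) with physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = "confocal"

    _CHANNELS = ("confocal", "sted", "scatter")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.channel not in self._CHANNELS:
            raise ValueError(f"channel must be one of {self._CHANNELS}")
        if self.pixels.min(initial=0.0) < 0:
            raise ValueError("image intensities must be nonnegative")


def airy_radius_px(grid: PupilGrid, oversample: int) -> float:
    """First Airy minimum 0.61*lambda/NA expressed in focal pixels."""
    return 0.61 * grid.wavelength_nm / grid.na / focal_pixel_size_nm(grid, oversample)


class GuideStarFitness:
    """Callable fitness: pinhole-integrated focal intensity at the guide star.

    Precomputes the pinhole window and the flat-mask reference so repeated
    evaluations (the GA inner loop) cost two small matrix products.  The
    returned value is positive and normalized to the unaberrated ceiling
    of 1 (the physical PMT voltage is negative; its absolute value grows
    with signal, so maximizing this scalar is equivalent).
    """

    def __init__(
        self,
        grid: PupilGrid,
        screen: AberrationScreen,
        star: GuideStar | None = None,
        oversample: int = 2,
        noise_sd: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        if star is None:
            star = GuideStar(pinhole_radius_px=airy_radius_px(grid, oversample))
        if screen.phase.shape != grid.shape:
            raise ValueError("screen shape does not match grid")
        self.grid = grid
        self.screen = screen
        self.star = star
        self.oversample = oversample
        self.noise_sd = noise_sd
        self.rng = rng if rng is not None else np.random.default_rng()

        n_fft = grid.n_pixels * oversample
        r0 = n_fft // 2 + star.position_px[0]
        c0 = n_fft // 2 + star.position_px[1]
        half = int(ceil(star.pinhole_radius_px)) + 1
        rows = np.arange(int(round(r0)) - half, int(round(r0)) + half + 1)
        cols = np.arange(int(round(c0)) - half, int(round(c0)) + half + 1)
        if rows[0] < 0 or cols[0] < 0 or rows[-1] >= n_fft or cols[-1] >= n_fft:
            raise ValueError("guide star pinhole extends outside the simulated field")
        self._rows, self._cols = rows, cols
        rr, cc = np.meshgrid(rows - r0, cols - c0, indexing="ij")
        self._pinhole = (np.hypot(rr, cc) <= star.pinhole_radius_px).astype(float)

        # precomputed fast path: aperture * exp(i*screen) and the two DFT
        # factor matrices, so each evaluation is one exp and two matmuls
        aperture = grid.aperture()
        self._norm = float(aperture.sum()) ** 2
        self._screen_values = screen.phase.values
        self._pupil_static = aperture * np.exp(1j * self._screen_values)
        self._pupil_flat = aperture.astype(complex)
        y = np.arange(grid.n_pixels)
        u = (rows - n_fft // 2) % n_fft
        v = (cols - n_fft // 2) % n_fft
        self._wr = np.exp(-2j * np.pi * np.outer(u, y) / n_fft)
        self._wc = np.exp(-2j * np.pi * np.outer(y, v) / n_fft)

        flat = self._integrate(np.zeros(grid.shape), include_screen=False)
        if flat <= 0:
            raise ValueError("degenerate pinhole: zero reference signal")
        self._flat_reference = flat

    def _integrate(self, phase_values: np.ndarray, include_screen: bool = True) -> float:
        static = self._pupil_static if include_screen else self._pupil_flat
        pupil = static * np.exp(1j * phase_values)
        field = self._wr @ pupil @ self._wc
        intensity = np.abs(field) ** 2 / self._norm
        return float((intensity * self._pinhole).sum())

    @property
    def ceiling(self) -> float:
        """Normalized fitness of the unaberrated, uncorrected system (= 1)."""
        return 1.0

    def from_phase(self, correction_values: np.ndarray, noise_free: bool = False) -> float:
        value = self._integrate(correction_values) / self._flat_reference
        if self.noise_sd > 0 and not noise_free:
            value += float(self.rng.normal(0.0, self.noise_sd))
        return value

    def __call__(self, correction: PhaseMask, carrier: PhaseMask | None = None) -> float:
        # carrier (blazed grating) is selected out by the first-order pinhole
        del carrier
        return self.from_phase(correction.values)


def guide_star_signal(
    correction: PhaseMask,
    screen: AberrationScreen,
    grid: PupilGrid,
    star: GuideStar | None = None,
    noise_sd: float = 0.0,
    rng_seed: int | None = None,
    oversample: int = 2,
    carrier: PhaseMask | None = None,
) -> float:
    """One-shot guide-star fitness; see :class:`GuideStarFitness`."""
    rng = np.random.default_rng(rng_seed)
    fit = GuideStarFitness(grid, screen, star, oversample, noise_sd, rng)
    return fit(correction, carrier=carrier)


def effective_sted_psf(
    exc: IntensityPSF, dep: IntensityPSF, params: DepletionParams
) -> IntensityPSF:
    """Saturated-depletion effective PSF: h_exc * exp(-ln2 * zeta * h_dep).

    The depletion PSF is normalized to peak 1 before scaling by the
    saturation factor, so zeta = 1 halves emission where depletion peaks.
    """
    if exc.shape != dep.shape:
        raise ValueError(f"shape mismatch: exc {exc.shape} vs dep {dep.shape}")
    if not np.isclose(exc.pixel_size_nm, dep.pixel_size_nm, rtol=1e-6):
        raise ValueError("excitation and depletion PSFs must share a pixel size")
    zeta = params.saturation_factor
    ref = params.peak_reference
    if ref is None:
        ref = dep.peak if dep.peak > 0 else 1.0
    dep_norm = dep.intensity / ref
    h_eff = exc.intensity * np.exp(-np.log(2.0) * zeta * dep_norm)
    return IntensityPSF(h_eff, exc.pixel_size_nm)


def resample_psf(
    psf: IntensityPSF, pixel_size_nm: float, out_shape: tuple[int, int] | None = None
) -> IntensityPSF:
    """Bilinear resampling about the PSF centre onto a new pixel pitch."""
    if out_shape is None:
        out_shape = psf.shape
    scale = pixel_size_nm / psf.pixel_size_nm
    rc, cc = psf.centre
    rows = (np.arange(out_shape[0]) - out_shape[0] // 2) * scale + rc
    cols = (np.arange(out_shape[1]) - out_shape[1] // 2) * scale + cc
    rr, cc_ = np.meshgrid(rows, cols, indexing="ij")
    out = map_coordinates(psf.intensity, [rr, cc_], order=1, mode="constant")
    return IntensityPSF(np.clip(out, 0.0, None), pixel_size_nm)


def _deposit_emitters(
    positions_nm: np.ndarray,
    brightness: np.ndarray,
    field_size_nm: float,
    pixel_size_nm: float,
) -> np.ndarray:
    """Bilinear splat of point emitters onto the scan raster."""
    n_px = int(round(field_size_nm / pixel_size_nm))
    img = np.zeros((n_px, n_px))
    for (x, y), b in zip(positions_nm, brightness):
        if not (0 <= x <= field_size_nm and 0 <= y <= field_size_nm):
            raise ValueError(f"emitter at ({x}, {y}) nm lies outside the field")
        c, r = x / pixel_size_nm, y / pixel_size_nm
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        fr, fc = r - r0, c - c0
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < n_px and 0 <= cc < n_px:
                img[rr, cc] += b * w
    return img


def scan_image(
    phantom,
    psf: IntensityPSF,
    pixel_size_nm: float,
    photon_scale: float = 1.0,
    rng_seed: int | None = None,
    noise: str = "none",
    channel: str = "confocal",
) -> ImageStack:
    """Simulated scanned image: emitter impulses convolved with the PSF.

    ``phantom`` provides ``positions_nm`` (N x 2), ``brightness`` (N,) and
    ``field_size_nm``.  The PSF is resampled to the scan pixel size first.
    """
    if noise not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise!r}")
    impulses = _deposit_emitters(
        np.asarray(phantom.positions_nm, dtype=float).reshape(-1, 2),
        np.asarray(phantom.brightness, dtype=float).ravel(),
        phantom.field_size_nm,
        pixel_size_nm,
    )
    kernel = psf.intensity
    if not np.isclose(psf.pixel_size_nm, pixel_size_nm, rtol=1e-6):
        kernel = resample_psf(psf, pixel_size_nm).intensity
    # odd kernel keeps the convolution centred (centre pixel at n//2)
    if kernel.shape[0] % 2 == 0:
        kernel = kernel[1:, :]
    if kernel.shape[1] % 2 == 0:
        kernel = kernel[:, 1:]
    img = fftconvolve(impulses, kernel, mode="same") * photon_scale
    img = np.clip(img, 0.0, None)
    if noise == "poisson":
        img = np.random.default_rng(rng_seed).poisson(img).astype(float)
    return ImageStack(img, pixel_size_nm, channel)


def axial_stack(
    grid: PupilGrid,
    mask: PhaseMask,
    z_range_um: float | tuple[float, float],
    n_planes: int,
    oversample: int = 4,
) -> ImageStack:
    """Stack of focal PSFs at evenly spaced defocus values (for XZ views)."""
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if np.isscalar(z_range_um):
        z0, z1 = -float(z_range_um), float(z_range_um)
    else:
        z0, z1 = z_range_um
    zs = np.linspace(z0, z1, n_planes) if n_planes > 1 else np.array([z0])
    planes = [focal_psf(grid, mask, defocus_um=z, oversample=oversample) for z in zs]
    return ImageStack(
        np.stack([p.intensity for p in planes]), planes[0].pixel_size_nm, "scatter"
    )
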