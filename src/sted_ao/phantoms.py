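"""Synthetic stand-ins for lab-provided inputs, plus image-quality metrics.

Aberration screens replace the physical system optics and thick samples;
bead fields and filament networks replace fluorescent microspheres and
labeled tubulin.  Metrics mirror how images are judged: Gaussian-fit FWHM
of a line profile, donut null depth, and whole-frame mean intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from .microscope import AberrationScreen, ImageStack
from .optics import IntensityPSF, PhaseMask, PupilGrid, ZernikeSpec, defocus_phase, zernike_phase

__all__ = [
    "ScreenRecipe",
    "Phantom",
    "make_screen",
    "make_bead_field",
    "make_filaments",
    "metric_fwhm",
    "psf_fwhm_nm",
    "metric_null_depth",
    "ring_uniformity",
    "metric_mean_intensity",
]

SCREEN_KINDS = ("zernike_random", "defocus", "spherical", "turbulence")


@dataclass(frozen=True)
class ScreenRecipe:
    """Seeded description of an aberration screen.

    ``total_rms_rad`` is the realized RMS over the aperture for the random
    kinds (enforced by rescaling); the ``defocus`` kind is parameterized by
    ``defocus_um`` instead and its RMS follows from the optics.
    """

    kind: str = "zernike_random"
    total_rms_rad: float = 1.0
    mode_range: tuple[int, int] = (4, 11)
    power_law_exponent: float = -11.0 / 3.0
    rng_seed: int = 0
    defocus_um: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SCREEN_KINDS:
            raise ValueError(f"kind must be one of {SCREEN_KINDS}, got {self.kind!r}")
        if self.total_rms_rad < 0:
            raise ValueError("total_rms_rad must be >= 0")
        if self.mode_range[0] > self.mode_range[1] or self.mode_range[0] < 2:
            raise ValueError(f"empty or invalid mode range {self.mode_range}")


def aperture_rms(values: np.ndarray, grid: PupilGrid, remove_piston: bool = True) -> float:
    """RMS of a phase map over the aperture (piston removed by default)."""
    ap = grid.aperture().astype(bool)
    v = values[ap]
    if remove_piston:
        v = v - v.mean()
    return float(np.sqrt(np.mean(v**2)))


def make_screen(recipe: ScreenRecipe, grid: PupilGrid) -> AberrationScreen:
    """Deterministic aberration screen from a seeded recipe."""
    rng = np.random.default_rng(recipe.rng_seed)
    if recipe.kind == "defocus":
        values = defocus_phase(grid, recipe.defocus_um)
        return AberrationScreen(
            PhaseMask(values),
            "artificial_defocus",
            f"defocus z={recipe.defocus_um} um",
        )
    if recipe.kind == "spherical":
        values = zernike_phase(ZernikeSpec({11: recipe.total_rms_rad}), grid).values
        return AberrationScreen(PhaseMask(values), "system", "primary spherical")
    if recipe.kind == "zernike_random":
        j0, j1 = recipe.mode_range
        modes = list(range(j0, j1 + 1))
        coeffs = rng.normal(0.0, 1.0, size=len(modes)) / np.asarray(modes)
        values = zernike_phase(ZernikeSpec(dict(zip(modes, coeffs))), grid).values
    else:  # turbulence
        n = grid.n_pixels
        f = np.fft.fftfreq(n)
        fr = np.hypot(*np.meshgrid(f, f, indexing="ij"))
        amp = np.zeros_like(fr)
        nonzero = fr > 0
        amp[nonzero] = fr[nonzero] ** (recipe.power_law_exponent / 2.0)
        spectrum = amp * np.exp(2j * np.pi * rng.random((n, n)))
        values = np.real(np.fft.ifft2(spectrum)) * grid.aperture()
    if recipe.total_rms_rad > 0:
        rms = aperture_rms(values, grid)
        if rms == 0:
            raise ValueError("degenerate screen: zero RMS before scaling")
        values = values * (recipe.total_rms_rad / rms)
    else:
        values = np.zeros(grid.shape)
    ap = grid.aperture().astype(bool)
    values = values - values[ap].mean()
    return AberrationScreen(
        PhaseMask(values * grid.aperture()),
        "sample",
        f"{recipe.kind} screen, {recipe.total_rms_rad} rad RMS, seed {recipe.rng_seed}",
    )


@dataclass
class Phantom:
    """A field of point emitters: positions in nm, positive brightness."""

    positions_nm: np.ndarray
    brightness: np.ndarray
    field_size_nm: float
    kind: str = "bead_field"

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float).reshape(-1, 2)
        self.brightness = np.asarray(self.brightness, dtype=float).ravel()
        if self.positions_nm.shape[0] != self.brightness.size:
            raise ValueError("positions and brightness lengths differ")
        if np.any(self.brightness <= 0):
            raise ValueError("brightness must be positive")
        if self.positions_nm.size and (
            self.positions_nm.min() < 0 or self.positions_nm.max() > self.field_size_nm
        ):
            raise ValueError("emitter positions must lie inside the field")

    @property
    def n_emitters(self) -> int:
        return self.brightness.size

    def to_csv(self, path) -> None:
        rows = np.column_stack([self.positions_nm, self.brightness])
        np.savetxt(
            path, rows, delimiter=",", header="x_nm,y_nm,brightness", comments=""
        )


def make_bead_field(
    n_beads: int,
    min_separation_nm: float,
    field_size_nm: float,
    rng_seed: int = 0,
    margin_nm: float | None = None,
    pair_separation_nm: float | None = None,
) -> Phantom:
    """Random bead field with enforced minimum pairwise separation.

    Dart-throwing placement with bounded retries; optionally adds one
    sub-diffraction "close pair" at the field centre (counted within
    ``n_beads``) so resolvability can be probed.
    """
    rng = np.random.default_rng(rng_seed)
    if margin_nm is None:
        margin_nm = 0.1 * field_size_nm
    pts: list[np.ndarray] = []
    if pair_separation_nm is not None and n_beads >= 2:
        c = field_size_nm / 2.0
        half = pair_separation_nm / 2.0
        pts.append(np.array([c - half, c]))
        pts.append(np.array([c + half, c]))
    attempts = 0
    max_attempts = 10_000 * max(n_beads, 1)
    while len(pts) < n_beads:
        cand = margin_nm + rng.random(2) * (field_size_nm - 2 * margin_nm)
        # the deliberate close pair is exempt from the separation rule with
        # respect to each other; every other bead keeps clear of everything
        if all(np.hypot(*(cand - p)) >= min_separation_nm for p in pts):
            pts.append(cand)
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_beads} beads with separation "
                f"{min_separation_nm} nm in a {field_size_nm} nm field"
            )
    positions = np.array(pts) if pts else np.empty((0, 2))
    return Phantom(positions, np.ones(len(pts)), field_size_nm, "bead_field")


def make_filaments(
    n_filaments: int,
    persistence_nm: float,
    width_nm: float,
    field_size_nm: float,
    rng_seed: int = 0,
    step_nm: float = 25.0,
) -> Phantom:
    """Smooth random-walk polylines densely sampled into point emitters.

    The tangent angle diffuses with variance step/persistence per step, so
    persistence -> infinity gives straight filaments.  Emitters get a
    transverse Gaussian jitter of sigma = width/2 to mimic finite width.
    """
    if width_nm < 0:
        raise ValueError("width_nm must be >= 0")
    rng = np.random.default_rng(rng_seed)
    pts: list[np.ndarray] = []
    n_steps = int(2 * field_size_nm / step_nm)
    for _ in range(n_filaments):
        pos = 0.1 * field_size_nm + rng.random(2) * 0.8 * field_size_nm
        angle = rng.random() * 2 * np.pi
        sd = np.sqrt(step_nm / persistence_nm) if np.isfinite(persistence_nm) else 0.0
        for _ in range(n_steps):
            angle += rng.normal(0.0, sd)
            pos = pos + step_nm * np.array([np.cos(angle), np.sin(angle)])
            if not (0 <= pos[0] <= field_size_nm and 0 <= pos[1] <= field_size_nm):
                break
            p = pos
            if width_nm > 0:
                normal = np.array([-np.sin(angle), np.cos(angle)])
                p = pos + rng.normal(0.0, width_nm / 2.0) * normal
                p = np.clip(p, 0.0, field_size_nm)
            pts.append(p.copy())
    positions = np.array(pts) if pts else np.empty((0, 2))
    return Phantom(positions, np.ones(len(pts)), field_size_nm, "filaments")


def _gaussian(t, amplitude, centre, sigma, offset):
    return amplitude * np.exp(-((t - centre) ** 2) / (2.0 * sigma**2)) + offset


@dataclass
class FWHMFit:
    fwhm_nm: float
    sigma_nm: float
    centre_nm: float
    residual_rms: float


def metric_fwhm(
    image: ImageStack | np.ndarray,
    line: tuple[tuple[float, float], tuple[float, float]],
    pixel_size_nm: float | None = None,
    n_samples: int = 200,
    full_output: bool = False,
):
    """Gaussian-fit FWHM (nm) of the bilinear profile along a pixel-space line.

    ``line`` is ((row0, col0), (row1, col1)) in pixels.  Raises if the
    profile is flat (no peak to fit).
    """
    if isinstance(image, ImageStack):
        pixels, px = image.pixels, image.pixel_size_nm
    else:
        pixels = np.asarray(image, dtype=float)
        if pixel_size_nm is None:
            raise ValueError("pixel_size_nm required for raw arrays")
        px = pixel_size_nm
    (r0, c0), (r1, c1) = line
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= pixels.shape[0] - 1 and 0 <= c <= pixels.shape[1] - 1):
            raise ValueError("profile line extends outside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = r0 + (r1 - r0) * t
    cols = c0 + (c1 - c0) * t
    profile = map_coordinates(pixels, [rows, cols], order=1)
    length_nm = np.hypot(r1 - r0, c1 - c0) * px
    t_nm = t * length_nm

    span = profile.max() - profile.min()
    if span <= 0 or not np.isfinite(span):
        raise ValueError("no peak: flat intensity profile")
    p0 = (span, t_nm[int(np.argmax(profile))], length_nm / 8.0, profile.min())
    bounds = ([0.0, 0.0, 1e-3, -np.inf], [np.inf, length_nm, length_nm, np.inf])
    try:
        popt, _ = curve_fit(_gaussian, t_nm, profile, p0=p0, bounds=bounds, maxfev=5000)
    except RuntimeError as exc:  # pragma: no cover - pathological profiles
        raise ValueError(f"no peak: Gaussian fit failed ({exc})") from exc
    sigma = abs(popt[2])
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    residual = float(np.sqrt(np.mean((profile - _gaussian(t_nm, *popt)) ** 2)))
    if full_output:
        return FWHMFit(fwhm, sigma, float(popt[1]), residual)
    return float(fwhm)


def psf_fwhm_nm(psf: IntensityPSF, axis: str = "row") -> float:
    """FWHM of a PSF through its centre, by interpolated half-max crossings.

    Unlike :func:`metric_fwhm` this uses the literal definition (linear
    interpolation of the two half-maximum crossings of the central lobe),
    which is unbiased for non-Gaussian profiles such as the Airy pattern.
    """
    rc, cc = psf.centre
    profile = psf.intensity[rc, :] if axis == "row" else psf.intensity[:, cc]
    centre = cc if axis == "row" else rc
    half = profile[centre] / 2.0
    if profile[centre] < profile.max() * 0.5:
        raise ValueError("centre is not the dominant peak; use metric_fwhm")

    def crossing(direction: int) -> float:
        i = centre
        while 0 < i < profile.size - 1 and profile[i + direction] >= half:
            i += direction
        j = i + direction
        if not 0 <= j < profile.size:
            raise ValueError("half-maximum crossing outside the field")
        frac = (profile[i] - half) / (profile[i] - profile[j])
        return i + direction * frac

    return float((crossing(+1) - crossing(-1)) * psf.pixel_size_nm)


def metric_null_depth(psf: IntensityPSF) -> float:
    """Donut quality: centre intensity / ring (global) maximum."""
    centre = psf.intensity[psf.centre]
    peak = psf.peak
    if peak <= 0:
        raise ValueError("empty PSF")
    return float(centre / peak)


def ring_uniformity(psf: IntensityPSF, n_azimuth: int = 360) -> float:
    """Max/min intensity around the donut crest circle (1 = perfectly even)."""
    rc, cc = psf.centre
    peak_r, peak_c = np.unravel_index(np.argmax(psf.intensity), psf.shape)
    radius = np.hypot(peak_r - rc, peak_c - cc)
    if radius < 1:
        raise ValueError("PSF peak is at the centre; not a donut")
    ang = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    rows = rc + radius * np.sin(ang)
    cols = cc + radius * np.cos(ang)
    ring = map_coordinates(psf.intensity, [rows, cols], order=1)
    if ring.min() <= 0:
        return np.inf
    return float(ring.max() / ring.min())


def metric_mean_intensity(image: ImageStack | np.ndarray) -> float:
    """Arithmetic mean over all pixels (whole-frame statistic)."""
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image)
    if pixels.size == 0:
        raise ValueError("empty image")
    return float(pixels.mean())
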