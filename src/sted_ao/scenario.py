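"""End-to-end experiment orchestration.

A :class:`Scenario` is a fully declarative, YAML-serializable description
of one correction experiment: optical system, hidden aberration screen,
guide star, GA settings, depletion strengths, and phantom.  A single
master seed deterministically derives independent sub-streams for the
screen, the GA, the fitness noise and the phantom, so changing one stage's
draw count cannot shift another's.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .ga import (
    GAConfig,
    GenomeDecoder,
    GenomeSpec,
    run_ga,
)
from .io import save_mask_image, save_tiff, save_trace_csv
from .microscope import (
    DepletionParams,
    GuideStar,
    GuideStarFitness,
    effective_sted_psf,
    resample_psf,
    scan_image,
)
from .optics import (
    PhaseMask,
    PupilGrid,
    SegmentLayout,
    blazed_grating,
    compose,
    focal_psf,
    spiral_phase,
)
from .phantoms import (
    Phantom,
    ScreenRecipe,
    make_bead_field,
    make_filaments,
    make_screen,
    metric_fwhm,
    metric_mean_intensity,
    metric_null_depth,
    psf_fwhm_nm,
    ring_uniformity,
)

__all__ = ["Scenario", "ConfigError", "validate_config", "run_scenario", "demo_scenario"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridConfig(_Model):
    n_pixels: int = 128
    na: float = 1.4
    wavelength_exc_nm: float = 635.0
    wavelength_dep_nm: float = 760.0
    medium_index: float = 1.518
    pupil_fill: float = 1.0


class ScreenConfig(_Model):
    kind: str = "zernike_random"
    total_rms_rad: float = Field(1.5, ge=0)
    mode_lo: int = 4
    mode_hi: int = 11
    defocus_um: float = 0.0


class GuideStarConfig(_Model):
    position_px: tuple[float, float] = (0.0, 0.0)
    pinhole_radius_px: float | None = Field(None, ge=0)  # None -> 1 Airy radius
    noise_sd: float = Field(0.0, ge=0)


class GASection(_Model):
    mode: str = "zernike"
    segment_n: int = Field(3, ge=1)
    zernike_mode_lo: int = 4
    zernike_mode_hi: int = 15
    population_size: int = 30
    n_generations: int = 300
    n_parents: int = 15
    mutation_rate_initial: float = 0.1
    mutation_rate_final: float = 0.013
    mutation_decay: float = 60.0
    mutation_scale: float = 0.5
    mutation_scale_final: float | None = 0.05
    elitism: int = 2
    stop_patience: int = 30
    init_coeff_sd: float = 0.5


class PhantomConfig(_Model):
    kind: str = "bead_field"
    n_beads: int = 12
    min_separation_nm: float = 600.0
    pair_separation_nm: float | None = None
    n_filaments: int = 4
    persistence_nm: float = 4000.0
    width_nm: float = 40.0
    field_size_nm: float = 4000.0
    pixel_size_nm: float = 30.0


class Scenario(_Model):
    """Complete declarative description of one correction experiment."""

    grid: GridConfig = GridConfig()
    screen: ScreenConfig = ScreenConfig()
    guide_star: GuideStarConfig = GuideStarConfig()
    ga: GASection = GASection()
    zeta_list: list[float] = [16.0]
    phantom: PhantomConfig = PhantomConfig()
    blazed_period_px: float = 8.0
    psf_oversample: int = 8
    master_seed: int = 0
    out_dir: str = "sted_ao_out"

    # ---- derived helpers -------------------------------------------------

    def scenario_hash(self) -> str:
        # out_dir is where results land, not part of the experiment identity
        payload = self.model_dump(mode="json", exclude={"out_dir"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    def sub_seeds(self) -> dict[str, int]:
        """Named deterministic sub-seeds derived from the master seed."""
        names = ("screen", "ga", "noise", "phantom")
        children = np.random.SeedSequence(self.master_seed).spawn(len(names))
        return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}

    def dep_grid(self) -> PupilGrid:
        return PupilGrid(
            self.grid.n_pixels,
            self.grid.na,
            self.grid.wavelength_dep_nm,
            self.grid.medium_index,
            self.grid.pupil_fill,
        )

    def exc_grid(self) -> PupilGrid:
        return PupilGrid(
            self.grid.n_pixels,
            self.grid.na,
            self.grid.wavelength_exc_nm,
            self.grid.medium_index,
            self.grid.pupil_fill,
        )

    def screen_recipe(self) -> ScreenRecipe:
        return ScreenRecipe(
            kind=self.screen.kind,
            total_rms_rad=self.screen.total_rms_rad,
            mode_range=(self.screen.mode_lo, self.screen.mode_hi),
            rng_seed=self.sub_seeds()["screen"],
            defocus_um=self.screen.defocus_um,
        )

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(
            mode=self.ga.mode,
            layout=SegmentLayout(self.ga.segment_n),
            zernike_modes=tuple(
                range(self.ga.zernike_mode_lo, self.ga.zernike_mode_hi + 1)
            ),
            init_coeff_sd=self.ga.init_coeff_sd,
        )

    def ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.ga.population_size,
            n_generations=self.ga.n_generations,
            n_parents=self.ga.n_parents,
            mutation_rate_initial=self.ga.mutation_rate_initial,
            mutation_rate_final=self.ga.mutation_rate_final,
            mutation_decay=self.ga.mutation_decay,
            mutation_scale=self.ga.mutation_scale,
            mutation_scale_final=self.ga.mutation_scale_final,
            elitism=self.ga.elitism,
            stop_patience=self.ga.stop_patience,
            rng_seed=self.sub_seeds()["ga"],
        )

    def make_phantom(self) -> Phantom:
        seed = self.sub_seeds()["phantom"]
        p = self.phantom
        if p.kind == "bead_field":
            return make_bead_field(
                p.n_beads,
                p.min_separation_nm,
                p.field_size_nm,
                rng_seed=seed,
                pair_separation_nm=p.pair_separation_nm,
            )
        if p.kind == "filaments":
            return make_filaments(
                p.n_filaments, p.persistence_nm, p.width_nm, p.field_size_nm, rng_seed=seed
            )
        raise ValueError(f"unknown phantom kind {p.kind!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))


class ConfigError(ValueError):
    """Config validation failure carrying the complete list of violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


def _known_keys(model: type[BaseModel]) -> list[str]:
    return list(model.model_fields)


def validate_config(path: str | Path) -> Scenario:
    """Parse and validate a YAML scenario file; report *all* violations."""
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"unreadable YAML: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"top level must be a mapping, got {type(raw).__name__}"])
    try:
        return Scenario.model_validate(raw)
    except ValidationError as exc:
        violations = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            msg = f"{loc or '<root>'}: {err['msg']}"
            if err["type"] == "extra_forbidden":
                section = Scenario
                for part in err["loc"][:-1]:
                    ann = section.model_fields[str(part)].annotation
                    if isinstance(ann, type) and issubclass(ann, BaseModel):
                        section = ann
                close = difflib.get_close_matches(
                    str(err["loc"][-1]), _known_keys(section), n=1
                )
                if close:
                    msg += f" (did you mean {close[0]!r}?)"
            violations.append(msg)
        raise ConfigError(violations) from exc


def demo_scenario(out_dir: str = "sted_ao_demo", master_seed: int = 0) -> Scenario:
    """A small showcase scenario that completes in well under five minutes."""
    return Scenario(
        grid=GridConfig(n_pixels=64),
        screen=ScreenConfig(total_rms_rad=1.2),
        ga=GASection(n_generations=80, stop_patience=20),
        phantom=PhantomConfig(n_beads=8, field_size_nm=3000.0),
        psf_oversample=4,
        zeta_list=[16.0],
        master_seed=master_seed,
        out_dir=out_dir,
    )


def run_scenario(scenario: Scenario, stages: tuple[str, ...] = ("correct", "masks", "image", "report")) -> dict:
    """Run the correct -> image -> report pipeline, writing all artifacts.

    Returns a report dict with metrics and output paths.  Every CSV embeds
    the scenario hash and package version so a report can be traced to its
    exact configuration.
    """
    out = Path(scenario.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"scenario {scenario.scenario_hash()} sted-ao {__version__}"
    seeds = scenario.sub_seeds()
    report: dict = {"hash": scenario.scenario_hash(), "version": __version__}

    grid = scenario.dep_grid()
    screen = make_screen(scenario.screen_recipe(), grid)
    spiral = spiral_phase(grid)
    stage = "correct"
    try:
        noise_rng = np.random.default_rng(seeds["noise"])
        fitness = GuideStarFitness(
            grid,
            screen,
            star=None
            if scenario.guide_star.pinhole_radius_px is None
            else GuideStar(
                tuple(scenario.guide_star.position_px),
                scenario.guide_star.pinhole_radius_px,
            ),
            noise_sd=scenario.guide_star.noise_sd,
            rng=noise_rng,
        )
        spec = scenario.genome_spec()
        decoder = GenomeDecoder(spec, grid)
        best, trace = run_ga(
            lambda genome: fitness.from_phase(decoder.phase_values(genome)),
            scenario.ga_config(),
            spec,
        )
        correction = decoder(best)
        report["fitness_uncorrected"] = fitness.from_phase(
            np.zeros(grid.shape), noise_free=True
        )
        report["fitness_corrected"] = fitness.from_phase(
            correction.values, noise_free=True
        )
        report["n_evaluations"] = trace.n_evaluations
        report["generations"] = trace.n_generations
        save_trace_csv(trace, out / "fitness_trace.csv", header_comment=tag)

        stage = "masks"
        if "masks" in stages:
            save_mask_image(correction, out / "correction_mask.png")
            save_tiff(correction.values, out / "correction_mask.tiff", 1.0, tag)
            carrier = blazed_grating(grid, scenario.blazed_period_px)
            save_mask_image(
                compose([carrier, spiral, correction]), out / "slm_composite.png"
            )
            save_mask_image(spiral, out / "spiral_mask.png")

        stage = "image"
        ov = scenario.psf_oversample
        gauss_un = focal_psf(grid, screen.phase, oversample=ov)
        gauss_co = focal_psf(grid, compose([screen.phase, correction]), oversample=ov)
        donut_ideal = focal_psf(grid, spiral, oversample=ov)
        donut_un = focal_psf(grid, compose([spiral, screen.phase]), oversample=ov)
        donut_co = focal_psf(
            grid, compose([spiral, screen.phase, correction]), oversample=ov
        )
        if "image" in stages or "report" in stages:
            for name, psf in (
                ("psf_gauss_uncorrected", gauss_un),
                ("psf_gauss_corrected", gauss_co),
                ("psf_donut_uncorrected", donut_un),
                ("psf_donut_corrected", donut_co),
            ):
                save_tiff(psf.intensity, out / f"{name}.tiff", psf.pixel_size_nm, tag)

        px = scenario.phantom.pixel_size_nm
        kernel_shape = (129, 129)
        exc = resample_psf(
            focal_psf(scenario.exc_grid(), oversample=ov), px, kernel_shape
        )
        phantom = scenario.make_phantom()
        phantom.to_csv(out / "phantom.csv")
        conf_img = scan_image(phantom, exc, px, channel="confocal")
        zeta = scenario.zeta_list[0] if scenario.zeta_list else 16.0
        params = DepletionParams(zeta, peak_reference=donut_ideal.peak)
        eff_un = effective_sted_psf(
            exc, resample_psf(donut_un, px, kernel_shape), params
        )
        eff_co = effective_sted_psf(
            exc, resample_psf(donut_co, px, kernel_shape), params
        )
        sted_un = scan_image(phantom, eff_un, px, channel="sted")
        sted_co = scan_image(phantom, eff_co, px, channel="sted")
        if "image" in stages:
            for name, img in (
                ("image_confocal", conf_img),
                ("image_sted_uncorrected", sted_un),
                ("image_sted_corrected", sted_co),
            ):
                save_tiff(img.pixels, out / f"{name}.tiff", img.pixel_size_nm, tag)

        stage = "report"
        metrics = {
            "null_depth_uncorrected": metric_null_depth(donut_un),
            "null_depth_corrected": metric_null_depth(donut_co),
            "ring_uniformity_uncorrected": ring_uniformity(donut_un),
            "ring_uniformity_corrected": ring_uniformity(donut_co),
            "mean_intensity_confocal": metric_mean_intensity(conf_img),
            "mean_intensity_sted_uncorrected": metric_mean_intensity(sted_un),
            "mean_intensity_sted_corrected": metric_mean_intensity(sted_co),
            "psf_fwhm_confocal_nm": psf_fwhm_nm(exc),
        }
        if phantom.n_emitters:
            x, y = phantom.positions_nm[0]
            r, c = y / px, x / px
            half = min(12.0, c, r, conf_img.pixels.shape[1] - 1 - c)
            line = ((r, c - half), (r, c + half))
            for name, img in (
                ("bead_fwhm_confocal_nm", conf_img),
                ("bead_fwhm_sted_uncorrected_nm", sted_un),
                ("bead_fwhm_sted_corrected_nm", sted_co),
            ):
                try:
                    metrics[name] = metric_fwhm(img, line)
                except ValueError:
                    metrics[name] = float("nan")
        report["metrics"] = metrics
        if "report" in stages:
            with open(out / "metrics.csv", "w") as fh:
                fh.write(f"# {tag}\n")
                fh.write("metric,value\n")
                for k, v in metrics.items():
                    fh.write(f"{k},{v:.12g}\n")
            scenario.to_yaml(out / "scenario.yaml")
    except Exception as exc:
        raise RuntimeError(
            f"scenario {scenario.scenario_hash()} failed at stage {stage!r}: {exc}"
        ) from exc
    return report
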