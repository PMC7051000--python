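# sted-ao

Genetic-algorithm (GA) wavefront correction for STED microscopy, exercised
on a simulated optical bench so that every claim about restored donut
quality, signal intensity and resolution can be tested without hardware.

A spatial light modulator (SLM) in the depletion path of a STED microscope
carries three phases at once: a blazed-grating carrier, a 0–2π spiral that
shapes the donut, and a correction phase. The correction is found by a GA
whose fitness is the back-scattered signal of a gold nanoparticle guide
star. This package models the whole loop:

- **`sted_ao.optics`** — pupil grid, phase masks (Zernike/Noll with RMS
  normalization, spiral, blazed grating, SLM segments), 8-bit quantization
  (256 levels per 2π), and the scalar Fourier-optics focal PSF with
  spherical-cap defocus.
- **`sted_ao.microscope`** — guide-star fitness (pinhole-integrated focal
  intensity, normalized to the unaberrated ceiling of 1, with optional
  Gaussian noise), saturated-depletion effective STED PSF
  `h_exc · exp(−ln2 · ζ · h_dep)`, scanned-image formation, axial stacks.
- **`sted_ao.ga`** — genomes in segment mode (9·n² blocks of shared 8-bit
  levels), Zernike mode, or mixed mode; elitist GA with rank-weighted
  selection, uniform crossover, and exponentially decaying mutation.
- **`sted_ao.phantoms`** — seeded aberration screens (random Zernike
  mixtures, defocus, spherical, power-law turbulence), bead fields and
  filament phantoms, and the image metrics: Gaussian-fit FWHM along a line
  profile, donut null depth, ring uniformity, whole-frame mean intensity.
- **`sted_ao.scenario` / `sted_ao.cli`** — YAML-configured, fully seeded
  end-to-end experiments with TIFF/PNG/CSV artifacts.
- **`sted_ao.benchmarks`** — the acceptance experiments (Zernike recovery,
  defocus conjugacy, donut restoration, STED scaling law, imaging
  direction, random-search baseline).

## CLI

```sh
sted-ao demo --out demo_out --seed 0        # < 5 min end-to-end showcase
sted-ao correct -c scenario.yaml            # GA correction: trace + masks
sted-ao image   -c scenario.yaml            # confocal / STED phantom images
sted-ao report  -c scenario.yaml            # full pipeline + metrics table
sted-ao masks   -c scenario.yaml            # 8-bit SLM mask exports
```

A scenario YAML is fully declarative; every key has a default, so
`master_seed: 5` alone is a valid file. All randomness (screen, GA, noise,
phantom) derives from `master_seed` through named sub-streams, and every
CSV/TIFF embeds a scenario hash for traceability. Phase masks export as
8-bit PNG/BMP with gray level = `floor(phase/2π·256) mod 256` — the exact
payload an SLM driver consumes.

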