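"""Synthetic FLUO-like scenes with known ground-truth SIF.

The generator is a deliberately simple forward model — not an atmospheric
radiative-transfer code — whose only job is to produce radiance cubes whose
relation to SIF has the structure the emulator must learn:

``radiance(lam) = g * E(lam) * T(lam) * rho(lam) / pi + SIF(lam) + noise``

* ``E`` is a fixed smooth solar-like irradiance curve with a mild ripple
  (closed form below; its absolute scale is an arbitrary convention),
* ``T(lam) = 1 - depth * exp(-(lam - 760.5)^2 / (2 * 0.65^2))`` is the O2A
  absorption dip,
* ``SIF(lam) = a * exp(-(lam - 740)^2 / (2 * 18^2)) / exp(-(760 - 740)^2 /
  (2 * 18^2))`` is the far-red fluorescence shape, normalized so its value
  at 760 nm is the amplitude ``a``,
* ``g`` is a per-scene illumination factor standing in for acquisition-time
  differences between flight lines.

Land cover is a Voronoi mosaic of ``n_classes`` contiguous patches; each
class has a red-edge (vegetated) or flat/sloped (non-vegetated) reflectance
and a SIF amplitude (exactly 0 for non-vegetated classes). Within a class,
pixels vary through a small SIF-amplitude jitter and a multiplicative
reflectance brightness jitter, both of which show up in the radiance and are
therefore learnable. The "reference" SIF adds i.i.d. Gaussian band noise to
the truth, mimicking a spectral-fitting retrieval's output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import BandGrid, RadianceCube, SIFCube
from .errors import ArgumentError

# grid presets
FLUO_INPUT_GRID = (669.5, 781.9, 1024)
SIF_OUTPUT_GRID = (751.0, 777.0, 27)

_O2A_CENTER_NM = 760.5
_O2A_WIDTH_NM = 0.65
_SIF_CENTER_NM = 740.0
_SIF_WIDTH_NM = 18.0
_SIF_REFERENCE_NM = 760.0


def make_band_grid(start: float, stop: float, n_bands: int, label: str = "") -> BandGrid:
    """``n_bands`` evenly spaced band centers from ``start`` to ``stop`` inclusive."""
    if not (np.isfinite(start) and np.isfinite(stop)):
        raise ArgumentError("band grid endpoints must be finite")
    if stop <= start:
        raise ArgumentError("stop must exceed start")
    if n_bands < 2:
        raise ArgumentError("need at least 2 bands")
    return BandGrid(np.linspace(start, stop, int(n_bands)), label=label)


def fluo_input_grid() -> BandGrid:
    """The FLUO preset: 1024 bands spanning 669.5-781.9 nm."""
    return make_band_grid(*FLUO_INPUT_GRID, label="FLUO-input")


def sif_output_grid() -> BandGrid:
    """The SIF preset: 27 bands, 751-777 nm at 1 nm."""
    return make_band_grid(*SIF_OUTPUT_GRID, label="SIF-output")


@dataclass
class SceneConfig:
    rows: int = 300
    cols: int = 300
    n_classes: int = 8
    vegetation_fraction: float = 0.61
    input_grid: tuple = FLUO_INPUT_GRID          # (start, stop, n_bands)
    output_grid: tuple = SIF_OUTPUT_GRID
    sif_amplitude_range: tuple = (0.0, 6.0)      # mW m-2 sr-1 nm-1 at 760 nm
    amplitude_jitter_sd: float = 0.5             # within-class pixel spread
    reflectance_jitter_sd: float = 0.05          # multiplicative brightness spread
    radiance_noise_sd: float = 0.5               # sensor noise, mW m-2 sr-1 nm-1
    reference_sif_noise_sd: float = 0.3          # retrieval-like noise on the reference
    illumination_factor: float = 1.0
    absorption_depth: float = 0.85               # O2A dip depth in [0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rows, self.cols, self.n_classes) < 1:
            raise ArgumentError("rows, cols and n_classes must be >= 1")
        if not (0.0 <= self.absorption_depth < 1.0):
            raise ArgumentError("absorption_depth must be in [0, 1)")
        if self.illumination_factor <= 0:
            raise ArgumentError("illumination_factor must be positive")
        if not (0.0 <= self.vegetation_fraction <= 1.0):
            raise ArgumentError("vegetation_fraction must be in [0, 1]")
        lo, hi = self.sif_amplitude_range
        if hi < lo:
            raise ArgumentError("sif_amplitude_range must be (low, high)")


@dataclass
class ClassLibrary:
    """Per-class reflectance spectra (on the input grid) and SIF amplitudes."""

    reflectance: np.ndarray     # [n_classes, B_in], in [0, 1]
    sif_amplitude: np.ndarray   # [n_classes]; exactly 0 for non-vegetated
    labels: list[str]
    grid: BandGrid


@dataclass
class SceneTruth:
    class_map: np.ndarray       # [rows, cols] int class indices
    amplitude_map: np.ndarray   # [rows, cols] per-pixel SIF amplitude at 760 nm
    true_sif: SIFCube
    reference_sif: SIFCube
    library: ClassLibrary


def solar_irradiance(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth solar-like irradiance (arbitrary absolute scale).

    ``E(lam) = 520 exp(-((lam - 560)/290)^2) (1 + 0.04 cos(2 pi (lam - 669.5)/35))``
    — a gentle decline across the far-red window with a mild ripple that
    gives the input PCA some non-trivial spectral structure.
    """
    wl = np.asarray(wavelengths, dtype=float)
    base = 520.0 * np.exp(-(((wl - 560.0) / 290.0) ** 2))
    ripple = 1.0 + 0.04 * np.cos(2.0 * np.pi * (wl - 669.5) / 35.0)
    return base * ripple


def o2a_transmittance(wavelengths: np.ndarray, depth: float) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    dip = np.exp(-((wl - _O2A_CENTER_NM) ** 2) / (2.0 * _O2A_WIDTH_NM ** 2))
    return 1.0 - depth * dip


def sif_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Far-red fluorescence shape, unit value at 760 nm."""
    wl = np.asarray(wavelengths, dtype=float)
    g = np.exp(-((wl - _SIF_CENTER_NM) ** 2) / (2.0 * _SIF_WIDTH_NM ** 2))
    g760 = np.exp(-((_SIF_REFERENCE_NM - _SIF_CENTER_NM) ** 2)
                  / (2.0 * _SIF_WIDTH_NM ** 2))
    return g / g760


def generate_class_library(config: SceneConfig, rng: np.random.Generator) -> ClassLibrary:
    """Random land-cover library: red-edge vegetated classes with SIF, flat or
    gently sloped non-vegetated classes without."""
    grid = make_band_grid(*config.input_grid, label="FLUO-input")
    wl = grid.wavelengths
    n_veg = int(round(config.vegetation_fraction * config.n_classes))
    refl = np.zeros((config.n_classes, len(grid)))
    amp = np.zeros(config.n_classes)
    labels = []
    lo, hi = config.sif_amplitude_range
    for c in range(config.n_classes):
        if c < n_veg:
            rho_low = rng.uniform(0.03, 0.07)
            rho_high = rng.uniform(0.40, 0.60)
            edge = rng.uniform(715.0, 725.0)
            width = rng.uniform(5.0, 9.0)
            refl[c] = rho_low + (rho_high - rho_low) / (1.0 + np.exp(-(wl - edge) / width))
            amp[c] = rng.uniform(lo, hi)
            labels.append(f"vegetated-{c}")
        else:
            rho0 = rng.uniform(0.05, 0.45)
            slope = rng.uniform(-0.2, 0.2)
            mid = 0.5 * (wl[0] + wl[-1])
            refl[c] = rho0 * (1.0 + slope * (wl - mid) / (wl[-1] - wl[0]))
            labels.append(f"non-vegetated-{c}")
    refl = np.clip(refl, 0.0, 1.0)
    return ClassLibrary(reflectance=refl, sif_amplitude=amp, labels=labels, grid=grid)


def simulate_pixel(reflectance: np.ndarray, sif_amplitude: float,
                   config: SceneConfig, rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One pixel's (radiance on the input grid, true SIF on the output grid)."""
    in_grid = make_band_grid(*config.input_grid)
    out_grid = make_band_grid(*config.output_grid)
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.shape != (len(in_grid),):
        raise ArgumentError("reflectance must live on the input grid")
    E = solar_irradiance(in_grid.wavelengths)
    T = o2a_transmittance(in_grid.wavelengths, config.absorption_depth)
    radiance = (config.illumination_factor * E * T * reflectance / np.pi
                + sif_amplitude * sif_shape(in_grid.wavelengths))
    if config.radiance_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        radiance = radiance + rng.normal(0.0, config.radiance_noise_sd, radiance.shape)
    true_sif = sif_amplitude * sif_shape(out_grid.wavelengths)
    return radiance, true_sif


def _voronoi_class_map(rows: int, cols: int, n_classes: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Contiguous patches: label each pixel by its nearest seed point."""
    n_pix = rows * cols
    if n_classes > n_pix:
        raise ArgumentError("more classes than pixels")
    flat = rng.choice(n_pix, size=n_classes, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, (rows, cols))).astype(float)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = ((rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2)
    return np.argmin(d2, axis=2).astype(np.int32)


def simulate_scene(config: SceneConfig) -> tuple[RadianceCube, SceneTruth]:
    """A full scene: radiance cube plus class map, truth and noisy reference.

    Everything is reproducible from ``config.seed``: the seed is split into
    independent sub-streams for the class library, the class map, the
    within-class jitters and the two noise fields.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_lib, rng_map, rng_jit, rng_noise, rng_ref = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    library = generate_class_library(config, rng_lib)
    class_map = _voronoi_class_map(config.rows, config.cols, config.n_classes, rng_map)

    in_grid = library.grid
    out_grid = make_band_grid(*config.output_grid, label="SIF-output")
    E = solar_irradiance(in_grid.wavelengths)
    T = o2a_transmittance(in_grid.wavelengths, config.absorption_depth)
    s_in = sif_shape(in_grid.wavelengths)
    s_out = sif_shape(out_grid.wavelengths)

    flat_cls = class_map.ravel()
    n_pix = flat_cls.size
    class_amp = library.sif_amplitude[flat_cls]
    vegetated = class_amp != 0.0
    amp = class_amp.copy()
    if config.amplitude_jitter_sd > 0:
        jitter = rng_jit.normal(0.0, config.amplitude_jitter_sd, n_pix)
        amp = np.where(vegetated, np.maximum(class_amp + jitter, 0.0), 0.0)
    bright = np.ones(n_pix)
    if config.reflectance_jitter_sd > 0:
        bright = np.maximum(
            rng_jit.normal(1.0, config.reflectance_jitter_sd, n_pix), 0.0
        )

    base = config.illumination_factor * (E * T) / np.pi  # [B_in]
    rho = library.reflectance[flat_cls]                  # [n_pix, B_in]
    radiance = (bright[:, None] * rho) * base + amp[:, None] * s_in
    if config.radiance_noise_sd > 0:
        radiance = radiance + rng_noise.normal(
            0.0, config.radiance_noise_sd, radiance.shape
        )

    true = amp[:, None] * s_out
    reference = true.copy()
    if config.reference_sif_noise_sd > 0:
        reference = reference + rng_ref.normal(
            0.0, config.reference_sif_noise_sd, reference.shape
        )

    shape3 = (config.rows, config.cols, -1)
    cube = RadianceCube(
        radiance.reshape(shape3).astype(np.float32, copy=False), in_grid,
        metadata={"description": "sifemu synthetic radiance"},
    )
    truth = SceneTruth(
        class_map=class_map,
        amplitude_map=amp.reshape(config.rows, config.cols),
        true_sif=SIFCube(true.reshape(shape3).astype(np.float32, copy=False), out_grid),
        reference_sif=SIFCube(
            reference.reshape(shape3).astype(np.float32, copy=False), out_grid
        ),
        library=library,
    )
    return cube, truth
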