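"""Synthetic dried serum-spot hyperspectral mosaics.

The generator provides a forward model with the statistical structure the
downstream analysis assumes, so the whole pipeline is testable without
instrument data:

* a unit-thickness serum absorptivity spectrum eps(nu) built from amide I
  (~1651 cm^-1) and amide II (~1548 cm^-1) bands, a handful of minor
  fingerprint bands and a broad background;
* a radially symmetric "coffee-ring" thickness map t(r) — dried droplets
  deposit more material at the perimeter than the centre;
* per-pixel scatter-like baselines (offset + slope in wavenumber),
  i.i.d. Gaussian noise, and hard clipping at a saturation limit;
* per-patient band-parameter draws so two patient classes differ subtly in
  amide band position and amplitude ratio.

Pixel spectra follow A(x, y, nu) = clip(t(x, y) * eps(nu) + offset +
slope * (nu - nu_min) + noise, saturation_limit).  All randomness derives
from one cohort seed through per-spot substreams, so runs are bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FrequencyAxis,
    HyperCube,
    InstrumentPreset,
    PRESET_SIM,
    Spectrum,
    SpotLayout,
)

__all__ = [
    "BandModel",
    "SpotConfig",
    "ClassEffect",
    "CohortConfig",
    "DEFAULT_SERUM_BANDS",
    "CANCER_EFFECT",
    "CONTROL_EFFECT",
    "component_spectrum",
    "thickness_map",
    "simulate_spot",
    "simulate_mosaic",
    "simulate_cohort_spectra",
    "draw_patient_bands",
    "spot_noise_rng",
    "spot_param_rng",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandModel:
    """A single absorption band of eps(nu) (per unit thickness)."""

    center: float          # cm^-1
    amplitude: float       # AU per unit thickness
    width: float           # FWHM, cm^-1
    shape: str = "gaussian"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, nu: np.ndarray) -> np.ndarray:
        d = nu - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * np.log(2.0) * (d / self.width) ** 2)
        half = self.width / 2.0
        return self.amplitude * half**2 / (d**2 + half**2)


# Default serum band set.  Positions are the canonical protein amide I/II
# bands plus minor fingerprint features; amplitudes and the broad 0.25 AU
# background are synthetic choices (no absolute absorbance scale exists for
# these deposits) picked so the 1000-1080 cm^-1 points act as quasi-baseline.
DEFAULT_SERUM_BANDS: tuple[BandModel, ...] = (
    BandModel(1550.0, 0.25, 1600.0, "gaussian", name="background"),
    BandModel(1651.0, 1.00, 45.0, "gaussian", name="amide_I"),
    BandModel(1548.0, 0.60, 45.0, "gaussian", name="amide_II"),
    BandModel(1080.0, 0.08, 50.0, "gaussian", name="carbohydrate"),
    BandModel(1310.0, 0.10, 60.0, "gaussian", name="amide_III"),
    BandModel(1400.0, 0.15, 45.0, "gaussian", name="cooh"),
    BandModel(1740.0, 0.06, 30.0, "gaussian", name="lipid_ester"),
)


def component_spectrum(bands: Sequence[BandModel], axis: FrequencyAxis) -> Spectrum:
    """Render eps(nu): the sum of band profiles on ``axis`` (non-negative)."""
    if not bands:
        raise ValueError("band list must be non-empty")
    nu = axis.values
    total = np.zeros_like(nu)
    for band in bands:
        total += band.profile(nu)
    return Spectrum(axis, total)


@dataclass(frozen=True)
class SpotConfig:
    """Geometry, optics artefacts and noise of one dried serum spot."""

    spot_radius_um: float = 100.0
    ring_width_um: float = 12.0
    center_thickness: float = 1.0
    ring_thickness: float = 1.6           # must be >= center_thickness
    baseline_offset_range: tuple[float, float] = (0.0, 0.02)   # AU, per pixel
    baseline_slope_range: tuple[float, float] = (-2e-5, 2e-5)  # AU per cm^-1
    noise_sd: float = 0.01                # AU, i.i.d. per pixel-frequency
    saturation_limit: float = 2.0         # AU, hard clip
    thickness_scale_sd: float = 0.05      # lognormal sigma of per-spot scale
    bands: tuple[BandModel, ...] = DEFAULT_SERUM_BANDS

    def __post_init__(self) -> None:
        if self.ring_thickness < self.center_thickness:
            raise ValueError("coffee ring requires ring_thickness >= center_thickness")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.saturation_limit <= 0:
            raise ValueError("saturation_limit must be positive")
        if self.spot_radius_um <= 0 or self.ring_width_um <= 0:
            raise ValueError("spot geometry must be positive")

    @property
    def margin_um(self) -> float:
        """Radius beyond which the deposit thickness is exactly zero."""
        return self.spot_radius_um + 3.0 * self.ring_width_um


@dataclass(frozen=True)
class ClassEffect:
    """Systematic + inter-patient variation of the amide bands for a class.

    ``amideI_center_shift`` / ``amideII_center_shift`` move the band centres
    (cm^-1) relative to the control positions; ``amplitude_ratio_factor``
    multiplies the amide I/II amplitude ratio.  ``center_sd`` is the
    inter-patient SD of each centre (cm^-1) and ``ratio_sd`` the lognormal
    sigma of the per-patient ratio jitter.
    """

    amideI_center_shift: float = 0.0
    amideII_center_shift: float = 0.0
    amplitude_ratio_factor: float = 1.0
    center_sd: float = 1.5
    ratio_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.center_sd < 0 or self.ratio_sd < 0:
            raise ValueError("inter-patient SDs must be >= 0")
        if self.amplitude_ratio_factor <= 0:
            raise ValueError("amplitude_ratio_factor must be positive")


CONTROL_EFFECT = ClassEffect()
# Direction mimics the full->sparse centroid observations: amide I moves
# down, amide II up, with a slightly raised I/II amplitude ratio.
CANCER_EFFECT = ClassEffect(amideI_center_shift=-4.0, amideII_center_shift=3.0,
                            amplitude_ratio_factor=1.05)


@dataclass(frozen=True)
class CohortConfig:
    """A multi-patient mosaic: one spot grid row per class (mosaic style)."""

    class_effects: Mapping[str, ClassEffect]
    n_per_class: int
    axis: FrequencyAxis
    spot: SpotConfig = SpotConfig()
    instrument: InstrumentPreset = PRESET_SIM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not self.class_effects:
            raise ValueError("at least one class required")


def thickness_map(cfg: SpotConfig, preset: InstrumentPreset) -> np.ndarray:
    """Radially symmetric coffee-ring thickness image on the preset grid.

    t(r) = center_thickness * edge(r) + (ring - center) * gauss(r - R; w),
    where edge(r) is 1 inside the spot and decays with the ring scale
    outside; thickness is exactly zero beyond R + 3w.
    """
    if cfg.margin_um > preset.fov_um / 2.0:
        raise ValueError("spot (incl. ring margin) does not fit inside the FOV")
    n = preset.n_pixels
    coords = (np.arange(n) - (n - 1) / 2.0) * preset.pixel_size_um
    rr, cc = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(rr, cc)
    bump = np.exp(-((r - cfg.spot_radius_um) ** 2) / (2.0 * cfg.ring_width_um**2))
    edge = np.where(r <= cfg.spot_radius_um, 1.0, bump)
    t = cfg.center_thickness * edge + (cfg.ring_thickness - cfg.center_thickness) * bump
    t[r > cfg.margin_um] = 0.0
    return t


def spot_noise_rng(seed: int, index: int) -> np.random.Generator:
    """Noise/baseline substream for spot ``index`` of a run seeded ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index), 1]))


def spot_param_rng(seed: int, index: int) -> np.random.Generator:
    """Patient-parameter substream for spot ``index``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index), 0]))


def simulate_spot(cfg: SpotConfig, axis: FrequencyAxis,
                  preset: InstrumentPreset = PRESET_SIM,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> HyperCube:
    """Simulate the hyperspectral image of a single dried serum spot.

    Either ``seed`` or an explicit ``rng`` selects the random stream; with
    neither, the spot is rendered noise- and baseline-free.
    """
    t = thickness_map(cfg, preset)
    eps = component_spectrum(list(cfg.bands), axis).absorbance
    data = t[:, :, None] * eps[None, None, :]
    if rng is None and seed is not None:
        rng = spot_noise_rng(seed, 0)
    if rng is not None:
        n = t.shape[0]
        off_lo, off_hi = cfg.baseline_offset_range
        slo_lo, slo_hi = cfg.baseline_slope_range
        offset = rng.uniform(off_lo, off_hi, size=(n, n))
        slope = rng.uniform(slo_lo, slo_hi, size=(n, n))
        dnu = axis.values - axis.values[0]
        data = data + offset[:, :, None] + slope[:, :, None] * dnu[None, None, :]
        if cfg.noise_sd > 0:
            data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
    np.minimum(data, cfg.saturation_limit, out=data)
    return HyperCube(data, axis, pixel_size_um=preset.pixel_size_um)


def draw_patient_bands(bands: Sequence[BandModel], effect: ClassEffect,
                       rng: np.random.Generator) -> tuple[BandModel, ...]:
    """Draw one patient's band set from a class effect distribution.

    Shifts the amide I/II centres by the class effect plus N(0, center_sd)
    patient jitter and multiplies the amide I amplitude by the ratio factor
    times a lognormal jitter.  Other bands pass through unchanged.
    """
    out = []
    shift_I = effect.amideI_center_shift + rng.normal(0.0, effect.center_sd)
    shift_II = effect.amideII_center_shift + rng.normal(0.0, effect.center_sd)
    ratio = effect.amplitude_ratio_factor * rng.lognormal(0.0, effect.ratio_sd)
    for band in bands:
        if band.name == "amide_I":
            out.append(replace(band, center=band.center + shift_I,
                               amplitude=band.amplitude * ratio))
        elif band.name == "amide_II":
            out.append(replace(band, center=band.center + shift_II))
        else:
            out.append(band)
    return tuple(out)


def _mosaic_layout(cohort: CohortConfig) -> SpotLayout:
    npx = cohort.instrument.n_pixels
    labels = list(cohort.class_effects)
    n_rows, n_cols = len(labels), cohort.n_per_class
    sample_ids, class_labels = [], []
    for i, lab in enumerate(labels):
        for j in range(n_cols):
            sample_ids.append(f"{lab}_{j + 1:02d}")
            class_labels.append(lab)
    return SpotLayout(
        n_rows=n_rows, n_cols=n_cols,
        row_edges=np.arange(n_rows + 1) * npx,
        col_edges=np.arange(n_cols + 1) * npx,
        sample_ids=tuple(sample_ids), class_labels=tuple(class_labels),
    )


def simulate_mosaic(cohort: CohortConfig) -> tuple[HyperCube, SpotLayout, pd.DataFrame]:
    """Simulate a full multi-patient mosaic (one spot per grid cell).

    Returns the cube, its spot layout, and a truth table recording every
    drawn parameter (band centres/amplitudes, thickness scale) per sample.
    """
    layout = _mosaic_layout(cohort)
    npx = cohort.instrument.n_pixels
    n_freq = len(cohort.axis)
    data = np.zeros((layout.n_rows * npx, layout.n_cols * npx, n_freq))
    records = []
    idx = 0
    for i in range(layout.n_rows):
        for j in range(layout.n_cols):
            k = layout.cell_index(i, j)
            label = layout.class_labels[k]
            effect = cohort.class_effects[label]
            prng = spot_param_rng(cohort.seed, idx)
            bands = draw_patient_bands(cohort.spot.bands, effect, prng)
            tscale = prng.lognormal(0.0, cohort.spot.thickness_scale_sd)
            cfg = replace(cohort.spot, bands=bands,
                          center_thickness=cohort.spot.center_thickness * tscale,
                          ring_thickness=cohort.spot.ring_thickness * tscale)
            spot = simulate_spot(cfg, cohort.axis, cohort.instrument,
                                 rng=spot_noise_rng(cohort.seed, idx))
            rs, cs = layout.cell_slices(i, j)
            data[rs, cs, :] = spot.data
            amide_I = next(b for b in bands if b.name == "amide_I")
            amide_II = next(b for b in bands if b.name == "amide_II")
            records.append({
                "sample_id": layout.sample_ids[k],
                "class_label": label,
                "grid_row": i, "grid_col": j, "spot_index": idx,
                "amideI_center": amide_I.center, "amideI_amplitude": amide_I.amplitude,
                "amideII_center": amide_II.center, "amideII_amplitude": amide_II.amplitude,
                "thickness_scale": tscale,
                "seed": cohort.seed,
            })
            idx += 1
    cube = HyperCube(data, cohort.axis,
                     pixel_size_um=cohort.instrument.pixel_size_um, layout=layout)
    return cube, layout, pd.DataFrame.from_records(records)


def simulate_cohort_spectra(cohort: CohortConfig, spectrum_noise_sd: float = 0.002,
                            ) -> tuple[dict[str, list[Spectrum]], pd.DataFrame]:
    """Spectrum-level shortcut: per-patient mean spot spectra without imaging.

    Draws each patient's band parameters exactly as :func:`simulate_mosaic`
    does, renders the clean spectrum, applies the per-patient thickness
    scale, and adds spectrum-level Gaussian noise (the residual noise of a
    quality-passed pixel average).  Useful for classifier experiments where
    rendering full cubes would dominate the runtime.
    """
    labels = list(cohort.class_effects)
    spectra: dict[str, list[Spectrum]] = {lab: [] for lab in labels}
    records = []
    idx = 0
    for lab in labels:
        effect = cohort.class_effects[lab]
        for j in range(cohort.n_per_class):
            prng = spot_param_rng(cohort.seed, idx)
            bands = draw_patient_bands(cohort.spot.bands, effect, prng)
            tscale = prng.lognormal(0.0, cohort.spot.thickness_scale_sd)
            clean = component_spectrum(list(bands), cohort.axis).absorbance
            nrng = spot_noise_rng(cohort.seed, idx)
            ab = tscale * clean + nrng.normal(0.0, spectrum_noise_sd, size=clean.shape)
            spectra[lab].append(Spectrum(cohort.axis, ab))
            amide_I = next(b for b in bands if b.name == "amide_I")
            amide_II = next(b for b in bands if b.name == "amide_II")
            records.append({
                "sample_id": f"{lab}_{j + 1:02d}", "class_label": lab,
                "spot_index": idx,
                "amideI_center": amide_I.center, "amideII_center": amide_II.center,
                "thickness_scale": tscale, "seed": cohort.seed,
            })
            idx += 1
    return spectra, pd.DataFrame.from_records(records)
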