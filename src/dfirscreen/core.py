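"""Core domain types for discrete-frequency infrared (DFIR) imaging.

DFIR imaging acquires absorbance images only at selected mid-infrared
wavenumbers instead of a full interferogram-derived spectrum.  This module
holds the shared vocabulary of the package: the wavenumber axis and its
named presets, single spectra, hyperspectral cubes (rows x cols x
frequencies), the spot-grid layout of a multi-patient mosaic, and the
microscope presets, together with the axis/cube arithmetic every other
module builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrequencyAxis",
    "Spectrum",
    "HyperCube",
    "SpotLayout",
    "InstrumentPreset",
    "PRESET_HIGH_MAG",
    "PRESET_LOW_MAG",
    "PRESET_SIM",
    "DF_14_VALUES",
    "DF_9_VALUES",
    "build_axis",
    "downsample_to_axis",
    "cube_stats",
    "reduction_percent",
    "Reduction",
    "pixels_to_um",
    "pixels_to_mm",
]

# Fingerprint-region frequency presets (wavenumbers, cm^-1).  The sparse
# sets target the amide I/II bands plus a few low-frequency baseline points;
# the 9-point set drops the baseline points and the high-frequency tail.
DF_14_VALUES: tuple[int, ...] = (
    1000, 1030, 1080, 1482, 1520, 1546, 1570,
    1600, 1630, 1654, 1686, 1726, 1734, 1770,
)
DF_9_VALUES: tuple[int, ...] = (
    1482, 1520, 1546, 1570, 1600, 1630, 1654, 1686, 1726,
)
# 199 points: 1000 cm^-1 upward at 4 cm^-1 spacing (1000..1792).
_FULL_199_VALUES: tuple[int, ...] = tuple(range(1000, 1793, 4))

_PRESETS = {
    "FULL_199": _FULL_199_VALUES,
    "DF_14": DF_14_VALUES,
    "DF_9": DF_9_VALUES,
}


@dataclass(frozen=True)
class FrequencyAxis:
    """Strictly increasing grid of wavenumbers (cm^-1)."""

    values: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("axis must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("axis values must be finite")
        if np.any(vals <= 0):
            raise ValueError("wavenumbers must be positive")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("axis must be strictly increasing with no duplicates")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyAxis):
            return NotImplemented
        return len(self) == len(other) and bool(np.array_equal(self.values, other.values))

    def __hash__(self) -> int:
        return hash((self.name, self.values.tobytes()))

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def build_axis(preset: str | Iterable[float]) -> FrequencyAxis:
    """Build a :class:`FrequencyAxis` from a preset name or explicit list.

    Presets: ``FULL_199`` (1000..1792 cm^-1, 4 cm^-1 spacing), ``DF_14``
    and ``DF_9`` (the discrete-frequency acquisition sets; ``DF_9`` is a
    subset of ``DF_14``).
    """
    if isinstance(preset, str):
        try:
            values = _PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
            ) from None
        return FrequencyAxis(np.asarray(values, dtype=float), name=preset)
    return FrequencyAxis(np.asarray(list(preset), dtype=float))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum A(nu) on a frequency axis (AU)."""

    axis: FrequencyAxis
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.ndim != 1:
            raise ValueError("absorbance must be 1-D")
        if ab.size != len(self.axis):
            raise ValueError(
                f"absorbance length {ab.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance values must be finite")
        object.__setattr__(self, "absorbance", ab)


@dataclass(frozen=True)
class InstrumentPreset:
    """Microscope objective geometry (square field of view)."""

    name: str
    fov_um: float
    magnification: float
    numerical_aperture: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        for f in ("fov_um", "magnification", "numerical_aperture", "pixel_size_um"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.pixel_size_um >= self.fov_um:
            raise ValueError("pixel_size_um must be smaller than fov_um")

    @property
    def n_pixels(self) -> int:
        """Pixels per side of the square field of view."""
        return int(round(self.fov_um / self.pixel_size_um))


# High-magnification objective used for piezo-dispensed micro-spots and the
# low-magnification objective used for hand-pipetted ~1 mm spots.
PRESET_HIGH_MAG = InstrumentPreset("high_mag", fov_um=650.0, magnification=12.5,
                                   numerical_aperture=0.70, pixel_size_um=1.36)
PRESET_LOW_MAG = InstrumentPreset("low_mag", fov_um=2000.0, magnification=4.0,
                                  numerical_aperture=0.15, pixel_size_um=4.25)
# Coarser desk-scale preset used by the simulator defaults (64 x 64 pixels).
PRESET_SIM = InstrumentPreset("sim", fov_um=320.0, magnification=12.5,
                              numerical_aperture=0.70, pixel_size_um=5.0)


@dataclass(frozen=True)
class SpotLayout:
    """Rectangular grid of spot cells tiling a mosaic image.

    ``row_edges``/``col_edges`` are pixel boundaries (length n+1, starting at
    0 and ending at the image extent); cell (i, j) covers rows
    ``row_edges[i]:row_edges[i+1]`` and similarly for columns.  Sample ids
    and class labels are stored row-major.
    """

    n_rows: int
    n_cols: int
    row_edges: np.ndarray
    col_edges: np.ndarray
    sample_ids: tuple[str, ...]
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        re = np.asarray(self.row_edges, dtype=int)
        ce = np.asarray(self.col_edges, dtype=int)
        if re.size != self.n_rows + 1 or ce.size != self.n_cols + 1:
            raise ValueError("edge arrays must have length n+1")
        if np.any(np.diff(re) <= 0) or np.any(np.diff(ce) <= 0):
            raise ValueError("cell edges must be strictly increasing")
        n_cells = self.n_rows * self.n_cols
        if len(self.sample_ids) != n_cells or len(self.class_labels) != n_cells:
            raise ValueError("one sample id and class label per cell required")
        if len(set(self.sample_ids)) != n_cells:
            raise ValueError("sample ids must be unique")
        object.__setattr__(self, "row_edges", re)
        object.__setattr__(self, "col_edges", ce)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))

    def cell_index(self, i: int, j: int) -> int:
        return i * self.n_cols + j

    def cell_slices(self, i: int, j: int) -> tuple[slice, slice]:
        return (slice(int(self.row_edges[i]), int(self.row_edges[i + 1])),
                slice(int(self.col_edges[j]), int(self.col_edges[j + 1])))

    def cells(self):
        """Yield (sample_id, class_label, (row_slice, col_slice)) row-major."""
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                k = self.cell_index(i, j)
                yield self.sample_ids[k], self.class_labels[k], self.cell_slices(i, j)


@dataclass
class HyperCube:
    """Absorbance image stack: data[row, col, frequency] in AU."""

    data: np.ndarray
    axis: FrequencyAxis
    pixel_size_um: float = 1.0
    layout: SpotLayout | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("cube data must be 3-D (rows x cols x frequencies)")
        if d.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {d.shape[2]} planes but axis has {len(self.axis)} values"
            )
        if d.shape[0] < 1 or d.shape[1] < 1:
            raise ValueError("cube must have at least one pixel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.layout is not None:
            if (self.layout.row_edges[-1] != d.shape[0]
                    or self.layout.col_edges[-1] != d.shape[1]):
                raise ValueError("layout does not tile the cube")
        self.data = d

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixel_spectra(self) -> np.ndarray:
        """Flattened (n_pixels, n_freq) view of the cube."""
        return self.data.reshape(-1, self.data.shape[2])


def _interp_weights(source: np.ndarray, target: np.ndarray):
    lo, hi = source[0], source[-1]
    if np.any(target < lo) or np.any(target > hi):
        raise ValueError(
            f"target axis values outside source range [{lo:g}, {hi:g}]"
        )
    hi_idx = np.searchsorted(source, target, side="left")
    hi_idx = np.clip(hi_idx, 1, source.size - 1)
    lo_idx = hi_idx - 1
    w = (target - source[lo_idx]) / (source[hi_idx] - source[lo_idx])
    return lo_idx, hi_idx, w


def downsample_to_axis(obj: Spectrum | HyperCube, target: FrequencyAxis):
    """Resample a spectrum or cube onto a (typically sparser) axis.

    Linear interpolation between the two bracketing source points; exact
    passthrough where a target wavenumber coincides with a source one.
    Raises if any target value lies outside the source range.
    """
    if isinstance(obj, Spectrum):
        src = obj.axis.values
        lo_idx, hi_idx, w = _interp_weights(src, target.values)
        ab = obj.absorbance[lo_idx] * (1 - w) + obj.absorbance[hi_idx] * w
        return Spectrum(target, ab)
    if isinstance(obj, HyperCube):
        src = obj.axis.values
        lo_idx, hi_idx, w = _interp_weights(src, target.values)
        data = obj.data[..., lo_idx] * (1 - w) + obj.data[..., hi_idx] * w
        return HyperCube(data.astype(obj.data.dtype, copy=False), target,
                         pixel_size_um=obj.pixel_size_um, layout=obj.layout)
    raise TypeError(f"cannot downsample object of type {type(obj).__name__}")


def cube_stats(n_spectra: float, n_freq: int) -> dict[str, float]:
    """Data-volume bookkeeping: one spectrum per pixel, one data point per
    (pixel, frequency) pair."""
    if n_spectra <= 0 or n_freq <= 0:
        raise ValueError("n_spectra and n_freq must be positive")
    return {"n_spectra": float(n_spectra), "n_datapoints": float(n_spectra) * n_freq}


@dataclass(frozen=True)
class Reduction:
    """Relative data reduction of a sparse acquisition versus a full one."""

    exact_percent: float
    rounded_percent: int


def reduction_percent(n_full: float, n_sparse: float) -> Reduction:
    """Percent reduction in data points going from ``n_full`` to ``n_sparse``."""
    if n_sparse <= 0 or n_full <= 0:
        raise ValueError("counts must be positive")
    if n_full < n_sparse:
        raise ValueError("n_full must be >= n_sparse")
    exact = 100.0 * (n_full - n_sparse) / n_full
    return Reduction(exact_percent=exact, rounded_percent=int(round(exact)))


def pixels_to_um(n_pixels: float, pixel_size_um: float) -> float:
    """Physical length of a pixel run (e.g. a scale bar) in micrometres."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return n_pixels * pixel_size_um


def pixels_to_mm(n_pixels: float, pixel_size_um: float) -> float:
    return pixels_to_um(n_pixels, pixel_size_um) / 1000.0
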