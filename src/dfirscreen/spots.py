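"""From QC-masked mosaics to one representative spectrum per serum spot.

Quality-passed pixel spectra inside each layout cell are averaged into a
single spot spectrum, which is then min-max scaled and optionally truncated
to the high-frequency (amide) region.  Spots whose good pixels touch a cell
boundary are flagged (stitching artefacts); spots with too few good pixels
are excluded with a recorded reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import FrequencyAxis, HyperCube, Spectrum, SpotLayout
from .qc import PixelMask

__all__ = [
    "SpotSpectrum",
    "SpotPixels",
    "assign_spots",
    "mean_spot_spectrum",
    "min_max_scale",
    "truncate_spectrum",
    "extract_spot_spectra",
]

DEFAULT_MIN_PIXELS = 25


@dataclass(frozen=True)
class SpotPixels:
    """Good-pixel set of one layout cell (absolute image coordinates)."""

    sample_id: str
    class_label: str
    rows: np.ndarray
    cols: np.ndarray
    n_pixels_total: int          # all pixels in the cell
    boundary_flag: bool = False  # good pixels touch the cell boundary

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)


@dataclass(frozen=True)
class SpotSpectrum:
    """Quality-passed mean spectrum of one serum spot."""

    sample_id: str
    class_label: str
    spectrum: Spectrum
    n_pixels_used: int
    n_pixels_total: int
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_pixels_used > self.n_pixels_total:
            raise ValueError("n_pixels_used cannot exceed n_pixels_total")

    @property
    def qc_pass_fraction(self) -> float:
        return self.n_pixels_used / self.n_pixels_total


def assign_spots(cube: HyperCube, mask: PixelMask, layout: SpotLayout,
                 ) -> tuple[list[SpotPixels], list[str]]:
    """Assign every good pixel to the layout cell containing it.

    Returns the per-cell pixel sets (cells in layout order) and the sample
    ids of cells with zero good pixels.  A cell whose good pixels include a
    boundary row/column is flagged, mirroring the exclusion of spots that
    fell on stitching boundaries.
    """
    if mask.labels.shape != cube.data.shape[:2]:
        raise ValueError("mask does not match cube shape")
    if (layout.row_edges[-1] != cube.data.shape[0]
            or layout.col_edges[-1] != cube.data.shape[1]):
        raise ValueError("layout does not tile the cube")
    good = mask.good
    spots: list[SpotPixels] = []
    empty: list[str] = []
    for sample_id, class_label, (rs, cs) in layout.cells():
        cell_good = good[rs, cs]
        rr, cc = np.nonzero(cell_good)
        rr = rr + rs.start
        cc = cc + cs.start
        on_boundary = False
        if rr.size:
            on_boundary = bool(
                (rr.min() == rs.start) or (rr.max() == rs.stop - 1)
                or (cc.min() == cs.start) or (cc.max() == cs.stop - 1)
            )
        n_total = (rs.stop - rs.start) * (cs.stop - cs.start)
        spots.append(SpotPixels(sample_id, class_label, rr, cc, n_total,
                                boundary_flag=on_boundary))
        if rr.size == 0:
            empty.append(sample_id)
    if empty:
        warnings.warn(f"cells with zero good pixels: {empty}")
    return spots, empty


def mean_spot_spectrum(spot: SpotPixels, cube: HyperCube,
                       min_pixels: int = DEFAULT_MIN_PIXELS) -> SpotSpectrum:
    """Unweighted per-frequency mean over a spot's good pixels.

    Raises ``ValueError`` when fewer than ``min_pixels`` good pixels remain
    (the spot is excluded, mirroring incompletely captured spots).
    """
    if spot.n_pixels < min_pixels:
        raise ValueError(
            f"spot {spot.sample_id}: only {spot.n_pixels} good pixels "
            f"(< {min_pixels}); excluded"
        )
    mean = cube.data[spot.rows, spot.cols, :].mean(axis=0)
    return SpotSpectrum(spot.sample_id, spot.class_label,
                        Spectrum(cube.axis, mean),
                        n_pixels_used=spot.n_pixels,
                        n_pixels_total=spot.n_pixels_total,
                        boundary_flag=spot.boundary_flag)


def min_max_scale(s: Spectrum) -> Spectrum:
    """Scale to [0, 1]: (A - min) / (max - min); errors on flat spectra."""
    lo = float(s.absorbance.min())
    hi = float(s.absorbance.max())
    if hi <= lo:
        raise ValueError("cannot min-max scale a flat spectrum")
    return Spectrum(s.axis, (s.absorbance - lo) / (hi - lo))


def truncate_spectrum(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep axis points with lo <= nu <= hi (inclusive both ends)."""
    if lo >= hi:
        raise ValueError("truncation requires lo < hi")
    sel = (s.axis.values >= lo) & (s.axis.values <= hi)
    if not sel.any():
        raise ValueError(f"truncation window [{lo}, {hi}] misses the axis")
    return Spectrum(FrequencyAxis(s.axis.values[sel], name=s.axis.name),
                    s.absorbance[sel])


def extract_spot_spectra(cube: HyperCube, mask: PixelMask, layout: SpotLayout,
                         min_pixels: int = DEFAULT_MIN_PIXELS,
                         scale: bool = True,
                         truncate: tuple[float, float] | None = None,
                         exclude_boundary: bool = False,
                         ) -> tuple[list[SpotSpectrum], dict[str, str]]:
    """Full extraction: assign, average, then scale and optionally truncate.

    The processing order is mean -> min-max scale -> truncate (scaling
    before truncation); pass ``scale=False`` for raw means.  Returns the
    kept spot spectra plus a dict of excluded sample ids -> reason.
    """
    spots, _ = assign_spots(cube, mask, layout)
    kept: list[SpotSpectrum] = []
    excluded: dict[str, str] = {}
    for spot in spots:
        if exclude_boundary and spot.boundary_flag:
            excluded[spot.sample_id] = "boundary"
            continue
        try:
            ss = mean_spot_spectrum(spot, cube, min_pixels=min_pixels)
        except ValueError:
            excluded[spot.sample_id] = (
                f"too_few_good_pixels ({spot.n_pixels} < {min_pixels})"
            )
            continue
        spec = ss.spectrum
        if scale:
            spec = min_max_scale(spec)
        if truncate is not None:
            spec = truncate_spectrum(spec, *truncate)
        kept.append(SpotSpectrum(ss.sample_id, ss.class_label, spec,
                                 ss.n_pixels_used, ss.n_pixels_total,
                                 boundary_flag=ss.boundary_flag))
    return kept, excluded
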