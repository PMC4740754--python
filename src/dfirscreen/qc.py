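"""Per-pixel quality control of serum-spot hyperspectral images.

Every pixel spectrum is labelled ``good``, ``background`` (no or low
signal), ``saturated`` (clipped / non-linear absorption) or ``scatter``
(tilted or offset baseline from light-scattering artefacts).  A k-means
segmentation of min-max scaled pixel spectra provides spatial consistency:
clusters whose member majority carries a defect flag are relabelled
wholesale, which operationalises "spatially locating" poor-quality pixels.

All numeric thresholds are package defaults (documented in the methods
note); they are carried in :class:`QCParams` and echoed into every report
for auditability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import FrequencyAxis, HyperCube, Spectrum

__all__ = [
    "QCParams",
    "PixelMask",
    "LABEL_GOOD",
    "LABEL_BACKGROUND",
    "LABEL_SATURATED",
    "LABEL_SCATTER",
    "LABEL_NAMES",
    "flag_background",
    "flag_saturated",
    "flag_scatter",
    "baseline_fit",
    "kmeans_segment",
    "qc_pipeline",
]

LABEL_GOOD = 0
LABEL_BACKGROUND = 1
LABEL_SATURATED = 2
LABEL_SCATTER = 3
LABEL_NAMES = {LABEL_GOOD: "good", LABEL_BACKGROUND: "background",
               LABEL_SATURATED: "saturated", LABEL_SCATTER: "scatter"}

# Provenance codes: which rule set a pixel's label.
PROV_NONE = 0
PROV_RULE = 1
PROV_CLUSTER = 2


@dataclass(frozen=True)
class QCParams:
    """Thresholds and segmentation settings for the QC pipeline."""

    background_fraction: float = 0.05       # of max integrated absorbance
    saturation_limit_au: float = 1.8        # AU
    plateau_run: int = 3                    # consecutive points at global max
    baseline_window: tuple[float, float] = (1000.0, 1080.0)  # cm^-1, inclusive
    # Offset/slope limits sit above the intrinsic serum baseline-window
    # absorbance and tilt of the thickest deposits, so only scatter-like
    # artefacts on top of the chemistry trip them.
    max_baseline_offset_au: float = 0.6     # AU
    max_abs_slope: float = 2.5e-3           # AU per cm^-1
    negative_dip_limit_au: float = 0.05     # AU
    kmeans_k: int = 4
    kmeans_seed: int = 0
    cluster_rule: bool = True               # majority-relabel clusters
    cluster_majority: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.background_fraction < 1):
            raise ValueError("background_fraction must be in (0, 1)")
        if self.saturation_limit_au <= 0:
            raise ValueError("saturation_limit_au must be positive")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ValueError("baseline_window must be (lo, hi) with lo < hi")


@dataclass
class PixelMask:
    """Per-pixel QC labels with flag provenance and summary counts."""

    labels: np.ndarray        # int image, codes in LABEL_NAMES
    provenance: np.ndarray    # int image, PROV_* codes
    params: QCParams
    scatter_skipped: bool = False

    def __post_init__(self) -> None:
        if self.labels.shape != self.provenance.shape:
            raise ValueError("labels and provenance must have the same shape")

    @property
    def counts(self) -> dict[str, int]:
        c = {name: int(np.sum(self.labels == code))
             for code, name in LABEL_NAMES.items()}
        return c

    @property
    def n_pixels(self) -> int:
        return int(self.labels.size)

    @property
    def good(self) -> np.ndarray:
        return self.labels == LABEL_GOOD

    def summary(self) -> dict:
        return {
            "n_pixels": self.n_pixels,
            "counts": self.counts,
            "good_fraction": float(np.mean(self.good)),
            "scatter_skipped": self.scatter_skipped,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.params).items()},
        }


def _integrated_absorbance(cube: HyperCube) -> np.ndarray:
    return np.trapezoid(cube.data, x=cube.axis.values, axis=2)


def flag_background(cube: HyperCube, params: QCParams) -> np.ndarray:
    """Low-signal pixels: integrated absorbance below a fraction of the
    image maximum."""
    integ = _integrated_absorbance(cube)
    max_integ = float(integ.max())
    if max_integ <= 0:
        warnings.warn("cube has no positive integrated absorbance; "
                      "all pixels flagged background")
        return np.ones(integ.shape, dtype=bool)
    return integ < params.background_fraction * max_integ


def flag_saturated(cube: HyperCube, params: QCParams) -> np.ndarray:
    """Clipped pixels: absorbance at or above the saturation limit, or a run
    of >= ``plateau_run`` consecutive points flat at the cube's global
    maximum (a clipped plateau)."""
    over = cube.data.max(axis=2) >= params.saturation_limit_au
    gmax = cube.data.max()
    at_max = cube.data == gmax
    run = max(int(params.plateau_run), 1)
    if run <= cube.data.shape[2]:
        # sliding AND over `run` consecutive frequency points
        acc = at_max[:, :, : cube.data.shape[2] - run + 1].copy()
        for k in range(1, run):
            acc &= at_max[:, :, k: cube.data.shape[2] - run + 1 + k]
        plateau = acc.any(axis=2)
    else:
        plateau = np.zeros(cube.data.shape[:2], dtype=bool)
    return over | plateau


def baseline_fit(cube: HyperCube, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares offset and slope of each pixel over a wavenumber window.

    Returns ``(offset, slope)`` images; the offset is the fitted absorbance
    at the window's first axis point.  Raises if fewer than two axis points
    fall inside the window.
    """
    nu = cube.axis.values
    sel = (nu >= window[0]) & (nu <= window[1])
    if int(sel.sum()) < 2:
        raise ValueError(
            f"baseline window {window} intersects the axis in < 2 points"
        )
    x = nu[sel] - nu[sel][0]
    y = cube.data[:, :, sel].reshape(-1, x.size)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    shape = cube.data.shape[:2]
    return coef[0].reshape(shape), coef[1].reshape(shape)


def flag_scatter(cube: HyperCube, params: QCParams) -> np.ndarray:
    """Scatter-distorted pixels: excessive baseline slope or offset over the
    baseline window, or a negative dip anywhere in the spectrum."""
    offset, slope = baseline_fit(cube, params.baseline_window)
    dip = cube.data.min(axis=2) < -params.negative_dip_limit_au
    return ((np.abs(slope) > params.max_abs_slope)
            | (offset > params.max_baseline_offset_au)
            | dip)


def _minmax_scale_rows(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    rng = hi - lo
    flat = rng[:, 0] <= 0
    rng[flat] = 1.0
    out = (X - lo) / rng
    out[flat] = 0.0
    return out


def kmeans_segment(cube: HyperCube, params: QCParams) -> tuple[np.ndarray, list[Spectrum]]:
    """K-means segmentation of min-max scaled pixel spectra.

    Scaling per pixel removes thickness differences so clusters reflect
    spectral shape.  Returns the cluster-label image and the per-cluster
    mean *unscaled* spectra for inspection.  Deterministic for a fixed
    ``kmeans_seed``.
    """
    X = cube.pixel_spectra()
    if params.kmeans_k > X.shape[0]:
        raise ValueError("kmeans_k exceeds the number of pixels")
    Xs = _minmax_scale_rows(X)
    # noise-free cubes can collapse to fewer distinct scaled shapes than k
    n_distinct = np.unique(Xs, axis=0).shape[0]
    if n_distinct < 2:
        raise ValueError("fewer than 2 distinct pixel spectra; nothing to segment")
    k = min(params.kmeans_k, n_distinct)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*distinct clusters.*")
        km = KMeans(n_clusters=k, random_state=params.kmeans_seed, n_init=10)
        labels = km.fit_predict(Xs)
    means = [Spectrum(cube.axis, X[labels == c].mean(axis=0))
             for c in np.unique(labels)]
    return labels.reshape(cube.data.shape[:2]), means


def qc_pipeline(cube: HyperCube, params: QCParams = QCParams()) -> PixelMask:
    """Full QC: rule flags with priority background > saturated > scatter >
    good, then the cluster-majority spatial-consistency relabelling.

    If the baseline window intersects the axis in fewer than two points
    (e.g. the 9-frequency preset has no low-frequency baseline points) the
    scatter rule is skipped with a warning and recorded in the mask.
    """
    bg = flag_background(cube, params)
    sat = flag_saturated(cube, params)
    scatter_skipped = False
    try:
        sca = flag_scatter(cube, params)
    except ValueError:
        warnings.warn("baseline window has < 2 axis points; scatter rule skipped")
        sca = np.zeros(cube.data.shape[:2], dtype=bool)
        scatter_skipped = True

    labels = np.full(cube.data.shape[:2], LABEL_GOOD, dtype=np.int16)
    labels[sca] = LABEL_SCATTER
    labels[sat] = LABEL_SATURATED
    labels[bg] = LABEL_BACKGROUND
    provenance = np.where(labels != LABEL_GOOD, PROV_RULE, PROV_NONE).astype(np.int16)

    if params.cluster_rule:
        clusters, _ = kmeans_segment(cube, params)
        for c in np.unique(clusters):
            member = clusters == c
            member_labels = labels[member]
            defect = member_labels != LABEL_GOOD
            if defect.mean() > params.cluster_majority:
                # modal defect among flagged members
                codes, freq = np.unique(member_labels[defect], return_counts=True)
                modal = int(codes[np.argmax(freq)])
                relabel = member & (labels == LABEL_GOOD)
                labels[relabel] = modal
                provenance[relabel] = PROV_CLUSTER
    return PixelMask(labels=labels, provenance=provenance, params=params,
                     scatter_skipped=scatter_skipped)
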