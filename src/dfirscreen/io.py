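"""ENVI-style cube I/O and CSV spectra tables.

Cubes are stored as a plain-text ENVI header (``<base>.hdr``) next to a raw
binary payload (``<base>.img``): band-sequential (BSQ) interleave,
little-endian IEEE-754 float32 (ENVI data type 4), wavelengths in cm^-1
recorded ascending in the header.  Only this subset of the ENVI dialect is
read or written.  Spectra tables are CSV with the wavenumber as the first
column and one column per sample.
"""

from __future__ import annotations

import os
import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FrequencyAxis, HyperCube, Spectrum

__all__ = [
    "write_cube",
    "read_cube",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_mask_envi",
    "read_mask_envi",
]

_DTYPE_CODES = {4: np.dtype("<f4"), 2: np.dtype("<i2"), 3: np.dtype("<i4")}
_CODE_FOR_DTYPE = {np.dtype("float32"): 4, np.dtype("int16"): 2, np.dtype("int32"): 3}


def _paths(path: str) -> tuple[str, str]:
    base, ext = os.path.splitext(path)
    if ext.lower() == ".hdr":
        return path, base + ".img"
    if ext:
        return base + ".hdr", path
    return path + ".hdr", path + ".img"


def _format_header(fields: Mapping[str, object]) -> str:
    lines = ["ENVI"]
    for key, val in fields.items():
        if isinstance(val, (list, tuple, np.ndarray)):
            joined = ", ".join(f"{v:.17g}" if isinstance(v, (int, float, np.floating)) else str(v)
                               for v in val)
            lines.append(f"{key} = {{ {joined} }}")
        else:
            lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict[str, object]:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    body = text.lstrip()[4:]
    fields: dict[str, object] = {}
    # key = value, where value may be a { ... } block spanning lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        raw = m.group(2).strip()
        if raw.startswith("{"):
            items = [s.strip() for s in raw[1:-1].replace("\n", " ").split(",") if s.strip()]
            fields[key] = items
        else:
            fields[key] = raw
    return fields


def write_cube(path: str, cube: HyperCube) -> str:
    """Write ``cube`` as an ENVI header/raw pair; returns the header path.

    Data are stored as little-endian float32, BSQ.  Cubes already in
    float32 round-trip bit-identically.
    """
    hdr_path, img_path = _paths(path)
    rows, cols, bands = cube.shape
    data = np.ascontiguousarray(
        np.transpose(cube.data, (2, 0, 1)).astype("<f4", copy=False)
    )
    fields = {
        "samples": cols,
        "lines": rows,
        "bands": bands,
        "header offset": 0,
        "file type": "ENVI Standard",
        "data type": 4,
        "interleave": "bsq",
        "byte order": 0,
        "wavelength units": "cm-1",
        "pixel size um": f"{cube.pixel_size_um:.17g}",
        "wavelength": cube.axis.values,
    }
    with open(hdr_path, "w") as fh:
        fh.write(_format_header(fields))
    data.tofile(img_path)
    return hdr_path


def read_cube(path: str) -> HyperCube:
    """Read an ENVI header/raw pair written by :func:`write_cube`."""
    hdr_path, img_path = _paths(path)
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())
    try:
        rows = int(fields["lines"])  # type: ignore[arg-type]
        cols = int(fields["samples"])  # type: ignore[arg-type]
        bands = int(fields["bands"])  # type: ignore[arg-type]
        dtype_code = int(fields.get("data type", 4))  # type: ignore[arg-type]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed ENVI header {hdr_path}: {exc}") from exc
    interleave = str(fields.get("interleave", "bsq")).lower()
    if interleave != "bsq":
        raise ValueError(f"unsupported interleave {interleave!r} (only bsq)")
    if int(fields.get("byte order", 0)) != 0:  # type: ignore[arg-type]
        raise ValueError("unsupported byte order (only little-endian)")
    try:
        dtype = _DTYPE_CODES[dtype_code]
    except KeyError:
        raise ValueError(f"unsupported ENVI data type {dtype_code}") from None
    wavelengths = fields.get("wavelength")
    if wavelengths is None:
        raise ValueError("header missing wavelength list")
    axis = FrequencyAxis(np.asarray([float(w) for w in wavelengths]))
    if len(axis) != bands:
        raise ValueError("wavelength list length does not match band count")
    expected = rows * cols * bands
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != expected:
        raise ValueError(
            f"payload has {raw.size} values but header declares {expected} "
            f"({rows}x{cols}x{bands})"
        )
    data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    pixel_size = float(fields.get("pixel size um", 1.0))  # type: ignore[arg-type]
    return HyperCube(np.ascontiguousarray(data), axis, pixel_size_um=pixel_size)


def write_mask_envi(path: str, labels: np.ndarray, pixel_size_um: float = 1.0) -> str:
    """Write an integer label image as a single-band ENVI pair."""
    hdr_path, img_path = _paths(path)
    lab = np.asarray(labels, dtype="<i2")
    if lab.ndim != 2:
        raise ValueError("label image must be 2-D")
    fields = {
        "samples": lab.shape[1],
        "lines": lab.shape[0],
        "bands": 1,
        "header offset": 0,
        "file type": "ENVI Classification",
        "data type": 2,
        "interleave": "bsq",
        "byte order": 0,
        "pixel size um": f"{pixel_size_um:g}",
    }
    with open(hdr_path, "w") as fh:
        fh.write(_format_header(fields))
    np.ascontiguousarray(lab).tofile(img_path)
    return hdr_path


def read_mask_envi(path: str) -> np.ndarray:
    hdr_path, img_path = _paths(path)
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())
    rows = int(fields["lines"])  # type: ignore[arg-type]
    cols = int(fields["samples"])  # type: ignore[arg-type]
    dtype = _DTYPE_CODES[int(fields.get("data type", 2))]  # type: ignore[arg-type]
    raw = np.fromfile(img_path, dtype=dtype)
    if raw.size != rows * cols:
        raise ValueError("mask payload/header mismatch")
    return raw.reshape(rows, cols).astype(np.int16)


def write_spectra_csv(path: str, spectra: Sequence[Spectrum],
                      names: Sequence[str] | None = None) -> None:
    """Write spectra sharing one axis as a CSV table (wavenumber + columns)."""
    if not spectra:
        raise ValueError("no spectra to write")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis != axis:
            raise ValueError("all spectra must share one axis")
    if names is None:
        names = [f"sample_{i + 1}" for i in range(len(spectra))]
    if len(names) != len(spectra):
        raise ValueError("one name per spectrum required")
    df = pd.DataFrame({"wavenumber_cm1": axis.values})
    for name, s in zip(names, spectra):
        df[name] = s.absorbance
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str) -> tuple[list[Spectrum], list[str]]:
    """Read a spectra CSV; returns (spectra, sample names)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("spectra CSV needs a wavenumber column plus >=1 sample")
    axis = FrequencyAxis(df.iloc[:, 0].to_numpy(dtype=float))
    names = list(df.columns[1:])
    spectra = [Spectrum(axis, df[c].to_numpy(dtype=float)) for c in names]
    return spectra, names
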