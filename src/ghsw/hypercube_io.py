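"""Hypercube data model, ENVI I/O, radiometric calibration, background masking.

A transmittance hypercube is a 3-D array indexed ``(row, col, band)`` with a
strictly increasing wavelength axis in nm.  Raw detector counts become
transmittance through the standard two-point calibration

    T = (raw - dark) / (white - dark)

where the dark reference (lens capped, source off) defines 0% transmittance
and the white reference (bare glass plate) defines 100%.  On a calibrated
cube the bright glass-plate background sits near 1, so foreground (root)
pixels are those whose band-averaged transmittance falls below a threshold.

Files use the ENVI convention: an ASCII ``.hdr`` describing dimensions,
interleave (BSQ/BIL/BIP), data type and wavelength list, next to a raw
binary cube.  Pixel indexing is 0-based ``(row, col)``; the scan axis is
rows, matching line-scan (pushbroom) acquisition where each frame is one
spatial line x all bands.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Malformed or internally inconsistent file content."""


class GeometryError(ValueError):
    """Array shapes that do not match where they must."""


# ENVI data type codes <-> numpy dtypes (the subset a transmittance
# pipeline meets in practice).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """3-D transmittance (or raw-count) array with a wavelength axis.

    Parameters
    ----------
    values
        Array of shape ``(rows, cols, bands)``.
    wavelengths
        Band centers in nm, strictly increasing, length = number of bands.
    meta
        Free-form provenance: source file, calibration state, counters.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError(
                f"cube must be 3-D (row, col, band); got ndim={self.values.ndim}"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise GeometryError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.meta.get("calibrated") and not np.all(np.isfinite(self.values)):
            raise ValueError("calibrated cube contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band center nearest ``wavelength_nm``.

        Raises ``ValueError`` if the request lies outside the axis range,
        listing the nearest available band centers.
        """
        wl = self.wavelengths
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside axis range "
                f"[{wl[0]:.1f}, {wl[-1]:.1f}] nm; nearest available bands: "
                f"{wl[0]:.1f} and {wl[-1]:.1f} nm"
            )
        return int(np.argmin(np.abs(wl - wavelength_nm)))


@dataclass
class ReferencePair:
    """Dark and white reference images for two-point calibration.

    Each reference is either a full cube ``(rows, cols, bands)`` or a
    per-line frame ``(cols, bands)`` that is broadcast along the scan
    (row) axis — the natural shape for line-scan acquisition, where one
    reference frame covers every scan line.
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise GeometryError(
                f"dark shape {self.dark.shape} != white shape {self.white.shape}"
            )
        if self.dark.ndim not in (2, 3):
            raise GeometryError("references must be 2-D (col, band) or 3-D cubes")
        frac_ok = np.mean(self.white >= self.dark)
        if frac_ok < 0.99:
            warnings.warn(
                f"white < dark on {100 * (1 - frac_ok):.1f}% of elements; "
                "check reference acquisition",
                stacklevel=2,
            )

    def broadcast_to(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (dark, white) expanded to the full cube shape."""
        if self.dark.ndim == 3:
            if self.dark.shape != shape:
                raise GeometryError(
                    f"reference shape {self.dark.shape} != cube shape {shape}"
                )
            return self.dark, self.white
        if self.dark.shape != shape[1:]:
            raise GeometryError(
                f"per-line reference shape {self.dark.shape} does not match "
                f"cube (col, band) shape {shape[1:]}"
            )
        return (
            np.broadcast_to(self.dark, shape),
            np.broadcast_to(self.white, shape),
        )


@dataclass
class SampleMask:
    """Boolean foreground map: True = root pixel, False = background."""

    mask: np.ndarray
    n_foreground: int = -1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise GeometryError("mask must be 2-D")
        count = int(self.mask.sum())
        if self.n_foreground == -1:
            self.n_foreground = count
        elif self.n_foreground != count:
            raise ValueError(
                f"n_foreground={self.n_foreground} but mask has {count} true pixels"
            )


# ---------------------------------------------------------------------------
# ENVI format


def _parse_header(text: str, path: Path) -> dict[str, Any]:
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError(f"{path}: missing ENVI magic line")
    # Collapse brace-delimited multi-line values onto one line.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, Any] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            inner = val.strip("{}").strip()
            fields[key] = [v.strip() for v in inner.split(",") if v.strip()]
        else:
            fields[key] = val
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI header + binary pair into a :class:`HyperCube`.

    ``path`` names the ``.hdr`` file; the companion binary is the same
    path without the ``.hdr`` suffix (or with ``.dat`` appended if the
    bare name does not exist).
    """
    hdr_path = Path(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_header(hdr_path.read_text(), hdr_path)

    for required in ("samples", "lines", "bands", "data type", "interleave"):
        if required not in fields:
            raise FormatError(f"{hdr_path}: missing required header field '{required}'")
    samples = int(fields["samples"])  # cols
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported data type code {dtype_code}")
    interleave = str(fields["interleave"]).lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"{hdr_path}: unsupported interleave '{interleave}'")
    byte_order = int(fields.get("byte order", 0))
    if "wavelength" not in fields:
        raise FormatError(
            f"{hdr_path}: header has no wavelength list; supply a wavelength "
            "axis in the header ('wavelength = {...}')"
        )
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if len(wavelengths) != bands:
        raise FormatError(
            f"{hdr_path}: wavelength list length {len(wavelengths)} != bands {bands}"
        )

    bin_path = hdr_path.with_suffix("")
    if not bin_path.exists():
        alt = hdr_path.with_suffix(".dat")
        if alt.exists():
            bin_path = alt
        else:
            raise FileNotFoundError(
                f"companion binary for {hdr_path} not found ({bin_path} or {alt})"
            )

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")
    data = np.fromfile(bin_path, dtype=dtype)
    expected = samples * lines * bands
    if data.size != expected:
        raise FormatError(
            f"{bin_path}: binary holds {data.size} elements but header declares "
            f"{lines} lines x {samples} samples x {bands} bands = {expected}"
        )
    if interleave == "bsq":  # (band, row, col)
        values = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":  # (row, band, col)
        values = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip: (row, col, band)
        values = data.reshape(lines, samples, bands)

    meta: dict[str, Any] = {"source": str(hdr_path), "interleave": interleave}
    if "description" in fields:
        desc = fields["description"]
        meta["description"] = ", ".join(desc) if isinstance(desc, list) else desc
    if str(fields.get("calibrated", "")).lower() in ("1", "true", "yes"):
        meta["calibrated"] = True
    return HyperCube(values=np.ascontiguousarray(values), wavelengths=wavelengths, meta=meta)


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> None:
    """Write ``cube`` as an ENVI header + raw binary pair.

    ``path`` names the ``.hdr``; the binary is written next to it without
    the suffix.  Round-trips losslessly through :func:`read_envi`.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    hdr_path = Path(path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    bin_path = hdr_path.with_suffix("")

    values = cube.values
    if np.dtype(values.dtype) not in _DTYPE_CODES:
        values = values.astype(np.float64)
    rows, cols, bands = values.shape

    if interleave == "bsq":
        ordered = values.transpose(2, 0, 1)
    elif interleave == "bil":
        ordered = values.transpose(0, 2, 1)
    else:
        ordered = values

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"description = {{{cube.meta.get('description', 'ghsw hypercube')}}}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(values.dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
    ]
    if cube.meta.get("calibrated"):
        lines.append("calibrated = 1")
    hdr_path.write_text("\n".join(lines) + "\n")
    np.ascontiguousarray(ordered).tofile(bin_path)


# ---------------------------------------------------------------------------
# Calibration and background masking


def calibrate(
    raw: HyperCube, refs: ReferencePair, epsilon: float | None = None
) -> HyperCube:
    """Two-point radiometric calibration to transmittance.

    Computes ``(raw - dark) / (white - dark)`` elementwise.  Pixels where
    ``|white - dark|`` falls below ``epsilon`` (default: 1e-6 of the white
    reference's dynamic range) are set to 0 and counted in
    ``meta['n_zero_denominator']`` so dead detector elements cannot
    propagate infinities.

    The output is flagged ``meta['calibrated'] = True``; feeding an
    already-calibrated cube warns but proceeds.
    """
    dark, white = refs.broadcast_to(raw.values.shape)
    if raw.meta.get("calibrated"):
        warnings.warn("input cube is already flagged calibrated; proceeding", stacklevel=2)

    if epsilon is None:
        dynamic = float(np.ptp(refs.white))
        epsilon = 1e-6 * dynamic if dynamic > 0 else 1e-6
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    denom = white - dark
    bad = np.abs(denom) < epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (raw.values.astype(float) - dark) / denom
    out[bad] = 0.0
    meta = dict(raw.meta)
    meta.update(calibrated=True, n_zero_denominator=int(bad.sum()))
    return HyperCube(values=out, wavelengths=raw.wavelengths.copy(), meta=meta)


def segment_background(cube: HyperCube, threshold: float = 0.85) -> SampleMask:
    """Separate root pixels from the bright glass-plate background.

    On a calibrated cube the background transmits near 1, so foreground is
    every pixel whose band-averaged transmittance is below ``threshold``.
    Only the largest 4-connected foreground component is kept, removing
    stray speckle.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if not cube.meta.get("calibrated"):
        warnings.warn(
            "segmenting an uncalibrated cube; band-averaged counts may not "
            "separate background from sample",
            stacklevel=2,
        )
    mean_img = cube.values.mean(axis=2)
    fg = mean_img < threshold
    if not fg.any():
        raise ValueError(f"no sample detected at threshold {threshold}")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return SampleMask(mask=fg)
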