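"""Topography containers and on-disk formats.

A hopping-mode SICM scan is a grid of surface heights (micrometres) sampled
on a regular lateral pitch.  The enhancement pipeline operates on an 8-bit
grayscale rendering of that grid, so this module provides the two containers
(:class:`HeightMap`, :class:`GrayImage`), the invertible linear map between
them, and readers/writers for the plain-text and raster formats the rest of
the package exchanges:

* CSV matrix (one row per line, comma separated) for height maps,
* 16-bit single-channel TIFF or PGM (P5, maxval 65535) with a JSON sidecar
  ``{"h_min": ..., "h_max": ..., "pixel_pitch": ...}`` recording the linear
  height scale,
* 8-bit PNG/PGM for grayscale images and edge masks.

Conventions: row-major ``(row, col)`` indexing, 0-based, pixel centers on the
integer lattice.  The grayscale map is linear min-max with round-half-up; a
flat map (``h_min == h_max``) renders as all zeros so the map stays total.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from PIL import Image

from .errors import ConfigurationError, DataError, FormatError

__all__ = [
    "HeightMap",
    "GrayImage",
    "EdgeMap",
    "read_height_map",
    "write_height_map",
    "height_to_gray",
    "gray_to_height",
    "read_gray",
    "write_gray",
    "round_half_up",
]

_PGM_MAXVAL = 65535


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1).

    numpy's ``round`` uses banker's rounding; the pipeline needs the
    conventional half-up rule so that e.g. 127.5 renders as 128.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class HeightMap:
    """A rectangular grid of surface heights in micrometres.

    Parameters
    ----------
    heights
        2-D array of finite heights (µm).
    pixel_pitch
        Lateral step between adjacent pixels (µm per pixel), > 0.
    label
        Free-text description carried through the pipeline.
    """

    heights: np.ndarray
    pixel_pitch: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.heights, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("heights must be a non-empty 2-D grid")
        if not np.isfinite(arr).all():
            raise DataError("height map contains NaN or infinite values")
        if not (self.pixel_pitch > 0):
            raise ValueError("pixel_pitch must be positive")
        self.heights = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def h_min(self) -> float:
        return float(self.heights.min())

    @property
    def h_max(self) -> float:
        return float(self.heights.max())


@dataclass
class GrayImage:
    """An integer image on ``[0, 2**bit_depth - 1]`` plus its height scale.

    ``h_min``/``h_max`` record the linear map used when the image was
    rendered from a :class:`HeightMap`, so the conversion can be inverted.
    Images loaded from bare rasters have no scale (``None``) and cannot be
    converted back to heights until one is attached.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    h_min: Optional[float] = None
    h_max: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.int64)
        if arr.min() < 0 or arr.max() > self.peak:
            raise ValueError(
                f"pixel values must lie in [0, {self.peak}] for {self.bit_depth}-bit images"
            )
        if (self.h_min is None) != (self.h_max is None):
            raise ConfigurationError("h_min and h_max must be set together")
        if self.h_min is not None and self.h_min > self.h_max:
            raise ValueError("h_min must not exceed h_max")
        self.pixels = arr.astype(np.int64)

    @property
    def peak(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def has_scale(self) -> bool:
        return self.h_min is not None

    def same_scale(self, other: "GrayImage", rtol: float = 1e-9) -> bool:
        if not (self.has_scale() and other.has_scale()):
            return True  # nothing recorded, nothing to contradict
        return bool(
            math.isclose(self.h_min, other.h_min, rel_tol=rtol, abs_tol=1e-12)
            and math.isclose(self.h_max, other.h_max, rel_tol=rtol, abs_tol=1e-12)
        )


@dataclass
class EdgeMap:
    """A binary edge mask at a stated resolution factor (1 = native, 2 = upscaled)."""

    mask: np.ndarray
    resolution_factor: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("edge mask values must be strictly binary")
            arr = arr.astype(bool)
        if self.resolution_factor < 1:
            raise ValueError("resolution_factor must be >= 1")
        self.mask = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# height map I/O
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "tiff16", "pgm16")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext == ".csv":
        return "csv"
    if ext in (".tif", ".tiff"):
        return "tiff16"
    if ext == ".pgm":
        return "pgm16"
    raise FormatError(f"cannot infer height-map format from extension {ext!r}")


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    if not rows:
        raise FormatError(f"{path}: empty CSV matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged CSV rows (expected {width} columns)")
    arr = np.asarray(rows, dtype=float)
    if not np.isfinite(arr).all():
        raise DataError(f"{path}: NaN or infinite cells")
    return arr


def _read_pgm16(path: Path) -> np.ndarray:
    # Minimal P5 reader (netpbm binary grayscale); Pillow's 16-bit PGM
    # handling round-trips unreliably across versions, and the format is a
    # three-token header plus big-endian samples.
    data = path.read_bytes()
    tokens: list[bytes] = []
    pos = 0
    while len(tokens) < 4 and pos < len(data):
        m = re.compile(rb"\s*(#[^\n]*\n)*\s*(\S+)").match(data, pos)
        if m is None:
            break
        tokens.append(m.group(2))
        pos = m.end()
    if len(tokens) < 4 or tokens[0] != b"P5":
        raise FormatError(f"{path}: not a binary PGM (P5) file")
    width, height, maxval = (int(t) for t in tokens[1:4])
    if maxval != _PGM_MAXVAL:
        raise FormatError(f"{path}: expected 16-bit PGM (maxval {_PGM_MAXVAL})")
    raster = data[pos + 1 :]  # single whitespace byte after maxval
    expected = width * height * 2
    if len(raster) < expected:
        raise FormatError(f"{path}: truncated PGM raster")
    arr = np.frombuffer(raster[:expected], dtype=">u2").reshape(height, width)
    return arr.astype(np.uint16)


def _write_pgm16(path: Path, arr: np.ndarray) -> None:
    h, w = arr.shape
    header = f"P5\n{w} {h}\n{_PGM_MAXVAL}\n".encode("ascii")
    path.write_bytes(header + arr.astype(">u2").tobytes())


def _load_sidecar(path: Path) -> dict:
    sp = _sidecar_path(path)
    if not sp.exists():
        raise ConfigurationError(
            f"{path}: 16-bit rasters need a JSON sidecar {sp.name} with h_min/h_max/pixel_pitch"
        )
    meta = json.loads(sp.read_text())
    for key in ("h_min", "h_max", "pixel_pitch"):
        if key not in meta:
            raise ConfigurationError(f"{sp}: sidecar missing {key!r}")
    return meta


def read_height_map(path, fmt: Optional[str] = None, pixel_pitch: float = 1.0) -> HeightMap:
    """Read a :class:`HeightMap` from CSV, 16-bit TIFF or 16-bit PGM.

    Raster formats carry their height scale and pitch in a JSON sidecar
    (``<name>.json`` next to the file); CSV stores heights directly and
    takes the pitch from the sidecar if present, else from ``pixel_pitch``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown height-map format {fmt!r}")
    if fmt == "csv":
        arr = _read_csv_matrix(path)
        sp = _sidecar_path(path)
        if sp.exists():
            pixel_pitch = float(json.loads(sp.read_text()).get("pixel_pitch", pixel_pitch))
        return HeightMap(arr, pixel_pitch=pixel_pitch, label=path.stem)
    meta = _load_sidecar(path)
    if fmt == "tiff16":
        raw = tifffile.imread(path)
        if raw.ndim != 2:
            raise FormatError(f"{path}: expected a single-channel 2-D TIFF")
        raw = raw.astype(np.uint16)
    else:
        raw = _read_pgm16(path)
    h_min, h_max = float(meta["h_min"]), float(meta["h_max"])
    heights = h_min + raw.astype(float) / _PGM_MAXVAL * (h_max - h_min)
    return HeightMap(heights, pixel_pitch=float(meta["pixel_pitch"]), label=path.stem)


def write_height_map(hmap: HeightMap, path, fmt: Optional[str] = None) -> None:
    """Write a :class:`HeightMap`; 16-bit formats use linear min-max scaling
    and emit the JSON sidecar needed to invert it."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown height-map format {fmt!r}")
    if fmt == "csv":
        lines = "\n".join(",".join(f"{v:.10g}" for v in row) for row in hmap.heights)
        path.write_text(lines + "\n", encoding="utf-8")
        _sidecar_path(path).write_text(
            json.dumps({"pixel_pitch": hmap.pixel_pitch}, indent=2)
        )
        return
    h_min, h_max = hmap.h_min, hmap.h_max
    span = h_max - h_min
    if span > 0:
        raw = round_half_up((hmap.heights - h_min) / span * _PGM_MAXVAL)
    else:
        raw = np.zeros_like(hmap.heights)
    raw = np.clip(raw, 0, _PGM_MAXVAL).astype(np.uint16)
    if fmt == "tiff16":
        tifffile.imwrite(path, raw)
    else:
        _write_pgm16(path, raw)
    _sidecar_path(path).write_text(
        json.dumps(
            {"h_min": h_min, "h_max": h_max, "pixel_pitch": hmap.pixel_pitch}, indent=2
        )
    )


# ---------------------------------------------------------------------------
# 3D <-> 2D conversion
# ---------------------------------------------------------------------------


def height_to_gray(
    hmap: HeightMap,
    bit_depth: int = 8,
    h_range: Optional[tuple[float, float]] = None,
) -> GrayImage:
    """Render a height map as a grayscale image via linear min-max scaling.

    ``pixel = round_half_up((h - h_min) / (h_max - h_min) * (2**B - 1))``.

    ``h_range`` pins the scale explicitly (heights outside it are clipped),
    which is how two maps are rendered onto a common grid for comparison.
    A degenerate flat map renders as all zeros with the scale retained.
    """
    if h_range is None:
        h_min, h_max = hmap.h_min, hmap.h_max
    else:
        h_min, h_max = float(h_range[0]), float(h_range[1])
        if h_min > h_max:
            raise ValueError("h_range must be (min, max) with min <= max")
    peak = (1 << bit_depth) - 1
    span = h_max - h_min
    if span == 0:
        px = np.zeros(hmap.shape, dtype=np.int64)
    else:
        px = round_half_up((hmap.heights - h_min) / span * peak)
        px = np.clip(px, 0, peak).astype(np.int64)
    return GrayImage(px, bit_depth=bit_depth, h_min=h_min, h_max=h_max)


def gray_to_height(img: GrayImage, pixel_pitch: float = 1.0, label: str = "") -> HeightMap:
    """Invert :func:`height_to_gray` using the recorded scale.

    ``h = h_min + pixel / (2**B - 1) * (h_max - h_min)``.
    """
    if not img.has_scale():
        raise ConfigurationError(
            "gray image has no h_min/h_max scale metadata; cannot recover heights"
        )
    heights = img.h_min + img.pixels.astype(float) / img.peak * (img.h_max - img.h_min)
    return HeightMap(heights, pixel_pitch=pixel_pitch, label=label)


# ---------------------------------------------------------------------------
# 8-bit grayscale raster I/O
# ---------------------------------------------------------------------------


def write_gray(img: GrayImage, path) -> None:
    """Write an 8-bit grayscale image as PNG/PGM, plus a scale sidecar if known."""
    path = Path(path)
    if img.bit_depth != 8:
        raise FormatError("only 8-bit grayscale raster export is supported")
    Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(path)
    if img.has_scale():
        _sidecar_path(path).write_text(
            json.dumps({"h_min": img.h_min, "h_max": img.h_max}, indent=2)
        )


def read_gray(path) -> GrayImage:
    """Read an 8-bit grayscale PNG/PGM, picking up a scale sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.int64)
    h_min = h_max = None
    sp = _sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
        h_min, h_max = meta.get("h_min"), meta.get("h_max")
    return GrayImage(arr, bit_depth=8, h_min=h_min, h_max=h_max)
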