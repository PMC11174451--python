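"""Canny edge detection and edge-map expansion to the 2x target lattice.

The edge map gates the interpolation stage: pixels inside the (dilated,
upscaled) edge band are filled by edge-directed interpolation, everything
else by separable bilinear interpolation.  The detector is the canonical
four-stage Canny chain — Gaussian smoothing, Sobel gradients, non-maximum
suppression along the quantized gradient direction, double-threshold
hysteresis linking — with hysteresis thresholds expressed as fractions of
the maximum gradient magnitude so the defaults are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .topo import EdgeMap, GrayImage

__all__ = ["CannyConfig", "canny_edges", "upscale_edge_map"]


@dataclass(frozen=True)
class CannyConfig:
    """Canny detector settings.

    ``low_frac``/``high_frac`` are the hysteresis thresholds as fractions of
    the maximum smoothed gradient magnitude; ``dilation_radius`` is used by
    :func:`upscale_edge_map` when expanding the mask to the 2x lattice.
    """

    gaussian_sigma: float = 1.0
    low_frac: float = 0.1
    high_frac: float = 0.25
    dilation_radius: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.low_frac < self.high_frac <= 1):
            raise ValueError("need 0 < low_frac < high_frac <= 1")
        if not (self.gaussian_sigma > 0):
            raise ValueError("gaussian_sigma must be positive")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be non-negative")


def _smoothed_gradient(arr: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    smoothed = ndimage.gaussian_filter(arr, sigma=sigma, mode="nearest")
    gr = ndimage.sobel(smoothed, axis=0, mode="nearest")  # d/d(row)
    gc = ndimage.sobel(smoothed, axis=1, mode="nearest")  # d/d(col)
    return np.hypot(gr, gc), gr, gc


def _nonmax_suppress(mag: np.ndarray, gr: np.ndarray, gc: np.ndarray) -> np.ndarray:
    """Thin ridges to one pixel across the quantized gradient direction.

    The comparison is strict toward the +gradient neighbor and non-strict
    toward the -gradient neighbor, so an exactly symmetric two-pixel ridge
    keeps a single deterministic side instead of both or neither.
    """
    angle = np.mod(np.degrees(np.arctan2(gr, gc)), 180.0)
    # sector -> (dr, dc) of the +gradient neighbor
    sector_offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    sectors = np.zeros(mag.shape, dtype=np.int8)
    sectors[(angle >= 22.5) & (angle < 67.5)] = 1
    sectors[(angle >= 67.5) & (angle < 112.5)] = 2
    sectors[(angle >= 112.5) & (angle < 157.5)] = 3

    padded = np.pad(mag, 1, mode="constant")
    keep = np.zeros(mag.shape, dtype=bool)
    for sec, (dr, dc) in sector_offsets.items():
        sel = sectors == sec
        fwd = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        bwd = padded[1 - dr : padded.shape[0] - 1 - dr, 1 - dc : padded.shape[1] - 1 - dc]
        keep |= sel & (mag > fwd) & (mag >= bwd)
    return keep


def canny_edges(img: GrayImage, cfg: CannyConfig = CannyConfig()) -> EdgeMap:
    """Detect edges in a grayscale image; returns a native-resolution mask.

    The output is a subset of pixels whose smoothed gradient magnitude
    reaches the low threshold, connected (8-neighborhood) to at least one
    pixel reaching the high threshold.  Invariant to global additive
    intensity shifts that do not clip, since thresholds are relative to the
    maximum gradient.
    """
    if img.shape[0] < 5 or img.shape[1] < 5:
        raise ValueError("image must be at least 5x5 for edge detection")
    mag, gr, gc = _smoothed_gradient(img.pixels.astype(float), cfg.gaussian_sigma)
    gmax = float(mag.max())
    if gmax == 0.0:
        return EdgeMap(np.zeros(img.shape, dtype=bool), resolution_factor=1)
    keep = _nonmax_suppress(mag, gr, gc)
    strong = keep & (mag >= cfg.high_frac * gmax)
    weak = keep & (mag >= cfg.low_frac * gmax)
    linked = ndimage.binary_propagation(strong, structure=np.ones((3, 3), bool), mask=weak)
    return EdgeMap(linked, resolution_factor=1)


def upscale_edge_map(edges: EdgeMap, factor: int = 2, dilation_radius: int = 1) -> EdgeMap:
    """Expand a native-resolution edge mask to the 2x interpolation lattice.

    Nearest-neighbor 2x magnification followed by morphological dilation
    with a square element of the given radius, so the band covers every
    high-resolution lattice site adjacent to a low-resolution edge pixel.
    Monotone: a larger input mask yields a larger output mask.
    """
    if factor != 2:
        raise ValueError("only 2x edge-map expansion is defined")
    if edges.resolution_factor != 1:
        raise ValueError("input edge map must be at native resolution (factor 1)")
    up = np.repeat(np.repeat(edges.mask, 2, axis=0), 2, axis=1)
    if dilation_radius > 0:
        size = 2 * dilation_radius + 1
        up = ndimage.binary_dilation(up, structure=np.ones((size, size), bool))
    return EdgeMap(up, resolution_factor=2)
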