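"""Denoising stage: median filter (the method of choice for the isolated
spike noise of fast hopping scans) plus mean/Gaussian/wavelet baselines and
a comparison harness that ranks them by PSNR against a reference.

All filters preserve shape, bit depth and height-scale metadata; borders use
replicate (edge) padding; outputs are rounded half-up and clamped to the
pixel range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import ndimage

from .topo import GrayImage, round_half_up

__all__ = ["FilterSpec", "FilterComparison", "denoise_image", "compare_filters"]

_METHODS = ("median", "mean", "gaussian", "wavelet")


@dataclass(frozen=True)
class FilterSpec:
    """One denoising filter configuration.

    ``kernel`` is the square window side for median/mean/gaussian (odd,
    >= 3).  ``sigma`` applies to the Gaussian kernel only (defaults to
    kernel/4 when unset, a conventional fit of the mass to the window).
    The wavelet baseline is a single-level decomposition with universal soft
    thresholding of the detail coefficients (MAD noise estimate).
    """

    method: str = "median"
    kernel: int = 3
    sigma: Optional[float] = None
    wavelet_name: str = "haar"
    threshold_rule: str = "universal"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown filter method {self.method!r}; pick from {_METHODS}")
        if self.kernel < 3 or self.kernel % 2 == 0:
            raise ValueError("kernel must be an odd integer >= 3")
        if self.sigma is not None and not (self.sigma > 0):
            raise ValueError("sigma must be positive when given")
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")


def _wavelet_denoise(arr: np.ndarray, spec: FilterSpec) -> np.ndarray:
    approx, details = pywt.dwt2(arr, spec.wavelet_name, mode="symmetric")
    cH, cV, cD = details
    # universal threshold sigma_hat * sqrt(2 ln n); sigma_hat from the MAD of
    # the diagonal detail band
    sigma_hat = np.median(np.abs(cD)) / 0.6745 if cD.size else 0.0
    thr = sigma_hat * math.sqrt(2.0 * math.log(max(arr.size, 2)))
    # explicit soft shrinkage (sign(c) * max(|c| - t, 0)); well-defined at 0
    details = tuple(
        np.sign(c) * np.maximum(np.abs(c) - thr, 0.0) for c in (cH, cV, cD)
    )
    out = pywt.idwt2((approx, details), spec.wavelet_name, mode="symmetric")
    return out[: arr.shape[0], : arr.shape[1]]  # idwt2 pads odd sizes


def denoise_image(img: GrayImage, spec: FilterSpec) -> GrayImage:
    """Apply one filter to an image; see :class:`FilterSpec` for semantics."""
    arr = img.pixels.astype(float)
    if spec.method == "median":
        out = ndimage.median_filter(arr, size=spec.kernel, mode="nearest")
    elif spec.method == "mean":
        out = ndimage.uniform_filter(arr, size=spec.kernel, mode="nearest")
    elif spec.method == "gaussian":
        sigma = spec.sigma if spec.sigma is not None else spec.kernel / 4.0
        out = ndimage.gaussian_filter(
            arr, sigma=sigma, mode="nearest", radius=spec.kernel // 2
        )
    else:
        out = _wavelet_denoise(arr, spec)
    out = np.clip(round_half_up(out), 0, img.peak).astype(np.int64)
    return GrayImage(out, bit_depth=img.bit_depth, h_min=img.h_min, h_max=img.h_max)


@dataclass
class FilterComparison:
    """PSNR (dB) per filter against a reference, plus the unfiltered baseline."""

    psnr_db: dict[str, float] = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        """Methods sorted from best to worst PSNR (baseline included)."""
        return sorted(self.psnr_db, key=lambda m: -self.psnr_db[m])

    @property
    def best(self) -> str:
        filtered = {m: v for m, v in self.psnr_db.items() if m != "none"}
        return max(filtered, key=filtered.get)


def compare_filters(
    noisy: GrayImage,
    reference: GrayImage,
    specs: Sequence[FilterSpec],
) -> FilterComparison:
    """Denoise ``noisy`` with every spec and score each output against
    ``reference`` by PSNR; the unfiltered image is reported as ``"none"``."""
    from .metrics import psnr  # local import to keep module layering acyclic

    if not specs:
        raise ValueError("need at least one FilterSpec to compare")
    if noisy.shape != reference.shape:
        raise ValueError(f"shape mismatch: {noisy.shape} vs {reference.shape}")
    table = {"none": psnr(noisy, reference)}
    for spec in specs:
        table[spec.method] = psnr(denoise_image(noisy, spec), reference)
    return FilterComparison(psnr_db=table)


def default_comparison_specs(kernel: int = 3) -> list[FilterSpec]:
    """The four-way comparison set: gaussian, mean, median, wavelet."""
    return [
        FilterSpec(method="gaussian", kernel=kernel),
        FilterSpec(method="mean", kernel=kernel),
        FilterSpec(method="median", kernel=kernel),
        FilterSpec(method="wavelet"),
    ]
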