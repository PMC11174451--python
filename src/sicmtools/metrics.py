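"""Image-quality metrics: MSE, PSNR, global SSIM, multi-scan reference
construction and repeated-scan aggregation.

Because the true surface is generally unknowable from a single scan, the
evaluation protocol builds a reference as the per-pixel mean of many
(denoised) repeated scans, then averages the per-scan PSNR and SSIM against
that reference.  SSIM here is the global-statistics form (whole-image means,
variances and covariance), not the sliding-window variant:

    SSIM = [(2 mu1 mu2 + c1)(2 cov + c2)] / [(mu1^2 + mu2^2 + c1)(var1 + var2 + c2)]

with c_i = (k_i L)^2, L = 2^B - 1, k1 = 0.01, k2 = 0.03.

Images are compared on the integer grid after identical height scaling;
comparing images rendered with different h_min/h_max scales is an error
rather than a silent rescale.  PSNR of identical images is the +inf
sentinel; aggregation excludes sentinels and reports how many were dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .topo import GrayImage, round_half_up

__all__ = ["QualityReport", "mse", "psnr", "ssim", "build_reference", "aggregate_quality"]


@dataclass(frozen=True)
class QualityReport:
    """MSE / PSNR / SSIM for an image pair, or their means over many pairs."""

    mse: float
    psnr_db: float  # may be math.inf when the images are identical
    ssim: float
    n_images: int = 1
    n_psnr_excluded: int = 0  # +inf PSNR entries dropped from the mean

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("mse must be non-negative")
        if not (-1.0 - 1e-12 <= self.ssim <= 1.0 + 1e-12):
            raise ValueError("ssim must lie in [-1, 1]")


def _check_pair(a: GrayImage, b: GrayImage) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.bit_depth != b.bit_depth:
        raise ValueError("bit depths differ")
    if not a.same_scale(b):
        raise ValueError(
            "images were rendered with different h_min/h_max scales; "
            "re-render them on a common height range before comparing"
        )


def mse(a: GrayImage, b: GrayImage) -> float:
    """Mean squared intensity difference over all pixels."""
    _check_pair(a, b)
    diff = a.pixels.astype(float) - b.pixels.astype(float)
    return float(np.mean(diff * diff))


def psnr(a: GrayImage, b: GrayImage) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2 / MSE) in dB; +inf when
    the images are identical."""
    err = mse(a, b)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(a.peak**2 / err)


def ssim(a: GrayImage, b: GrayImage, k1: float = 0.01, k2: float = 0.03) -> float:
    """Global structural similarity in [-1, 1]; 1 means identical (up to the
    stabilizing constants for constant images)."""
    _check_pair(a, b)
    x = a.pixels.astype(float)
    y = b.pixels.astype(float)
    L = a.peak
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    return float(
        ((2 * mu_x * mu_y + c1) * (2 * cov + c2))
        / ((mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2))
    )


def build_reference(stack: Sequence[GrayImage]) -> GrayImage:
    """Per-pixel arithmetic mean of repeated scans, rounded to the integer
    grid — the stand-in for the unknown true image."""
    if not stack:
        raise ValueError("need at least one image to build a reference")
    first = stack[0]
    for img in stack[1:]:
        _check_pair(first, img)
    mean = np.mean([img.pixels for img in stack], axis=0)
    px = np.clip(round_half_up(mean), 0, first.peak).astype(np.int64)
    return GrayImage(px, bit_depth=first.bit_depth, h_min=first.h_min, h_max=first.h_max)


def aggregate_quality(pairs: Sequence[tuple[GrayImage, GrayImage]]) -> QualityReport:
    """Mean MSE/PSNR/SSIM over (image, reference) pairs.

    Identical pairs contribute a +inf PSNR sentinel which is excluded from
    the PSNR mean; ``n_psnr_excluded`` counts them.
    """
    if not pairs:
        raise ValueError("need at least one image pair")
    mses, psnrs, ssims = [], [], []
    for img, ref in pairs:
        mses.append(mse(img, ref))
        psnrs.append(psnr(img, ref))
        ssims.append(ssim(img, ref))
    finite = [p for p in psnrs if math.isfinite(p)]
    excluded = len(psnrs) - len(finite)
    mean_psnr = float(np.mean(finite)) if finite else math.inf
    return QualityReport(
        mse=float(np.mean(mses)),
        psnr_db=mean_psnr,
        ssim=float(np.mean(ssims)),
        n_images=len(pairs),
        n_psnr_excluded=excluded,
    )
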