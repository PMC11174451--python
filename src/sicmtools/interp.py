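"""Edge-directed 2x interpolation: separable bilinear upscaling, NEDI
(new edge-directed interpolation) weight estimation, the edge-gated hybrid
dispatcher, and iterated power-of-two enhancement.

NEDI exploits *geometric duality*: the orientation statistics of an edge are
the same at low and high resolution, so interpolation weights fitted from
the low-resolution covariance structure can fill high-resolution sites.
For the diagonal (odd, odd) site ``(2i+1, 2j+1)`` the estimate is

    I(2i+1, 2j+1) = sum_{a,b in {0,1}} alpha_{2a+b} * I(2(i+a), 2(j+b))

i.e. a weighted sum of the four diagonal low-resolution neighbors in
NW, NE, SW, SE order.  The weights solve the least-squares problem built
from an M x M low-resolution window (default M = 5): every window pixel is
predicted from *its* four diagonal neighbors, giving M^2 equations in 4
unknowns, solved via ridge-stabilized normal equations

    (C^T C + eps * tr(C^T C)/4 * Id) alpha = C^T y.

The remaining (even, odd)/(odd, even) sites are filled by the identical
estimator on the 45-degree-rotated lattice, where the four "diagonal"
neighbors become the axial neighbors available after the first pass.
Ill-conditioned windows (flat or nearly flat patches) fall back to bilinear,
as do sites whose training window would leave the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .denoise import FilterSpec, denoise_image
from .edges import CannyConfig, canny_edges, upscale_edge_map
from .topo import EdgeMap, GrayImage, round_half_up

__all__ = [
    "NEDIConfig",
    "NEDICoeffs",
    "bilinear_upscale",
    "nedi_coefficients",
    "nedi_upscale",
    "hybrid_upscale",
    "enhance_n",
]

# interpolation-neighbor offsets in NW, NE, SW, SE order; pass 2 uses the
# same order rotated by 45 degrees, where diagonals become axial neighbors
_DIAG = np.array([(-1, -1), (-1, 1), (1, -1), (1, 1)])
_AXIAL = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)])


@dataclass(frozen=True)
class NEDIConfig:
    """NEDI estimator settings.

    ``window_m`` is the training window side (odd, >= 3; M = 5 gives 25
    training equations for the 4 weights).  ``ridge_epsilon`` scales the
    ridge term relative to tr(C^T C)/4; ``condition_limit`` is the
    condition-number gate above which a window falls back to bilinear.
    """

    window_m: int = 5
    ridge_epsilon: float = 1e-6
    condition_limit: float = 1e8
    fallback: str = "bilinear"

    def __post_init__(self) -> None:
        if self.window_m < 3 or self.window_m % 2 == 0:
            raise ValueError("window_m must be an odd integer >= 3")
        if self.ridge_epsilon < 0:
            raise ValueError("ridge_epsilon must be non-negative")
        if self.fallback != "bilinear":
            raise ValueError("only the bilinear fallback is supported")


@dataclass(frozen=True)
class NEDICoeffs:
    """Fitted interpolation weights in NW, NE, SW, SE order."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.alpha, dtype=float)
        if arr.shape != (4,) or not np.isfinite(arr).all():
            raise ValueError("alpha must be a finite 4-vector")
        object.__setattr__(self, "alpha", arr)


def _as_array(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels.astype(float)
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    return arr


# ---------------------------------------------------------------------------
# bilinear
# ---------------------------------------------------------------------------


def _bilinear_float(arr: np.ndarray) -> np.ndarray:
    """Separable 2x upscale in real arithmetic: X-pass midpoints, then
    Y-pass midpoints, replicating the last row/column.  Low-resolution
    pixels land on the even-even lattice: ``out[2i, 2j] = arr[i, j]``."""
    h, w = arr.shape
    tmp = np.empty((h, 2 * w))
    tmp[:, 0::2] = arr
    tmp[:, 1:-1:2] = 0.5 * (arr[:, :-1] + arr[:, 1:])
    tmp[:, -1] = arr[:, -1]
    out = np.empty((2 * h, 2 * w))
    out[0::2] = tmp
    out[1:-1:2] = 0.5 * (tmp[:-1] + tmp[1:])
    out[-1] = tmp[-1]
    return out


def bilinear_upscale(img: GrayImage) -> GrayImage:
    """Separable bilinear 2x upscale; exact on constants and linear ramps."""
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    out = _bilinear_float(img.pixels.astype(float))
    out = np.clip(round_half_up(out), 0, img.peak).astype(np.int64)
    return GrayImage(out, bit_depth=img.bit_depth, h_min=img.h_min, h_max=img.h_max)


# ---------------------------------------------------------------------------
# NEDI weight estimation
# ---------------------------------------------------------------------------


def _batched_fit(
    arr: np.ndarray,
    ctr_r: np.ndarray,
    ctr_c: np.ndarray,
    win_rel: np.ndarray,
    neigh: np.ndarray,
    cfg: NEDIConfig,
    train_scale: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit alpha at many sites at once.

    ``win_rel`` holds the K training-pixel offsets relative to each window
    center; each training pixel is predicted from its 4 neighbors at
    ``train_scale`` times the interpolation offsets ``neigh`` (geometric
    duality: 1 when fitting on the low-resolution array, 2 when fitting on
    the half-filled high-resolution lattice).  Returns ``(alphas, ok)``
    where ``ok`` is False for ill-conditioned or singular windows.  The
    caller guarantees all indices are in bounds.
    """
    R = ctr_r[:, None] + win_rel[None, :, 0]  # (n, K)
    C_ = ctr_c[:, None] + win_rel[None, :, 1]
    y = arr[R, C_]  # (n, K)
    C = arr[
        R[:, :, None] + train_scale * neigh[None, None, :, 0],
        C_[:, :, None] + train_scale * neigh[None, None, :, 1],
    ]  # (n, K, 4)
    Ct = C.transpose(0, 2, 1)
    A = Ct @ C  # (n, 4, 4)
    b = (Ct @ y[:, :, None])[:, :, 0]
    with np.errstate(all="ignore"):
        conds = np.linalg.cond(A)
    ok = np.isfinite(conds) & (conds <= cfg.condition_limit)
    alphas = np.zeros((len(ctr_r), 4))
    if ok.any():
        Aok = A[ok]
        if cfg.ridge_epsilon > 0:
            ridge = cfg.ridge_epsilon * (np.trace(Aok, axis1=1, axis2=2) / 4.0)
            Aok = Aok + ridge[:, None, None] * np.eye(4)
        try:
            sol = np.linalg.solve(Aok, b[ok][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # a singular member in the batch: fall back to per-site lstsq
            sol = np.empty((int(ok.sum()), 4))
            for i, (Ai, bi) in enumerate(zip(Aok, b[ok])):
                sol[i] = np.linalg.lstsq(Ai, bi, rcond=None)[0]
        bad = ~np.isfinite(sol).all(axis=1)
        sol[bad] = 0.0
        idx = np.flatnonzero(ok)
        ok[idx[bad]] = False
        alphas[ok] = sol[~bad]
    return alphas, ok


def nedi_coefficients(
    img, site: tuple[int, int], cfg: NEDIConfig = NEDIConfig()
) -> Optional[NEDICoeffs]:
    """Fit the four NEDI weights from the M x M window centered at ``site``
    (low-resolution coordinates).

    Returns ``None`` — the fallback signal — when the window or any training
    neighbor leaves the image, or when the window covariance is too
    ill-conditioned (e.g. a constant patch).  Accepts a :class:`GrayImage`
    or a raw 2-D float array.
    """
    arr = _as_array(img)
    i, j = site
    m2 = cfg.window_m // 2
    margin = m2 + 1  # window plus its diagonal training neighbors
    if not (margin <= i < arr.shape[0] - margin and margin <= j < arr.shape[1] - margin):
        return None
    off = np.arange(-m2, m2 + 1)
    win_rel = np.array([(dr, dc) for dr in off for dc in off])
    alphas, ok = _batched_fit(
        arr, np.array([i]), np.array([j]), win_rel, _DIAG, cfg
    )
    if not ok[0]:
        return None
    return NEDICoeffs(alpha=alphas[0])


# ---------------------------------------------------------------------------
# NEDI / hybrid upscaling
# ---------------------------------------------------------------------------


def _nedi_fill(
    hr: np.ndarray,
    lr: np.ndarray,
    cfg: NEDIConfig,
    site_mask: Optional[np.ndarray],
) -> np.ndarray:
    """Overwrite interpolated sites of ``hr`` (a float 2x lattice pre-filled
    with bilinear values and LR pixels at even-even sites) with NEDI
    estimates.  ``site_mask`` restricts which HR sites are treated (None =
    all interpolated sites).  Returns the mask of sites actually estimated
    by NEDI (excluding bilinear fallbacks), used for the cleanup pass."""
    H, W = lr.shape
    m2 = cfg.window_m // 2
    used = np.zeros(hr.shape, dtype=bool)

    # pass 1: diagonal (odd, odd) sites, trained on the LR lattice
    margin = m2 + 1
    ii, jj = np.meshgrid(np.arange(margin, H - margin), np.arange(margin, W - margin),
                         indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    if site_mask is not None:
        sel = site_mask[2 * ii + 1, 2 * jj + 1]
        ii, jj = ii[sel], jj[sel]
    if len(ii):
        off = np.arange(-m2, m2 + 1)
        win_rel = np.array([(dr, dc) for dr in off for dc in off])
        alphas, ok = _batched_fit(lr, ii, jj, win_rel, _DIAG, cfg)
        nb = np.stack(
            [lr[ii + a, jj + b] for a, b in ((0, 0), (0, 1), (1, 0), (1, 1))], axis=1
        )
        vals = np.einsum("nk,nk->n", alphas, nb)
        r, c = 2 * ii[ok] + 1, 2 * jj[ok] + 1
        hr[r, c] = vals[ok]
        used[r, c] = True

    # pass 2: axial (even,odd)/(odd,even) sites, trained on the quincunx
    # lattice (LR pixels + pass-1 sites) rotated 45 degrees
    hmargin = 2 * m2 + 3  # rotated window extent plus training neighbors
    rr, cc = np.meshgrid(np.arange(hmargin, 2 * H - hmargin),
                         np.arange(hmargin, 2 * W - hmargin), indexing="ij")
    parity = (rr + cc) % 2 == 1
    rr, cc = rr[parity], cc[parity]
    if site_mask is not None:
        sel = site_mask[rr, cc]
        rr, cc = rr[sel], cc[sel]
    if len(rr):
        s = np.arange(-m2, m2 + 1)
        st = np.array([(a + b, a - b) for a in s for b in s])
        win_rel = st + _AXIAL[0]  # window centered on the rotated-NW neighbor
        alphas, ok = _batched_fit(hr, rr, cc, win_rel, _AXIAL, cfg, train_scale=2)
        nb = np.stack([hr[rr + dr, cc + dc] for dr, dc in _AXIAL], axis=1)
        vals = np.einsum("nk,nk->n", alphas, nb)
        hr[rr[ok], cc[ok]] = vals[ok]
        used[rr[ok], cc[ok]] = True
    return used


def nedi_upscale(img: GrayImage, cfg: NEDIConfig = NEDIConfig()) -> GrayImage:
    """Full NEDI 2x upscale (every interpolated site edge-directed; border
    band and ill-conditioned windows fall back to bilinear)."""
    out, _ = _hybrid_float(img, None, cfg)
    out = np.clip(round_half_up(out), 0, img.peak).astype(np.int64)
    return GrayImage(out, bit_depth=img.bit_depth, h_min=img.h_min, h_max=img.h_max)


def _hybrid_float(
    img: GrayImage, edges_hr: Optional[EdgeMap], cfg: NEDIConfig
) -> tuple[np.ndarray, np.ndarray]:
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    lr = img.pixels.astype(float)
    hr = _bilinear_float(lr)
    mask = None
    if edges_hr is not None:
        if edges_hr.mask.shape != hr.shape:
            raise ValueError(
                f"edge map shape {edges_hr.mask.shape} does not match 2x lattice {hr.shape}"
            )
        if edges_hr.resolution_factor != 2:
            raise ValueError("edge map must be at resolution factor 2")
        mask = edges_hr.mask
        if not mask.any():
            return hr, np.zeros(hr.shape, dtype=bool)
    used = _nedi_fill(hr, lr, cfg, mask)
    return hr, used


def hybrid_upscale(
    img: GrayImage,
    edges_hr: EdgeMap,
    cfg: NEDIConfig = NEDIConfig(),
    cleanup_kernel: int = 3,
    cleanup: str = "band",
) -> GrayImage:
    """Edge-gated 2x upscale: NEDI inside the high-resolution edge band,
    bilinear elsewhere; low-resolution pixels keep their values on the
    even-even lattice.

    A final median pass with ``cleanup_kernel`` suppresses the occasional
    singular-value outliers of the least-squares fit; ``cleanup`` selects
    its scope: ``"band"`` (only where NEDI was used, the default),
    ``"global"`` (whole image) or ``"off"``.  With an empty edge map the
    result is bit-identical to :func:`bilinear_upscale`.
    """
    if cleanup not in ("band", "global", "off"):
        raise ValueError("cleanup must be 'band', 'global' or 'off'")
    hr, used = _hybrid_float(img, edges_hr, cfg)
    out = np.clip(round_half_up(hr), 0, img.peak).astype(np.int64)
    if cleanup == "band" and used.any():
        med = ndimage.median_filter(out, size=cleanup_kernel, mode="nearest")
        out[used] = med[used]
    elif cleanup == "global":
        out = ndimage.median_filter(out, size=cleanup_kernel, mode="nearest")
    return GrayImage(out, bit_depth=img.bit_depth, h_min=img.h_min, h_max=img.h_max)


def enhance_n(
    img: GrayImage,
    n: int,
    filter_spec: FilterSpec = FilterSpec(),
    canny_cfg: CannyConfig = CannyConfig(),
    nedi_cfg: NEDIConfig = NEDIConfig(),
    cleanup_kernel: int = 3,
    cleanup: str = "band",
) -> GrayImage:
    """Iterate the denoise -> detect-edges -> expand -> hybrid-upscale cycle
    ``n`` times, doubling resolution each time (2^n overall); ``n = 0`` is
    the identity."""
    if n < 0:
        raise ValueError("iteration count must be non-negative")
    out = img
    for _ in range(n):
        den = denoise_image(out, filter_spec)
        edge_lr = canny_edges(den, canny_cfg)
        edge_hr = upscale_edge_map(edge_lr, 2, canny_cfg.dilation_radius)
        out = hybrid_upscale(den, edge_hr, nedi_cfg, cleanup_kernel, cleanup)
    return out
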