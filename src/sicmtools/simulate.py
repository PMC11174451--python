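"""Hopping-mode SICM scan simulator.

The probe in hopping mode retracts a fixed hop height above the local
surface, then descends while the ion current through the nanopipette is
sampled every ``period_T`` milliseconds.  The current follows the approach
curve

    I(d) = I_ref / (1 + (3/2) * tan(theta) * r / (d * ln(r_o / r)))

where ``d`` is the tip-sample distance, ``r``/``r_o`` the inner/outer tip
radii and ``theta`` the cone half-angle.  The first sample whose measured
current drops below ``threshold_frac * I_ref`` (the usual 1% criterion)
triggers, and the probe position at that moment — minus the deterministic
trigger distance — is recorded as the sample height.

Two discretisation effects generate exactly the artifacts the enhancement
pipeline targets:

* the descent advances ``D = T * v`` per sample, so recorded heights are
  quantised to within one step ``D`` even without noise;
* additive Gaussian current noise occasionally pushes a far-field sample
  below threshold, producing an isolated positive height spike
  ("salt-and-pepper" noise).  The per-sample current noise SD scales with
  ``sqrt(v / noise_ref_speed)`` — a faster approach needs a wider
  measurement bandwidth — so spike density grows with scan speed, matching
  the qualitative argument that a faster descent steepens the sampled
  current drop.

All heights are in micrometres; tip radii and distances fed to the approach
curve are in nanometres; speeds in nm/ms; currents in nA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError
from .topo import EdgeMap, HeightMap

__all__ = [
    "ApproachCurveParams",
    "ScanConfig",
    "SurfaceSpec",
    "approach_current",
    "trigger_distance",
    "current_change_rate",
    "make_surface",
    "make_edge_scene",
    "simulate_hop_scan",
    "count_noise_points",
]


@dataclass(frozen=True)
class ApproachCurveParams:
    """Physical constants of the approach curve.

    Defaults follow a typical single-barrel nanopipette: 30 nm inner tip
    radius, 200 nm outer diameter, shallow cone.
    """

    I_ref: float = 1.0  # reference current far from the sample (nA)
    r_o: float = 100.0  # outer tip radius (nm)
    r: float = 30.0  # inner tip radius (nm)
    tan_theta: float = 0.05  # tangent of the cone half-angle

    def __post_init__(self) -> None:
        if not (self.I_ref > 0):
            raise ValueError("I_ref must be positive")
        if not (self.r_o > self.r > 0):
            raise ValueError("need r_o > r > 0 so that ln(r_o / r) > 0")
        if not (self.tan_theta > 0):
            raise ValueError("tan_theta must be positive")

    @property
    def k(self) -> float:
        """Characteristic length (3/2) * tan(theta) * r / ln(r_o/r), in nm."""
        return 1.5 * self.tan_theta * self.r / np.log(self.r_o / self.r)


@dataclass(frozen=True)
class ScanConfig:
    """Hopping-scan acquisition settings.

    ``current_noise_sd`` is the additive current noise SD (nA) at the
    reference speed ``noise_ref_speed``; at other speeds it scales with
    sqrt(v / noise_ref_speed).  The default SD is calibrated so that at the
    480 nm/ms operating speed roughly 0.5% of pixels misfire into spikes.
    """

    speed_v: float = 480.0  # probe descent speed (nm/ms)
    period_T: float = 0.5  # current sampling period (ms)
    hop_height: float = 10.0  # retract height above the local surface (µm)
    threshold_frac: float = 0.99  # trigger when I < threshold_frac * I_ref
    current_noise_sd: float = 0.0026  # additive current noise SD (nA) at ref speed
    noise_ref_speed: float = 480.0  # speed at which current_noise_sd applies (nm/ms)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.speed_v > 0 and self.period_T > 0):
            raise ValueError("speed_v and period_T must be positive")
        if not (0 < self.threshold_frac < 1):
            raise ValueError("threshold_frac must lie in (0, 1)")
        if not (self.hop_height > 0):
            raise ValueError("hop_height must be positive")
        if self.current_noise_sd < 0:
            raise ValueError("current_noise_sd must be non-negative")

    @property
    def step_D(self) -> float:
        """Distance covered per sampling period, D = T * v (nm)."""
        return self.period_T * self.speed_v


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of a synthetic cell-like topography."""

    shape: tuple[int, int] = (48, 48)
    pixel_pitch: float = 1.0  # µm per pixel
    n_features: int = 5  # Gaussian bumps / flat-top plateaus
    height_range: tuple[float, float] = (0.0, 30.0)  # µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("surface shape must have positive area")
        if not (self.height_range[1] > self.height_range[0]):
            raise ValueError("height_range max must exceed min")
        if self.n_features < 0:
            raise ValueError("n_features must be non-negative")


def approach_current(d, params: ApproachCurveParams):
    """Ion current at tip-sample distance ``d`` (nm); scalar or array.

    Strictly increasing in ``d`` and bounded by (0, I_ref).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("tip-sample distance must be positive")
    out = params.I_ref / (1.0 + params.k / d)
    return float(out) if out.ndim == 0 else out


def trigger_distance(params: ApproachCurveParams, threshold_frac: float) -> float:
    """Distance (nm) at which the noiseless current crosses the trigger.

    Solves I(d) = threshold_frac * I_ref:  d = k * tf / (1 - tf).
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must lie in (0, 1)")
    return params.k * threshold_frac / (1.0 - threshold_frac)


def current_change_rate(d_start: float, d_end: float, params: ApproachCurveParams) -> float:
    """Mean current change rate over one sampling interval (nA per nm).

    ``(I(d_start) - I(d_end)) / (d_start - d_end)``; the magnitude grows as
    the interval nears the sample, which is why a faster descent sees a
    steeper sampled drop.
    """
    if d_start == d_end:
        raise ValueError("degenerate interval: d_start == d_end")
    return (approach_current(d_start, params) - approach_current(d_end, params)) / (
        d_start - d_end
    )


# ---------------------------------------------------------------------------
# synthetic surfaces
# ---------------------------------------------------------------------------


def _feature_field(spec: SurfaceSpec, oversample: int) -> np.ndarray:
    """Evaluate the seeded continuous bump/plateau field on a grid.

    Feature geometry is drawn in physical (µm) coordinates so the same
    surface can be rendered at any oversampling factor; ``oversample = 2``
    yields the ideal half-pitch rendering used as ground truth for 2x
    enhancement.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    extent_y = rows * spec.pixel_pitch
    extent_x = cols * spec.pixel_pitch
    # geometry draws are independent of the evaluation grid
    cy = rng.uniform(0.1 * extent_y, 0.9 * extent_y, size=spec.n_features)
    cx = rng.uniform(0.1 * extent_x, 0.9 * extent_x, size=spec.n_features)
    sigma = rng.uniform(0.08, 0.22, size=spec.n_features) * min(extent_y, extent_x)
    amp = rng.uniform(0.35, 1.0, size=spec.n_features)
    flat_top = rng.random(size=spec.n_features) < 0.5

    pitch = spec.pixel_pitch / oversample
    y = np.arange(rows * oversample) * pitch
    x = np.arange(cols * oversample) * pitch
    Y, X = np.meshgrid(y, x, indexing="ij")
    field = np.zeros_like(Y)
    for i in range(spec.n_features):
        r2 = ((Y - cy[i]) ** 2 + (X - cx[i]) ** 2) / (2.0 * sigma[i] ** 2)
        if flat_top[i]:
            field += amp[i] * np.exp(-(r2**2))  # super-Gaussian: plateau with steep rim
        else:
            field += amp[i] * np.exp(-r2)
    return field


def make_surface(spec: SurfaceSpec, oversample: int = 1) -> HeightMap:
    """Generate a smooth, deterministic-given-seed synthetic topography.

    The realized max-min height difference on the base grid equals the
    requested span exactly (amplitudes are renormalized); there are no
    isolated single-pixel spikes.  ``oversample`` renders the same
    continuous surface on a finer grid with the normalization constants of
    the base grid, so base-grid pixels reappear at the even lattice sites of
    a 2x rendering.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    h_lo, h_hi = spec.height_range
    span = h_hi - h_lo
    if spec.n_features == 0:
        rows, cols = spec.shape
        flat = np.full((rows * oversample, cols * oversample), h_lo)
        return HeightMap(flat, pixel_pitch=spec.pixel_pitch / oversample, label="flat")
    base = _feature_field(spec, 1)
    lo, hi = float(base.min()), float(base.max())
    if hi - lo < 1e-12:  # features cancelled out; treat as flat
        rows, cols = spec.shape
        flat = np.full((rows * oversample, cols * oversample), h_lo)
        return HeightMap(flat, pixel_pitch=spec.pixel_pitch / oversample, label="flat")
    field = base if oversample == 1 else _feature_field(spec, oversample)
    heights = h_lo + (field - lo) / (hi - lo) * span
    return HeightMap(
        heights,
        pixel_pitch=spec.pixel_pitch / oversample,
        label=f"synthetic(seed={spec.seed})",
    )


def make_edge_scene(
    shape: tuple[int, int] = (48, 48),
    height_range: tuple[float, float] = (0.0, 30.0),
    pixel_pitch: float = 1.0,
    rim_width: float = 0.5,
    seed: int = 0,
    oversample: int = 1,
) -> HeightMap:
    """A plateau disk with a sharp sigmoidal rim plus a gentle background tilt.

    Unlike :func:`make_surface` this scene has a genuine step edge at every
    orientation, which is what exercises the edge-directed interpolation
    branch of the pipeline.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    extent_y, extent_x = rows * pixel_pitch, cols * pixel_pitch
    cy = rng.uniform(0.4, 0.6) * extent_y
    cx = rng.uniform(0.4, 0.6) * extent_x
    radius = 0.28 * min(extent_y, extent_x)
    pitch = pixel_pitch / oversample
    y = np.arange(rows * oversample) * pitch
    x = np.arange(cols * oversample) * pitch
    Y, X = np.meshgrid(y, x, indexing="ij")
    R = np.hypot(Y - cy, X - cx)
    disk = 1.0 / (1.0 + np.exp((R - radius) / (rim_width * pixel_pitch)))
    tilt = 0.08 * ((X / extent_x) + (Y / extent_y))
    field = disk + tilt
    lo, hi = field.min(), field.max()
    h_lo, h_hi = height_range
    heights = h_lo + (field - lo) / (hi - lo) * (h_hi - h_lo)
    return HeightMap(heights, pixel_pitch=pitch, label=f"edge-scene(seed={seed})")


# ---------------------------------------------------------------------------
# hopping-mode scan
# ---------------------------------------------------------------------------


def simulate_hop_scan(
    surface: HeightMap,
    cfg: ScanConfig = ScanConfig(),
    params: ApproachCurveParams = ApproachCurveParams(),
    seed: Optional[int] = None,
) -> tuple[HeightMap, EdgeMap]:
    """Simulate one hopping-mode scan of ``surface``.

    Per pixel the probe starts ``hop_height`` above the local surface and
    descends in steps ``D = T * v``; each sampled current is the approach
    curve plus Gaussian noise, and the first sample below
    ``threshold_frac * I_ref`` triggers.  Recorded height is the probe
    position at trigger minus the deterministic trigger distance, so the
    noiseless recording is within one step ``D`` of the truth.

    Returns the noisy height map and a binary mask marking "noise points":
    pixels whose recorded height deviates from the truth by more than
    ``3 * D`` (separating genuine false triggers from sampling-step
    quantization).  One seeded RNG stream per scan; per-pixel draws are
    consumed in row-major order, so results are fully deterministic.
    """
    h = surface.heights
    hop_nm = cfg.hop_height * 1000.0
    # the probe retracts above the *local* surface, then translates: it must
    # clear the height increase to any adjacent pixel
    steps = 0.0
    if h.shape[0] > 1:
        steps = max(steps, float(np.abs(np.diff(h, axis=0)).max()))
    if h.shape[1] > 1:
        steps = max(steps, float(np.abs(np.diff(h, axis=1)).max()))
    if steps * 1000.0 >= hop_nm:
        raise ConfigurationError(
            f"hop_height {cfg.hop_height} µm does not clear the local surface relief "
            f"({steps:.2f} µm between adjacent pixels)"
        )

    D = cfg.step_D  # nm
    d_trig = trigger_distance(params, cfg.threshold_frac)  # nm
    n_steps = int(np.ceil(hop_nm / D)) + 2
    n_pix = h.size
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # the sampling clock is not synchronized to the probe's vertical
    # position, so each descent ladder carries a uniform phase in [0, D)
    phase = rng.uniform(0.0, D, size=n_pix)
    # per-pixel descent ladder: distances to the local surface
    d = (hop_nm + phase)[:, None] - np.arange(1, n_steps + 1)[None, :] * D
    above = d > 0
    current = np.zeros_like(d)
    current[above] = approach_current(d[above], params)

    sigma = cfg.current_noise_sd * np.sqrt(cfg.speed_v / cfg.noise_ref_speed)
    if sigma > 0:
        measured = current + rng.normal(0.0, sigma, size=(n_pix, n_steps))
    else:
        measured = current
    triggered = measured < cfg.threshold_frac * params.I_ref
    triggered[~above] = True  # at/below the surface the current collapses
    first = np.argmax(triggered, axis=1)
    recorded = h.ravel() + (d[np.arange(n_pix), first] - d_trig) / 1000.0
    recorded = recorded.reshape(h.shape)

    tol = 3.0 * D / 1000.0  # µm
    mask = np.abs(recorded - h) > tol
    noisy = HeightMap(recorded, pixel_pitch=surface.pixel_pitch,
                      label=f"{surface.label} scan(v={cfg.speed_v})")
    return noisy, EdgeMap(mask, resolution_factor=1)


def count_noise_points(noisy: HeightMap, reference: HeightMap, tol: float) -> int:
    """Number of pixels deviating from the reference by more than ``tol`` (µm)."""
    if noisy.shape != reference.shape:
        raise ValueError(f"shape mismatch: {noisy.shape} vs {reference.shape}")
    return int((np.abs(noisy.heights - reference.heights) > tol).sum())
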