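# Methods

This note documents the models implemented in `sicmtools`, the parameter
choices that matter, what the synthetic scan generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Scan simulator

### Approach curve

The ion current through a conical nanopipette at tip–sample distance `d` is

    I(d) = I_ref / (1 + k/d),      k = (3/2) · tanθ · r / ln(r_o/r)

with `I_ref` the far-field reference current (nA), `r`/`r_o` the inner and
outer tip radii (nm) and `θ` the cone half-angle.  `I(d)` is strictly
increasing and bounded by `(0, I_ref)`; the characteristic length `k` sets
where the current collapses.  Defaults: `I_ref = 1 nA`, `r = 30 nm`,
`r_o = 100 nm` (a 200 nm-diameter single-barrel pipette), `tanθ = 0.05`.
With these, the 1% trigger criterion `I(d) = 0.99·I_ref` is crossed at
`d* = k·0.99/0.01 ≈ 185 nm` — consistent with the textbook statement that
the current begins to drop when the tip–sample distance is comparable to
the tip diameter.

### Hopping-mode descent

Per pixel the probe starts `hop_height` (default 10 µm) above the local
surface and descends at `v` nm/ms while the current is sampled every
`T` ms, i.e. every `D = T·v` nm of travel.  Each sample is
`I(d) + ε`, `ε ~ N(0, σ_v²)`; the first sample below `0.99·I_ref` triggers
and the recorded height is the probe position minus the analytic trigger
distance `d*`.  Without the `d*` subtraction every recording would carry a
constant ≈185 nm bias; with it, the noiseless recording is within one step
`D` of the truth (the sampling-step bound).

Two refinements make the simulated noise match the character of real fast
scans:

* **Sampling phase.**  The sampling clock is not synchronized to the
  probe's vertical position, so each descent ladder carries a uniform
  per-pixel phase in `[0, D)`.  Without it every pixel's ladder lands at
  the same distance from `d*` and the background error becomes a bimodal
  toggle; with it, the background is a benign quantization-like band.
* **Speed-dependent noise.**  `σ_v = current_noise_sd · sqrt(v/480)`:
  tracking a faster approach requires a wider measurement bandwidth, and
  noise power scales with bandwidth.  This realizes, as a generative
  mechanism, the qualitative argument that a faster descent steepens the
  sampled current drop and raises the false-trigger probability — spike
  density is monotone increasing in scan speed (a Monte-Carlo-tested
  property).

A *noise point* is a pixel whose recorded height deviates from the truth by
more than `3·D`, separating genuine false triggers (µm-scale positive
spikes) from sampling-step quantization.

Calibration: `T = 0.5 ms` and `current_noise_sd = 0.0026 nA` yield ≈0.5%
noise points at the 480 nm/ms operating speed (≈13 per 48×48 scan) on an
otherwise smooth background — impulse-dominated noise, which is the regime
the median-filter stage targets.  These values were fixed once, from pilot
runs of the generator itself, before any evaluation was written.

### Synthetic surfaces

`make_surface` sums seeded Gaussian bumps and flat-top (super-Gaussian)
plateaus drawn in physical coordinates, then renormalizes so the realized
height span equals the requested range (default 0–30 µm over 48×48 px at
1 µm pitch).  Because features live in physical coordinates, the same
surface can be rendered at any oversampling; the 2× rendering supplies the
ground truth for evaluating enhancement, with base-grid pixels reappearing
exactly on its even lattice sites.  `make_edge_scene` adds a disk plateau
with a sharp sigmoidal rim (width 0.5 px) for exercising the edge-directed
branch, which smooth bump fields barely trigger.

What the generator does *not* emulate: probe–sample convolution, drift and
creep of the piezo stage, double-layer and rectification effects on the
current, spatially correlated interference, and partial/compressed
sampling.  Passing tests therefore demonstrate correct behaviour under
impulse-plus-quantization noise on smooth topographies with occasional
sharp rims — not performance on arbitrary real scans.

## Denoising

Median, mean and Gaussian filters use a square kernel (default 3×3) with
replicate borders; the wavelet baseline is a single-level Haar transform
with universal soft thresholding (`σ̂·sqrt(2 ln n)`, MAD estimate from the
diagonal band).  The Gaussian σ defaults to kernel/4.  Outputs are rounded
half-up and clamped.  The comparison harness scores each filter (and the
unfiltered baseline) by PSNR against a reference; under the simulator's
impulse-dominated noise the median filter ranks first — by ≈1.5–2 dB over
the runner-up and ≈5–7 dB over no filtering, mirroring the qualitative
outcome that motivated choosing it.

## Edge detection

The canonical four-stage Canny chain, written against `scipy.ndimage`
primitives: Gaussian smoothing (σ = 1), Sobel gradients, non-maximum
suppression over four quantized direction sectors, and double-threshold
hysteresis linking.  Thresholds are *fractions of the maximum gradient
magnitude* (defaults 0.1/0.25), which makes the defaults scale-free and the
edge map invariant to global intensity shifts.  In the suppression step the
comparison is strict toward the +gradient neighbour and non-strict toward
the −gradient neighbour, so a perfectly symmetric two-pixel ridge (e.g. an
ideal intensity step) keeps exactly one deterministic side.  The edge map
is carried to the 2× lattice by nearest-neighbour replication followed by a
square dilation (radius 1), guaranteeing the band covers every
high-resolution site adjacent to a low-resolution edge pixel.

## Interpolation

* **Bilinear**: separable X-then-Y midpoint averaging with the last
  row/column replicated; `out[2i, 2j] = in[i, j]`.  Exact on constants and
  linear ramps.
* **NEDI**: per diagonal site, the 5×5 low-resolution window yields 25
  training equations (each window pixel vs its four diagonal neighbours,
  NW/NE/SW/SE order) in the 4 weights, solved via ridge-stabilized normal
  equations `(CᵀC + ε·tr(CᵀC)/4·I)α = Cᵀy`, `ε = 1e-6`.  Windows whose
  raw `CᵀC` condition number exceeds `1e8` (flat patches), or that would
  leave the image, fall back to bilinear.  The remaining axial sites are
  filled by the identical estimator in the 45°-rotated frame, where the
  four "diagonal" neighbours are the axial neighbours available after the
  first pass and the training neighbours sit at twice that offset on the
  quincunx lattice.  All interpolation runs in float arithmetic and is
  rounded half-up and clamped once at output.
* **Hybrid dispatch**: interpolated sites inside the expanded edge band get
  NEDI values, all others bilinear; original pixels stay on the even-even
  lattice.  A final 3×3 median pass over the sites NEDI actually filled
  suppresses the rare singular-fit outliers; its scope is configurable
  (`band`/`global`/`off`), with `band` the default so smooth regions are
  not re-blurred.  With an empty edge map the hybrid result is bit-identical
  to plain bilinear upscaling.

Iterating denoise → detect → expand → hybrid N times yields 2^N×
enhancement; N = 0 is the identity.

## Quality metrics

MSE is the plain mean squared intensity difference; PSNR is
`10·log10((2^B−1)²/MSE)` with B = 8, returning an +inf sentinel at zero
MSE.  SSIM uses whole-image means, variances (population, ddof = 0) and
covariance with `k1 = 0.01`, `k2 = 0.03`, `L = 255`; windowed/multiscale
SSIM is out of scope.  Since the true image of a physical sample is
unknowable, the reference protocol averages many repeated (denoised) scans
pixel-wise; aggregation over repeated scans reports mean PSNR (excluding
+inf sentinels, with a count) and mean SSIM.  Comparing images rendered
with different height scales raises an error rather than silently
rescaling.

## Problem sizes

The test suite runs the simulator at 32–48 px image sizes with 50–200
Monte-Carlo replicates per property; the acceptance script runs the full
study at 48/64/100 px with 50 scans per size.  These sizes match the study
conditions the pipeline is designed around and keep the whole suite within
seconds on one CPU.

## Known limitations

* Only 2× (and iterated 2^N×) enhancement; arbitrary scale factors are out
  of scope.
* The interpolator operates on the 8-bit grayscale rendering, not on raw
  float heights, so output height precision is limited by the 8-bit
  quantization of the height range.
* Global SSIM saturates quickly on large smooth images; differences between
  methods show more clearly in PSNR.
* The simulator's current noise is white Gaussian per sample; real
  interference is often periodic or bursty, which would change the spike
  statistics (though not the pipeline's applicability).
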