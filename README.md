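# sicmtools

Denoising and edge-directed resolution enhancement for scanning ion
conductance microscopy (SICM) height maps, with a physics-based hopping-mode
scan simulator for generating test data.

## The problem

SICM images living cells non-invasively by scanning a nanopipette over the
sample in liquid and watching the ion current through the tip.  In hopping
mode the probe retracts and re-approaches at every pixel, recording the
height at which the current drops by a set fraction (≈1%) of its far-field
value.  Scanning fast enough to be useful on dynamic samples has two costs:
the coarse sampling of the descent quantises heights, and current noise
occasionally fires the trigger far above the surface, leaving isolated
salt-and-pepper height spikes.  Scanning at double the lateral resolution
instead multiplies the imaging time several-fold.

`sicmtools` implements the alternative: scan fast at native resolution,
remove the spike noise, and double the resolution computationally without
blurring edges.  The pipeline is

1. render the height map as an 8-bit grayscale image (linear min–max),
2. **median-filter** (3×3) the image — the right tool for impulse noise,
3. detect edges with a from-scratch four-stage **Canny** chain and expand
   the edge mask to the 2× lattice,
4. upscale 2×: **NEDI** (new edge-directed interpolation) inside the edge
   band, separable **bilinear** interpolation elsewhere, plus a final
   median pass over the NEDI band,
5. convert back to heights (iterate steps 2–4 `N` times for 2^N×).

NEDI estimates the four diagonal interpolation weights per pixel from the
local low-resolution covariance structure.  For the high-resolution site
`(2i+1, 2j+1)`:

    I(2i+1, 2j+1) = Σ_{a,b∈{0,1}} α_{2a+b} · I(2(i+a), 2(j+b))
    α = (CᵀC)⁻¹ Cᵀ y⃗

where `y⃗` stacks the M×M (M = 5) low-resolution window and each row of `C`
holds the four diagonal neighbours of one window pixel — *geometric
duality*: edge orientation statistics are resolution-invariant, so weights
fitted at low resolution apply at high resolution.  The remaining sites are
filled by the same estimator on the 45°-rotated lattice.  Quality is scored
with PSNR and a global SSIM against multi-scan mean references.

## Worked example

Simulate one fast scan (480 nm/ms) of a synthetic 48×48 cell-like surface,
enhance it to 96×96, and rank the denoising filters:

```console
$ sicmtools simulate --seed 7 --out-dir demo
wrote truth.csv, noisy.csv, noise_mask.png to demo (16 noise points)
$ sicmtools enhance demo/noisy.csv demo/enhanced.csv -n 1
wrote demo/enhanced.csv ((48, 48) -> (96, 96))
$ sicmtools compare-filters demo/noisy.csv demo/truth.csv
method,psnr_db
median,45.5138
gaussian,43.3608
mean,42.4360
none,37.9407
wavelet,37.6907
```

The simulated scan carries 16 height spikes from premature triggers (the
salt-and-pepper noise of fast scanning).  The median filter recovers the
clean rendering best — 45.5 dB against 37.9 dB unfiltered, a 7.6 dB gain —
while mean and Gaussian filtering blur the topography and wavelet
shrinkage barely touches the impulses.  `sicmtools demo` runs the full
repeated-scan experiment (50 scans each at 48×48, 64×64 and 100×100) and
prints aggregated PSNR/SSIM tables.

The same functionality is available as a library:

```python
from sicmtools import (SurfaceSpec, make_surface, simulate_hop_scan,
                       run_pipeline, PipelineConfig)

surface = make_surface(SurfaceSpec(shape=(48, 48), seed=7))
noisy, mask = simulate_hop_scan(surface)
result = run_pipeline(noisy, PipelineConfig(iterations=1))
print(result.enhanced.shape)   # (96, 96)
```

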