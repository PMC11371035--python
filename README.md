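# fiberfold

Data reduction for X-ray fiber diffraction patterns from striated muscle
and other fibrous systems.

Time-resolved diffraction experiments at synchrotron beamlines produce
thousands of 2-D detector frames per session. Extracting the physiology
numbers buried in them — the inter-filament lattice spacing d₁₀, the
I₁₁/I₁₀ equatorial intensity ratio that tracks mass movement between thick
and thin filaments, meridional reflection spacings and intensities —
requires a reproducible reduction chain: geometry calibration, quadrant
folding, diffuse background removal, 1-D projection and constrained peak
fitting. `fiberfold` provides that chain as an importable Python library
with a thin batch CLI, testable end to end on synthetic patterns with
exact ground truth.

## What it computes

**Quadrant folding.** By Friedel's law the four quadrants of a fiber
pattern are equivalent. Averaging them doubles the SNR (summing raises the
signal ×4), and pixels below a mask threshold (detector module gaps, masked
regions) are excluded per quadrant, so intact quadrants fill the gaps of
pixel-array detectors.

**2-D background subtraction.** Five estimators of the diffuse background —
circularly symmetric percentile profile, iterative Gaussian or boxcar
smooth-and-clamp, roving-window order statistic, morphological white
top-hat — plus a logistic radial blend of any two, and the background total
intensity for cross-pattern scaling.

**Equatorial analysis.** The equator is projected into a 1-D trace, the
background removed with a lower convex hull, and a bilateral peak model
fitted with positions constrained to the hexagonal filament lattice,

&nbsp;&nbsp;&nbsp;&nbsp;offset(h,k) = S₁₀·√(h² + hk + k²),

with Gaussian or Voigt profiles whose widths follow the para-crystalline
disorder model w(h,k) = σ_s + σ_d·Z², Z = √(h²+hk+k²). Outputs: S₁₀ (px),
d₁₀ (nm, when calibrated), per-reflection areas, I₁₁/I₁₀, σ_s, σ_d, and a
fit-quality flag; flagged frames can be refit from hand-edited initial
values, including extra non-indexing peaks.

**Projection traces.** Box-integrated projections along the meridian,
equator or arbitrary directions; convex-hull baselines; peak measurement by
Gaussian fit (center, area, σ) and by the centroid of the top half of the
peak, with height × FWHM as a triangular area cross-check.

**Stacking.** Time re-binning within one experiment and frame-matched
summing across experiments, with self-descriptive output names.

**Synthetic patterns.** `fiberfold.synthgen` renders patterns with known
lattice parameters, diffuse background, Poisson noise, gap stripes and
center/rotation offsets — every recovery test in the suite runs against it.

## Worked example

`examples/03_equator_analysis.py` generates a calibrated muscle-like
pattern (S₁₀ = 80 px, I₁₁/I₁₀ = 0.6, Poisson noise) and runs the full
equator pipeline:

```
S10 (px):      fitted   79.995   true 80.0
d10 (nm):      fitted   22.523   true 22.522
I11/I10:       fitted   0.5983   true 0.6000
sigma_s (px):  fitted    2.008   true 2.0
sigma_d (px):  fitted    0.296   true 0.3
fit error 0.0352, flagged: False
```

The fitted lattice spacing is recovered to <0.01%, the intensity ratio to
0.3%, and the disorder widths to a few percent at realistic counting
statistics. The other examples cover folding (`01`), background
subtraction (`02`), projection traces (`04`), stacking (`05`) and headless
batch processing over a JSON settings file (`06`).

## Command line

```
fiberfold fold|bgsub|equator|traces|stack|path-a|path-b|path-c|synth \
    --settings settings.json --input DIR [--output DIR] [--workers N]
```

`path-a/b/c` are workflow presets: direct analysis, fold-then-analyze, and
fold → background subtraction → traces. Batches never abort on a bad
frame (it becomes a flagged CSV row), and the sorted results are identical
for any worker count.

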