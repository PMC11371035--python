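# Methods

This note records the models, conventions, numerical choices and known
limitations of the fiberfold reduction chain.

## Coordinates and units

Images are `[row, col]` arrays; a point is `(x, y)` = (column, row), 0-based,
with pixel centers at integer coordinates (so pixel boundaries sit at
half-integers). Rotation angles are degrees, counterclockwise positive in
array coordinates, normalized to (−90, +90]; they give the angle of the
equatorial axis against the image row axis. All persisted images are 32-bit
float TIFF; internal accumulations (quadrant sums, totals) run in float64
and are cast to float32 on output, which makes the small-integer folding
identities (×4 in sum mode, mean-of-three under a gap) exact in float32.

The reciprocal coordinate is d\* = 1/d in nm⁻¹ (the fiber-diffraction
convention, not 2π/d). Conversions use the exact Bragg geometry
d = λ / (2 sin(½ atan(r·p/L))) with wavelength λ (nm), pixel size p (mm)
and camera length L (mm); the silver behenate standard spacing
d = 5.838 nm is a settings default, not a constant baked into the code.

## Geometry

**Center.** The pattern center is the peak of the correlation between the
image and its 180°-rotated copy (Friedel symmetry), computed as the full
self-convolution via FFT and refined to sub-pixel by 3-point parabolic
interpolation along each axis. A flat image raises a degenerate-input
error.

**Rotation.** Two estimators are selectable: the maximum of the 1°-binned
intensity-weighted azimuthal histogram (orientation folded mod 180°,
refined by a ±3-bin circular centroid), and the principal axis of the
intensity-weighted second-moment tensor. Weights are median-referenced and
clipped at zero so the diffuse floor does not dilute the histogram. When no
direction exceeds the histogram mean by 5 standard deviations the pattern
is declared isotropic and the caller may default to 0°.

**Calibration.** With one powder ring of known spacing, the center comes
from the Friedel correlation and the ring radius R from the sub-pixel peak
of the azimuthally averaged radial profile (annuli of width 1 px centred on
integer radii); L = R·p / tan(2θ), 2θ = 2 asin(λ/2d). Ring significance
requires the profile peak to exceed the median by 5 robust (MAD-based)
standard deviations over annuli holding at least 50 pixels. Detector tilt
is not modelled (patterns are assumed normal-incidence), and only one ring
is used — multi-ring wavelength refinement is out of scope.

**Rectification** rotates by −rotation about the center with bilinear
interpolation; out-of-footprint pixels take a caller-chosen fill value
(default −1) intended to sit below the mask threshold so downstream stages
exclude them. Rectify does not translate by default; the snap of the center
onto a pixel-boundary crossing happens inside quadrant folding, which
shifts by the sub-pixel remainder only when one exists. This keeps
rotation-free, boundary-centered images bit-identical through the chain.

## Quadrant folding

The common quadrant is the largest centered rectangle fitting the image.
Each output pixel averages (or sums) the 1–4 co-located quadrant values at
or above the mask threshold; `counts` records the contributors, and pixels
excluded everywhere carry the sentinel `mask_threshold − 1` rather than
raising, so a complete image is always produced. The reconstructed full
image mirrors the folded quadrant across both axes and is exactly
mirror-symmetric by construction. Averaging four independent Poisson
realizations halves the residual noise; the suite verifies
std(folded−truth)/std(raw−truth) = 0.50 ± 10% at means ≥ 100 counts.

## Background estimators

All five estimators are equivariant under adding a constant. The circular
estimator takes a per-annulus low percentile, pairing the value percentile
p with the radius percentile 100−p inside each annulus (removing the
within-bin bias on radially decreasing surfaces), smooths the profile with
a moving average and back-projects; empty annuli are interpolated from
neighbours and the extreme radii are anchored so corners interpolate
rather than clamp. The Gaussian/boxcar variants iterate B ← min(smooth(B),
I) from B = I — the clamp guarantees B ≤ I pointwise and monotone
non-increasing iterates; a fixed iteration count (default 20) is used
instead of a tolerance for deterministic batch behavior. The roving window
takes a local low percentile over an odd window, lightly smooths, and
clamps to the image. The top-hat background is the grayscale opening with
a disc; anti-extensivity gives B ≤ I for free. Two estimates can be
blended radially with a logistic weight w(r) = 1/(1+exp((r−R)/T)) — the
paper-level recipe "different algorithms at low and high radii" needs a
transition rule, and a logistic of exposed width T is the smoothest
two-parameter choice. Subtraction preserves negative residuals
(over-subtraction is diagnostic) and reports the background total
intensity over unmasked pixels for cross-pattern scaling.

## Traces and peak measures

Box projections sum across the box width with per-position renormalization
to the nominal width when sentinel pixels (gaps, masks, rectification
fill) are excluded; oriented boxes sample rotated rows bilinearly and need
not pass through the pattern center. The baseline is the lower convex hull
of the trace (monotone-chain construction, linear interpolation between
hull vertices), which never exceeds the trace and touches it at the
vertices.

The top-half centroid uses samples strictly above half the window maximum,
weighted by intensity minus that level: Σx·(I−level)/Σ(I−level). The
level-referenced weights make the measure invariant to the constant level
and exactly symmetric for symmetric peaks; the prose definition admits
raw-intensity weights too, and the two differ negligibly in practice. The
FWHM comes from linearly interpolated half-height crossings, and the
triangular area is height × FWHM, giving triangular/Gaussian area →
√(8 ln 2)/√(2π) ≈ 0.9394 for a pure Gaussian. Under 5% multiplicative
noise the centroid is unbiased with variance of the same order as the
Gaussian-fit center (within ~3×: the half-height level itself jitters with
the noisy maximum); its real advantage is robustness to peak-shape change,
not raw variance.

## Equatorial model

The bilateral trace model is

I(x) = Σ_hk A_hk·[φ(x−c−S₁₀Z) + φ(x−c+S₁₀Z)] + extra peaks,
Z = √(h²+hk+k²),

with one area per (h,k) shared by both sides (Friedel symmetry), widths
tied to w = σ_s + σ_d·Z² — a constant term for the spread of lattice
spacings and a term growing with the square of the reflection order for
liquid-like (second-kind, Hosemann-type) disorder. The width law lives in
one function so an alternative parameterization can be swapped in. φ is an
area-normalized Gaussian or Voigt; the Voigt Lorentzian width is one
shared fraction of the Gaussian width per fit, left free (bounded at 0)
so purely Gaussian data is fit without bias. Default index set:
(1,0), (1,1), (2,0), (2,1), (3,0). Non-hexagonal lattices are out of
scope.

Pipeline: the integration box height is 2·k·σ_axial with σ_axial the
second-moment width of the strongest off-center column and k = 4 by
default (≥ 99.99% of the axial mass); the trace is hull-subtracted on each
side outward from the centerline; S₁₀ is initialized by scoring candidate
lattices (each detected peak tried as (1,0) or (1,1)) against all detected
peak offsets; the fit is Levenberg–Marquardt via lmfit. A fit is flagged
when the residual RMS exceeds 10% of the trace RMS (settings-exposed) or
the optimizer fails; flagged frames return diagnostics instead of raising
so batches continue, and `refit_with_overrides` re-runs from hand-set
initial values or added non-indexing peaks.

## Synthetic generator

Equatorial reflections are anisotropic 2-D Gaussians — radial width from
the para-crystal law (plus an optional per-peak extra), axial width
σ_axial (default 4 px) — each side carrying total mass equal to its
nominal area, so projected areas are exact ground truth. Meridional peaks,
circular exponential/Gaussian background terms, Poisson noise (seeded,
bit-reproducible), gap stripes and center/rotation offsets complete the
model; features are evaluated analytically in the rotated frame so
rotation adds no interpolation error. Default conditions are chosen to
mimic folded muscle patterns at synchrotron counting statistics: peak
amplitudes of order 10³–10⁴ counts over a diffuse floor of a few hundred
counts. The generator does **not** model layer-line fine structure,
sarcomere form factors, polarization/absorption corrections, detector
point-spread or per-module gain — so passing recovery tests demonstrate
the correctness of the reduction arithmetic and fitting under Poisson
statistics, not robustness to every systematic of real detectors.

## Batch driver and sizes

The headless driver maps one settings object over a directory; each file
is independent, failures become flagged CSV rows, and rows are sorted by
(filename, box, peak) so serial and multi-process runs produce identical
CSVs. Suite problem sizes are chosen to exercise every code path at
interactive runtimes: 256² patterns for folding statistics (20 Poisson
replicates), a 20-condition equator grid on 192×1024 frames spanning
S₁₀ ∈ [40, 120] px, I₁₁/I₁₀ ∈ {0.5, 2.0} and both peak shapes, 1000
random traces against the brute-force hull oracle, and 10-frame batches
for the parallel-equivalence and stacking checks.

## Known limitations

- No detector tilt/obliquity correction; calibration assumes a normal
  detector and a single ring.
- The meridional analysis measures whole reflections; resolving
  substructure within M1/M2 clusters is explicitly not attempted.
- Background estimators are global heuristics; none removes the diffuse
  scatter perfectly everywhere, and the residual sign is preserved so
  users can see where over/under-subtraction occurred.
- HDF5 support reads the first 2-D/3-D dataset (or `data`); exotic
  detector layouts may need conversion.
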