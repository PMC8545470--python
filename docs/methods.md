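# Methods

## Scope and model

The package quantifies mesoscale (hundreds of nm to μm) translational order
of nacre tablet stacking along the growth direction. Its analyses assume:

* tablets are separated by thin organic sheaths that image dark against the
  mineral in Z-contrast (BSE) micrographs;
* thickness is measured sheath-centerline to sheath-centerline, so the
  sheath width is included in the tablet thickness (this matches the
  minima-to-minima measurement);
* layer indices are 1-based and chronological (pearl center → edge), so a
  thickness profile is an evenly sampled time series with one tablet as the
  unit of "time".

## Synthetic growth model

No public micrograph data accompany the quantities this package targets, so
a generator with exact ground truth defines the test conditions. The
stacking model is

    w_N = clip(d̄ + e_N + c_N, floor)

* `c_N = φ·c_{N−1} + ε_N` — stationary AR(1) "corrective" term; ε i.i.d.
  Gaussian with SD `sigma_local`. φ < 0 (default −0.4) reproduces the
  thick-followed-by-thin self-correction and the rising high-frequency
  power spectrum.
* `e_N` — "environmental" modulation with power spectral density ∝ f^−α
  (default α = 1.5), synthesized by inverse real FFT of amplitudes
  `f^(−α/2)` with uniform random phases, scaled to an exact sample RMS
  `sigma_env`. This produces the long-memory fluctuations on 25–2,500
  tablet scales.
* `clip` at a 50 nm floor rather than resampling, to preserve the spectral
  shape; presets compensate the clip by solving the pre-clip Gaussian
  moments so the realized marginal mean/SD equal the stage statistics.
* the variance is split 25% environmental / 75% AR by default — enough
  environmental share for a clean 1/f band, enough AR share that the
  corrective signature dominates above f = 0.04.

Stage presets (marginal thickness statistics and interface-orientation
half-widths): early 500 ± 300 nm at ±15°, mature 340 ± 120 nm at ±5°,
full-pearl = mature at 2,615 layers.

### Interface roughness

Interface i carries a transverse displacement field `u_i(x)`;
`u_{i+1} = a·u_i + √(1−a²)·v_i` with `v_i` Gaussian-smoothed white noise of
lateral correlation length ℓ. The amplitude is calibrated analytically from
the smoothing kernel so that the tilt-angle distribution
`arctan(du/dx)` has a requested half-width at half maximum — the same
criterion the Fourier estimator reports, so generator and estimator are
co-calibrated to one definition.

For rendered presets the stage thickness variance is split between stacking
disorder (`σ_w²`) and adjacent-displacement differences
(`2(1−a)σ_u²`), because a column-wise thickness measurement sees their
sum; preset parameters are solved so the measured column statistics hit
the stage values (340 ± 120 nm mature, 500 ± 300 nm early). The presets
use *fully independent* per-layer roughness (`a = 0`): stacks whose tilt
fields are partially correlated across layers (0 < a < 1) diffract with a
*narrowed* azimuthal spread — the ring sees the coherently averaged tilt
of a few adjacent layers rather than the point-wise tilt distribution —
and the narrowing (up to ~30% of the variance at a ≈ 0.96) cannot be
undone estimator-side without knowing a. With a = 0 every layer supplies
an independent tilt sample and the ring second moment is unbiased.
Attenuated carry-over of bumps and valleys remains available through
`RenderSpec.roughness_attenuation` for non-preset use. Preset split:
mature σ_w = 85 nm, σ_u ≈ 60 nm (ℓ ≈ 0.8 μm); early σ_w = 212 nm,
σ_u ≈ 150 nm (ℓ ≈ 0.66 μm).

### Rendering and defects

Sheaths are dark Gaussian-profile lines (width parameter 15 nm) on a bright
tablet background, rasterized exactly on the interface curves so noise-free
column minima sit at the centerlines; then Gaussian blur (2 px) and
additive Gaussian noise (10% of the tablet–sheath contrast) at 3 nm/px.
Dislocations are inserted as terminating partial sheaths at the host-layer
midline with local thinning of the host tablet (default 28% at the defect,
Gaussian lateral decay of 500 nm); counts are `round(density × area)`
("exact" mode, deterministic) or Poisson.

What the generator does **not** emulate: curved/concentric layering at the
pearl scale, mineral bridges and tablet lateral boundaries, contrast drift
and scan artifacts, non-Gaussian noise, and real sheath substructure.
Passing the recovery tests therefore shows the estimators are correct under
the stated stochastic structure, not that they are robust to every
instrumental artifact of real mosaics.

## Detection

Minima of Gaussian-smoothed intensity (SD = max(1 px, sheath/2)), with a
prominence threshold of 35% of the robust tablet–sheath contrast (median
minus 2nd-percentile level of a lightly smoothed profile; the threshold is
gain- and offset-invariant). Sub-pixel refinement by three-point parabola.
The 35% default leaves a ≥2× margin below the worst-case real-sheath
prominence (two floor-thickness tablets flanking a sheath) and ≥7 noise
SDs above the smoothed noise floor, which is what makes an exact
2,615-layer count over a ~300,000-sample transect reproducible across
seeds.

Merged-layer flagging: thickness > τ (default 1.8) × rolling median
(window 11). With Gaussian mature-stage statistics, ~1.5% of clean layers
exceed that threshold — the flag is deliberately aggressive because a
missed sheath (ratio ≈ 2.0) must be caught reliably; excluded layers split
the transect for all pair statistics.

Transect direction is estimated from the averaged structure tensor
(reflective boundaries; near-axis estimates are snapped to the axis, a
<0.6% spacing bias, because an oblique line exits a tall narrow mosaic
after a few layers).

## Pair correlation and paracrystal assessment

All intra-transect pair separations within `x_max` (default 30·d̄) are
histogrammed at `bw` (default d̄/20) and normalized by `1/(k·bw)` with k
the number of sampled pairs, so `Σ g·bw·k` equals the pair count exactly.
A constant baseline plus per-order Gaussians is fitted jointly
(least squares, initialized at multiples of the median spacing with
σ-inits following √n).

The envelope amplitude `h_n` used for the correlation length is the
oscillation amplitude of the fitted curve — peak value minus the mean of
the model at the adjacent midpoints. For well-separated peaks this equals
the Gaussian amplitude; for overlapping high orders it converges to the
first-harmonic envelope `exp(−2π²σ₁²n/d²)`, which is the quantity that
fades when translational order is lost. (Defining `h_n` as the raw
component amplitude would decay only as `1/√n` and would place the loss of
order near n ≈ 100 instead of the observed ~16 at σ₁/d ≈ 0.088.)

Broadening exponent β from log–log regression of σ_n on n; classification
thresholds 0.15 (crystal-like) and 0.4 (ideal paracrystal).

## Spectral analysis

Bartlett averaging over 10 contiguous segments; each segment is linearly
detrended (not merely mean-subtracted: super-segment f^−1.5 power leaks
into the lowest bins otherwise and biases the slope by up to +0.1). The
power-law band is 0.0004 < f < 0.04 with the lower edge raised to
2/segment-length when unresolvable; exponent recovery is then within
±0.06 across α ∈ {0.5, 1.0, 1.5, 2.0} (Monte-Carlo, n = 2,500, 10
segments). High-frequency classification: log–log slope above f = 0.04,
with ±0.15 as the "flat" band.

## Angular order

2D FFT power (Hann-windowed; Welch row-blocks ≤ 24,576 rows bound memory on
tall mosaics); azimuth expressed as signed slope `s = f_x/|f_y|`. Three
numerical choices matter, each validated against the generator's
ground-truth slope distribution:

* the measurement band is selected by `|f_y|` (± 30% around the ring
  frequency), not by radius: every selected row then contributes its
  complete lateral modulation spread, whereas a radial annulus truncates
  the spread of rows near the annulus edges and biases the width low;
* the band sits by default at the **second** diffraction order, where the
  tilt geometry `s = f_x/f_y` is identical but the coherent Bragg spike
  that contaminates the first-order azimuth at modest roughness amplitudes
  (weight `e^(−β²)` with modulation index `β = 2π σ_u/d̄`) is suppressed as
  `e^(−4β²)`; the first order is used automatically when the second would
  exceed Nyquist;
* the slope SD is estimated by trimmed power-weighted second moments over
  the band *cells themselves* (cells sample slope space with near-uniform
  density; binned-density moments are corrupted by the sparse discrete
  satellite curves of the window lobe). The spectral second moment of a
  phase-modulated line equals the slope variance exactly at any modulation
  index, so the moment estimator carries no index-dependent smearing bias.

The noise floor (trimmed mean of cells beyond 0.75 of the azimuthal range)
is subtracted *signed* — clipping at zero would bias the tail moments
upward. A residual window-lobe-shaped central spike is measured as the
central excess over the locally interpolated pedestal and removed, and the
estimator's own widths — the lateral window's power-lobe variance
(computed from the window's DFT, scaled by the power-weighted ⟨1/f_y²⟩)
and the histogram bin — are deconvolved. The reported half-width is the
HWHM of the tilt-angle distribution implied by the slope SD
(`p(θ) ∝ N(tanθ; σ_s)·sec²θ`), the same numeric criterion the generator is
calibrated against. Validation: 12 seeds per preset (100 layers,
8,192 px wide) give 5.02 ± 0.19° (nominal 5°) and 15.01 ± 0.41°
(nominal 15°).

## Estimator caveats documented by design

* The rolling-mean-of-three deviation correlation has a null value of
  exactly −2/3 for uncorrelated growth (the filter (−1, 2, −1)/3 induces
  it); the package reports it for comparability but also provides
  `detrended_lag1_autocorrelation` (high-pass at 25 tablets, then direct
  lag-1 autocorrelation), whose null is ≈ 0 and which is monotone in the
  generator's φ.
* Defect detection from raw images is out of scope: densities are computed
  from annotated or synthetic-truth centers.
* The pair histogram is equivalent whether built from pairwise separations
  or cumulative thickness sums only for complete transects; the
  pairwise-separation construction is implemented.

## Problem sizes

Default test and reproduction runs use 100–1,000 layer renders at 3 nm/px
(65 px wide for transect statistics, 8,192 px wide for the angular
measurement), a 2,615-layer single-transect render for the layer count,
10 × 2,500-tablet realizations for the spectral exponent, and
10⁴–6×10⁴-layer position sets for the pair-correlation suites. These sizes
put every Monte-Carlo standard error comfortably inside the stated
tolerances on a single CPU; the full suite runs in about a minute and the
reproduction script in under a minute.
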