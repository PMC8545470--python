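# nacreorder

Quantification of mesoscale order in nacre — the periodically stacked
aragonite-tablet / organic-sheath composite of pearls and mollusk shells —
from cross-sectional electron micrographs or pre-extracted tablet-thickness
profiles.

Nacre tablets (~340–500 nm) stack along the growth direction with neither
perfect crystalline order nor unbounded disorder: each thickness error
displaces every subsequent layer (paracrystalline, cumulative disorder), yet
a self-correcting growth process — a tablet grown thick tends to be followed
by a thin one — limits how fast order is lost. This package measures that
balance:

* **detect** — interlamellar sheaths located as prominent local minima of
  smoothed backscatter-SEM intensity along transects perpendicular to the
  layering; the Nth tablet thickness is `x_{N+1} − x_N`; apparent
  double-thickness layers (missed sheaths) are flagged and excluded.
* **paircorr** — the 1D pair-correlation function `g(x)` of interface
  positions (all intra-transect pair separations, histogram normalized by
  `1/(k·bw)`), fitted with a constant baseline plus per-order Gaussians.
  For an ideal paracrystal the peak widths broaden as `σ_n = σ_1·√n`; the
  fitted exponent β in `σ_n = σ_1·n^β` classifies the stack between crystal
  (β≈0) and ideal paracrystal (β≈0.5). Translational order is lost at the
  first order whose envelope amplitude falls below 10% of the first peak's;
  that order × mean spacing is the correlation length.
* **growthstats** — the corrective-growth statistic: deviations from the
  centered rolling mean of three, `dev_N = w_N − (w_{N−1}+w_N+w_{N+1})/3`,
  correlated at lag 1. (Note: this estimator's null value under
  *uncorrelated* growth is exactly −2/3; a bias-free companion estimator is
  provided.) Also stage summaries (early/mature mean ± SD) and the growth
  rate (layers / lifetime).
* **spectral** — segment-averaged power spectral density of the thickness
  profile versus frequency in cycles/tablet; the 1/f^α exponent fitted over
  0.0004 < f < 0.04, and the high-frequency (f > 0.04) slope whose rise is
  the spectral signature of corrective growth.
* **morpho** — angular order: the azimuthal half-width (HWHM) of the
  diffraction ring bands of the 2D FFT, reported in degrees of interface
  tilt; topological-defect density = count / area with Poisson error.
* **synthgen** — a ground-truth synthetic generator: AR(1) corrective
  stacking plus spectrally synthesized f^−α environmental modulation,
  interface roughness with a calibrated tilt-angle half-width, BSE-like
  rendering (dark Gaussian sheath lines, blur, noise), and
  screw-dislocation insertion (terminating partial sheaths with ~28% local
  thinning).

## Worked example

Simulate a mature-stage pearl cross-section and analyze it end to end:

```bash
nacreorder run --preset mature --n-layers 500 --width 2048 --seed 1 --out out/
```

prints

```json
{
  "mean_thickness_nm": 334.2250981552504,
  "sd_thickness_nm": 114.44023230070384,
  "n_layers": 500
}
report -> out/report.json
```

i.e. the detected tablets average 334 ± 114 nm — the mature-stage
statistics (340 ± 120 nm) recovered through rendering and detection, with
the SD trimmed slightly because 9 of the 500 layers were flagged as
possible merged-layer artifacts and excluded. The full `out/report.json`
also contains the adjacent-deviation correlation (here −0.73; remember the
−2/3 null of this estimator), the paracrystal assessment (σ₁ = 118 nm,
β = 0.26, order lost by 5 layers ≈ 1.7 μm for this synthetic stack), the
spectral exponent with its high-frequency classification (`rising`, the
corrective-growth signature), and the angular half-width (4.5° on this
2,048-px-wide scene). Pass ``--days`` (pearl lifetime) to add the growth
rate in tablets/day and μm/day.

The same analyses are available as library calls (`nacreorder.detect`,
`.paircorr`, `.growthstats`, `.spectral`, `.morpho`) and as individual CLI
subcommands (`simulate`, `detect`, `paircorr`, `stats`, `spectrum`,
`angular`, `defects`).

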