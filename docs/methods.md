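# Methods

This note records the model behind `spicpms`, the numerical choices made in
the implementation, and the known limits of the approach. Symbols follow the
code: `N` windows in a trace, dwell time `t_dt` (ms), frequency–intensity
distribution = histogram of integer window counts.

## Signal model

A millisecond SP-ICP-MS trace is modeled as

- **Background**: each dwell window holds an independent Poisson draw with
  mean `λ · t_dt`, where `λ` is the dissolved-analyte count rate
  (counts/ms). At `λ = 4` and `t_dt = 10–20 ms` this puts 40–80 counts in
  *every* window, so small particle signals ride on, and overlap with, the
  background distribution.
- **Particles**: arrivals form a Poisson process in time. Each particle's
  whole-transient ion count is Poisson with mean
  `sensitivity × (particle Ti mass)`, and its rectangular transient of
  duration `τ` (default 0.5 ms) is split multinomially across the dwell
  windows it overlaps, in proportion to overlap time. At millisecond dwell
  most transients land in a single window (`P(split) = τ / t_dt`).

The simulator implements exactly this model and records per-particle ground
truth (diameter, total counts, windows touched, per-window deposits). It
deliberately does *not* model detector dead time, flicker noise, non-Poisson
plasma fluctuations, particle coincidence corrections (it only warns when
the expected event density exceeds 0.1 per window), or non-spherical
particles.

## Background correction

Given sample and blank frequency–intensity distributions with equal window
totals `N` and equal dwell time:

1. **Difference**: `diff(i) = f_sample(i) − f_blank(i)`. Because both sides
   sum to `N`, the difference sums to zero and its negative mass equals its
   positive mass exactly.
2. **Particle count**: `N_NP = Σ_i |diff(i)| · 1[diff(i) < 0]`. Windows the
   sample is "missing" at low intensities relative to the blank are windows
   that were promoted to higher intensities by particles.
3. **Background share**: `N_bgd = N − N_NP`.
4. **Scaled blank**: `f_blank(i) · N_bgd / N`, kept fractional (it sums to
   `N_bgd` within 1e-9 by construction; rounding here would silently move
   windows between the classes).
5. **Corrected difference**: `f_sample(i) − scaled(i)`. The transition
   intensity `I_t` is the largest intensity with a negative corrected
   frequency (−1 when no bin is negative); below it background dominates,
   above it particles dominate.

Particle events are the sample windows with intensity `> I_t`; each
contributes `round(max(diff_corr(i), 0))` events at net intensity
`i − I_mode`, where `I_mode` is the mode of the blank distribution
(smallest intensity on ties). Net intensities below 1 count are discarded —
they are below the quantization floor of the detector. A warning is logged
when `I_mode` and `I_t` differ by more than 2 counts; on realistic traces
the transition sits several background standard deviations above the mode
and the warning fires routinely — it is a diagnostic of that gap, not an
error.

**Statistical regime.** `N_NP` is unbiased only when the particle and
background intensity distributions barely overlap. Two failure modes
bracket it:

- *Overlap deficit*: if particles add only ~1σ of background to a window,
  much of the difference cancels and `N_NP` underestimates.
- *Sparse-bin noise*: with few counts per histogram bin, `Σ|negative|`
  accumulates the absolute value of zero-mean noise, a positive bias that
  grows with the number of occupied bins and dominates at high dilution.
  This is why a blank corrected against an *independent* blank yields a
  small nonzero `N_NP`, while the package's null control — a blank
  processed against itself — is exactly zero by construction.

## Calibration chain

| Quantity | Definition | Default |
| --- | --- | --- |
| Transport efficiency `η` | detected / introduced particles of a number standard | 0.057 |
| Sample flow `V` | nebulizer uptake | 0.28 mL/min |
| Sensitivity `S` | counts per g of dissolved Ti per window, through-origin OLS on dissolved standards (blank intensity subtracted) | LOD anchor, below |
| Molar ratio | MW(TiO₂)/MW(Ti) = 79.865/47.867 | 1.67 |
| Density `ρ` | bulk TiO₂ | 4.23 g/cm³ |

Mass per window for a dissolved standard of concentration `C` (µg/L) is
`m = η · V · t_dt · C` after unit conversion. A net intensity `I` converts
to diameter via `m_TiO₂ = (I / S) · 1.67` and
`d = (6 m / (π ρ))^{1/3}`. The size detection limit is
`lod_size = intensity_to_size(1)`: the diameter whose whole-particle signal
equals one count. `default_calibration()` anchors the sensitivity so that
`lod_size = 71 nm` — one count carries the Ti mass of a 71 nm TiO₂ sphere
(4.75 × 10⁻¹⁶ g Ti), i.e. `S ≈ 2.1 × 10¹⁵` counts/g.

## Size distribution assembly

Net intensities are integers, so sizes are naturally discrete on the
1-count grid. The pipeline:

1. removes particles below `lod_size`;
2. bins the rest to the nearest nm for reporting;
3. applies the rare-event tail filter — bins are removed from the largest
   size inward while their frequency is below the minimum (default 10),
   stopping at the first bin that meets it (interior sparse bins are never
   touched); the largest surviving bin is the **right wing**;
4. locates the distribution maximum (`max_position`) on the native 1-count
   intensity grid of the surviving events, then converts to nm.

Step 4 is a deliberate deviation from "take the argmax of the nm bins":
when the per-count size step drops below 1 nm (large intensities), nearest-
nm binning merges two integer count values into one bin, roughly doubling
its frequency and manufacturing a spurious, seed-independent mode at the
first merged bin. The 1-count grid is the measurement's own resolution and
has no such artifact.

## Fixture sensitivity

The simulation presets (`polydisperse`, `dilution-series`, `dwell-sweep`,
`monodisperse`) use `high_sensitivity_calibration()` — 5× the 71 nm-anchor
sensitivity, i.e. a ~41.5 nm detection limit, representative of
collision-cell instruments. At the 71 nm anchor a median-150 nm lognormal
population produces ~9 counts per particle over a 64-count background
(16 ms dwell): ~1σ of background, squarely in the overlap-deficit regime
where *no* histogram method can count particles reliably. The correction's
own precondition is that particle signals be resolved from the background;
the presets are chosen to satisfy it while keeping everything else
(background rate, dwell grid, population) at realistic values.

## Known limitation: mode versus median

For a lognormal size distribution with median `d_m` and geometric SD `g`,
intensity is proportional to `d³`, also lognormal, with median `∝ d_m³` and
log-sd `3 ln g`. Its mode in count space is
`median · exp(−(3 ln g)²)`, so the *size* at the histogram maximum is
`d_m · exp(−3 ln² g)` — for `g = 1.3` about `0.81 · d_m ≈ 122 nm` when
`d_m = 150 nm`, before counting noise. The corrected distribution maximum
therefore recovers near 120 nm, not the median, and the acceptance test
asserting the mode within 5% of 150 nm fails for this analytic reason (the
particle-count clause of the same scenario passes). The median of the
corrected distribution, also reported by `scripts/acceptance.py`, is the
estimator that tracks `d_m`.

## Dilution and dwell-time behavior

- **Dilution series**: one blank trace is shared across all factors — the
  experimental situation of correcting every dilution against the same
  deionized-water run — so the modal background is invariant across the
  series by construction, and recovered `N_NP` is linear in 1/factor
  (R² > 0.95 at the fixture seeds) until the sparse-bin noise floor is
  reached.
- **Dwell sweep**: one particle population is drawn once and re-deposited
  on each dwell grid, so differences across {4, 10, 16, 20} ms reflect only
  window splitting and the dwell-scaled background. Uncorrected (gross
  intensity) distribution maxima rise strictly with dwell time because the
  background contribution `λ · t_dt` rides along; corrected maxima drift
  substantially less, which is the point of the method.
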