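# Methods

## Signal model

A pulsed-laser photoacoustic (PA) measurement of a hydrogel phantom is
modeled as the impulse response of an underdamped second-order
linear-time-invariant system.  The physical constants of the underlying
thermoacoustic wave equation (thermal expansion coefficient, heat
capacity, bulk and shear viscosities, the Gruneisen parameter, the
propagation constant) are not separately identifiable from a single
output trace; they are lumped into three parameters:

* `omega_n` (rad/s) — natural frequency, the resonance carrier of the
  ring-down;
* `zeta` (dimensionless) — damping ratio, with `0 <= zeta < 1` assumed
  (the observed PA traces oscillate, so the system is underdamped);
* `gain` (V·s) — impulse magnitude, absorbing the optical forcing and
  thermoelastic conversion efficiency.

The forward simulator produces

```
y(t) = gain · (omega_n/√(1−zeta²)) · e^(−zeta·omega_n·(t−delay)) · sin(omega_d·(t−delay))
```

for `t ≥ delay` and zero before, with `omega_d = omega_n·√(1−zeta²)`.
The mechanical ratios `k/m = omega_n²` and `b/m = 2·zeta·omega_n` are
exposed (`physical_ratios`); the individual `k`, `b`, `m` are not.

Noise model: additive white Gaussian noise, with SNR defined on the RMS
of the noise-free trace over its support (`t ≥ delay` to the end of the
record).  Real acquisition noise is broadband and approximately white at
the oscilloscope front end, which this emulates; correlated interference,
trigger jitter and transducer ringing are *not* modeled.

## Discretization

`discretize` maps the continuous model to a discrete `{A, B, C}` through
the matrix exponential of the companion form, so the discrete eigenvalues
are exactly `exp((−zeta·omega_n ± j·omega_d)·Ts)` and the discrete impulse
response interpolates the continuous one at the sample instants.
`extract_modal_params` inverts this map through the principal branch of
the complex logarithm of the eigenvalue with positive imaginary part
(conjugate pairs carry identical modal content): `omega_n = |ln λ|/Ts`,
`zeta = −cos(∠ ln λ)`.  A real pole in (0, 1) maps to `zeta = 1`
(critically damped limit); a pole on the negative real axis sits on the
branch cut and triggers a warning rather than a hard error.  The
round-trip discretize → extract is the identity to ~1e−15 relative error
across `zeta ∈ [0.05, 0.95]`, `omega_n·Ts ∈ [0.01, 1]`.

## Subspace identification

`n4sid_fit` implements output-only N4SID:

1. **DC removal** — the *median* of the record is subtracted, not the
   mean: an impulse-like record spends most samples near the baseline, so
   the median estimates the offset without injecting a spurious constant
   mode (mean removal of a transient demonstrably raises the Hankel rank
   from 2 to 3).
2. **Decimation** — oscilloscope records oversample the transducer band
   by orders of magnitude, which ill-conditions the Hankel matrix.  The
   trace is block-averaged (boxcar) down to ~30 samples per period of the
   dominant spectral component.  A boxcar was chosen over a sharp FIR
   low-pass deliberately: white-noise variance still falls by exactly the
   decimation factor (identical to an ideal low-pass to the new Nyquist
   band), the filter's support of q raw samples confines the onset
   transient to a single decimated sample (a long FIR smears the onset
   over ~20 output samples and contaminates the subspace), and since any
   LTI filter preserves exponential modes exactly, the passband droop
   (<1% at 20+ samples/period) rescales amplitudes without biasing the
   eigenvalues that carry `omega_n` and `zeta`.
3. **Windowing** — identification runs on the ring-down segment: from the
   first sample exceeding 10% of the global peak (skipping the one
   decimated sample that straddles the onset) to the point where the
   half-period running maximum of |y| falls below max(2% of peak, 1.5×
   its median — a noise-floor proxy), but never shorter than three
   oscillation periods, because heavily damped members would otherwise
   leave too few Hankel columns for a stable estimate.
4. **Hankel + projection** — past/future block Hankel with `i = 20` block
   rows (shrunk to a quarter of the window when the window is short);
   the orthogonal projection of future outputs onto the row space of past
   outputs.  No input is measured — the laser pulse is an impulse — so
   past outputs serve as the instruments and the oblique projection
   degenerates to an orthogonal one.  An optional measured-input path
   implements the full oblique projection.
5. **Order selection** — largest relative gap in the singular values,
   restricted to candidates with `s_k/s_1 ≥ 1e−2`.  On noise-free
   second-order data the third singular value is at machine epsilon and
   the rule returns 2; at 20 dB SNR it still returns 2 in all tested
   realisations.
6. **Regression** — `Γ_i = U₁S₁^½`, state sequences by pseudo-inverse
   (relative cutoff 1e−12 everywhere; no explicit inversions), then one
   least-squares solve for `{A, C}` (and `B` when an input is supplied).
7. **B and fit quality** — with no input, `B` is taken from the
   least-squares initial state `x₀` of the free response `y_k = C A^k x₀`
   on the fitted window (an impulse one step before the window start
   would place the state there).  The reported NRMSE compares that free
   response against the *preprocessed* segment the model was fitted to —
   the decimated, windowed trace — which is the standard convention of
   judging a model on the data used for estimation.  The `gain` slot of
   the extracted modal parameters is left at 1: amplitude is carried by
   `B`/`x₀`, not by `A`.

Noise-free recovery is exact to ~1e−14 relative error with NRMSE ≈ 100;
at 20 dB SNR the median damping-ratio error over 50 noise realisations is
below 1%.

## Synthetic panel

The generator emulates the nine-hydrogel study panel: PVA 7, 9, 12, 15,
20% at the lower molecular weight (MW1) and 7, 9, 12, 15% at the higher
(MW2).  Per-member parameters:

* `zeta(conc)` linear, 0.10 at 7% to 0.50 at 20% (MW1); MW2 offset +0.04
  — damping rises with both concentration and molecular weight;
* `f_n(conc)` quadratic, 3.0 MHz at 7% down to 1.2 MHz at 20% (MW1); MW2
  offset −0.2 MHz — around the 2.25 MHz transducer band;
* diameters, acoustic delays and peak-to-peak amplitudes anchored to the
  measured panel values (e.g. MW1 7%: D = 39.70 mm, tₐ = 25.60 µs,
  A = 0.87 mV), so arrival times and amplitudes rise with concentration
  exactly as observed;
* records of 40 µs at 1 ns sampling (1 GS/s, a tractable stand-in for the
  instrument's 10 GS/s; the oscillation is still oversampled ~300–800×),
  20 dB SNR per shot, and **three-shot averaging** per trace, matching
  the measurement protocol in which every reported value is the average
  of three recordings.

What passing tests on this panel do show: the identification pipeline
recovers modal parameters and their concentration trends from noisy,
delayed, amplitude-scaled ring-downs of realistic record geometry.  What
they do not show: robustness to transducer band-pass coloration,
multipath reverberation, trigger jitter, or non-impulsive forcing — real
traces contain all of these.

## Optics

Sphere observables are computed exactly as defined (`Rcd = m·Pr/Pd`,
`Tcd = m·Pt/Pd`, `Tc = Pcoh/Po`, wall coefficient m = 0.98 by default).
The forward model behind the inverse estimator is deliberately minimal: a
homogeneous slab with Henyey–Greenstein scattering, index-matched
boundaries by default (optional Fresnel boundaries with total internal
reflection via `n_rel`), no sphere-exchange corrections and no specular
port.  It is this package's own documented stand-in for a full
integrating-sphere radiative-transfer treatment, adequate for ~100 µm
films at moderate optical depth.

The Monte-Carlo engine uses **absorption weighting** (a fraction
`µa/µt` of each photon's weight is deposited at every interaction) rather
than terminal absorption, and assigns random numbers per photon slot and
event index.  Both choices make the tallies a *smooth, deterministic*
function of (µa, µs, g) for a fixed seed — common random numbers — which
the Nelder–Mead inversion requires; with naive per-survivor draws the
objective is rugged and the simplex stalls on noise plateaus.  Weight
bookkeeping is exact: reflected + transmitted + absorbed + residual
weight sums to the photon count to ~1e−15.

Inversion: Nelder–Mead over (ln µa, ln µs, artanh g) from the start point
(0.5 cm⁻¹, 20 cm⁻¹, 0.7), 10⁵ photons per evaluation, up to 400
iterations.  The convergence tolerance (1e−4) applies to the simplex
spread in log-parameter space; a residual-based tolerance is useless here
because the coherent transmittance of a thin film is so insensitive to µa
that parameter errors of tens of percent change the residual by less than
1e−6.  When `Tc` is negligible (as for the lower-MW films) only two
informative observables remain and `fix_g` pins the anisotropy; `fix_mu_s
= 0` switches to the closed-form Beer–Lambert inverse `µa = −ln(Tc)/d`.
An all-zero measured triplet is flagged as diverging absorption rather
than fitted.  Anisotropy is the softest direction of the full
three-parameter fit — Rcd and Tcd constrain mainly the reduced scattering
µs(1−g) — so g recovery is not asserted in the tests.

## Porosity and mechanics

Pore diameters are binned into half-open decade bins [0,10), …, [70,80)
µm (the half-open convention resolves the overlapping printed labels of
such histograms); out-of-range diameters are counted separately so totals
are conserved.  A scaled LogNormal *density* is fitted to the counts at
bin midpoints by bounded nonlinear least squares — fitting the histogram
curve, not a maximum-likelihood fit to the raw diameters, mirroring how
such distributions are usually summarised.  The bounds anchor the
distribution to the observed diameter range (log-location within
[ln(x₁/4), ln(2·x_max)], shape in [0.05, 3]): without them the far tail
of an arbitrarily displaced, arbitrarily broad LogNormal can mimic any
slowly varying curve, including a constant.  For constant counts (zero
variance) R² is reported as 0 unless the residuals vanish.

Density ρ = m/V and Young's modulus E = σ/ε are direct quotients.  The
PVA-weight recipe is implemented as `concentration × volume / 100`, the
product form required by its own worked value (7% with 150 mL → 10.5);
the recipe's printed unit ("mg") is dimensionally inconsistent with
percent × millilitres (which yields grams) — the numeric value is
returned and the unit is reported as printed.

## Numerical choices and degenerate inputs

* Pseudo-inverse cutoff 1e−12 (relative) throughout the subspace path.
* Constant or all-zero traces raise a no-dynamics error; an all-zero
  singular spectrum selects order 0 with a warning.
* Arrival detection requires the global peak to exceed 5× the baseline
  noise RMS (baseline = first 10% of the record); the default criterion
  is the first crossing of 10% of the peak, with a first-local-extremum
  alternative.  Speeds of sound are reported rounded to integer m/s.
* Identified models with |eigenvalue| ≥ 1 are flagged unstable, not
  rejected.
* Times are seconds and amplitudes volts internally; reports use µs and
  mV.

## Known limitations

* The second-order lump cannot separate the physical constants it
  absorbs; only `omega_n`, `zeta` and the ratios `k/m`, `b/m` are
  identifiable from one trace.
* The slab Monte Carlo omits sphere exchange, specular ports and
  layering; absolute optical properties from real sphere data would
  inherit those simplifications.
* The LogNormal histogram fit inherits midpoint-approximation bias for
  very coarse bins; with the fixed 10 µm bins and 10⁴ pores the bias is
  within the tested 5% tolerance.
* Heavily damped members (ζ ≈ 0.5) carry only ~1.5 visible oscillations;
  their estimates have intrinsically higher variance, which drives the
  minimum panel NRMSE.
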