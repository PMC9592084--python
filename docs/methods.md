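# Methods

## TCSPC model and the tau8 fit

A periodically pulsed laser (period T = 12.5 ns) excites a fluorophore
whose emission decays as a mixture of exponentials; detection timing is
blurred by a Gaussian instrument response function (IRF).  The expected
arrival-time density on [0, T) is the closed-form exp⊗Gauss response

    h(t) = (1/2τ) · exp(σ²/2τ² − (t−t₀)/τ) · erfc((σ/τ − (t−t₀)/σ)/√2)

summed over the current and all previous pulses (k = −1 … K, with K
chosen so the truncated geometric tail is < 1e−15), plus an optional
uniform background.  The implementation integrates the analytic CDF
over bins and is stabilised with `erfcx` so it is exact to rounding for
any σ > 0 and τ; the periodic sum is verified in the tests against
direct numerical quadrature (< 1e−6 relative per bin).

Fitting restricts the data to the window from the peak-count bin
(earliest bin at the maximum) to 8 ns past it and maximises the
conditional multinomial (Poisson) likelihood of the windowed counts;
Poisson-weighted least squares is available as an option.  Parameters
are log-lifetimes, one amplitude fraction (two-component fits), and
optionally the IRF centre and width; optimisation is L-BFGS-B with
bounds τ ∈ [0.01, 50] ns, 500 iterations max, ftol 1e−12.
Two-component fits are initialised at 0.5× and 2× the empirical mean
arrival time past the peak with equal amplitudes; degenerate solutions
(lifetimes within 1 %) collapse to one component with a warning.

**tau8 definition.**  For a multi-component fit the scalar lifetime
readout is the amplitude-weighted mean Σ aᵢτᵢ of the windowed fit.  It
reduces to τ for a mono-exponential and is strictly increasing in each
component lifetime, which is what a scalar "lifetime" readout should
do.

**Background is fixed at 0 by default.**  A post-peak window carries
almost no information separating a uniform background from the wrapped
tail of a slow decay component; freeing the background visibly biases
tau8 (errors up to ~0.2 ns at 5×10⁵ photons in our simulations, versus
< 0.02 ns with it fixed).  `fit_background=True` restores the free
parameter for data where background genuinely matters and the window is
wide.

**Binning.**  256 uniform bins over the period (~49 ps), a standard
TCSPC depth that resolves IRF widths of 0.1–0.3 ns.

## Spectral unmixing

The bleed-through ratio is estimated as the mean of per-control-ROI
red/green count ratios (spread reported as their sample SD), matching
the per-cell-percentage convention of the measured 0.053 value.
Correction is `red − ratio·green` applied to photon counts before
lifetime fitting (per bin) or to frame intensities; small negative
results from Poisson noise are clamped to zero and counted in the log.

## Transient quantification

* Baseline: mean of all samples in the 60 s before the stimulus (the
  window length is a package choice; acquisitions have 10–60 s frame
  spacing at rest, so this typically averages 1–6 frames).
* Peak: extremum of (value − baseline) after the stimulus — minimum
  for quench-type signals (SBFI ΔF/F), maximum for lifetime increases.
* Half-decay: from the peak to the first linearly interpolated
  crossing of the halfway-to-baseline level; flagged undefined if the
  trace never returns halfway.  Computed on raw (unbinned) samples.
* Quality rules for ΔPeredox/ΔRCaMP ratios: recordings are excluded
  when |ΔRCaMP| < 0.2 ns (noisy denominator) or when the RCaMP
  half-decay is ≥ 35 s (poorly stimulus-locked Ca2+ transient).  An
  exclusion is a result object naming the failed rule, never an error.
* Cohort averages: per-trace times are stimulus-aligned, rounded to
  1 s outside a (0, 2) s stimulation window and to 10 ms inside it,
  then linearly interpolated onto the union grid with no
  extrapolation; per-point n is tracked and SEM = SD/√n.
* Group comparisons: Shapiro–Wilk at α = 0.05 on each group gates
  t-tests (paired or two-sample) versus Wilcoxon / Mann–Whitney.
  Constant groups, for which Shapiro–Wilk is undefined, are treated as
  normal; identical paired samples short-circuit to p = 1 (the null is
  exactly true and the test statistics are degenerate).
* Box summaries report mean, median, and the 5–95 % range with
  linear-interpolation percentiles.  Ratio summaries carry both SD and
  SEM, since either spread convention appears in practice.

## SBFI calibration

The calibration functional form is a single-site binding quench,
F(Na) = F_free·(1 − a·f(Na)) with f(x) = x/(K_d + x), K_d = 26 mM, and
ΔF/F referenced to rest (13 mM).  The quench amplitude a = 0.74 is a
package constant fitted once to the anchor −25.6 % ↔ +25 mM; the
second anchor (−11.5 % → +8.3 mM, rounding to 8) then follows without
further freedom and is asserted in the tests.  The inversion is exact
algebra; its valid domain runs from the maximal quench (Na → ∞,
excluded) to the maximal brightening (Na = 0), so positive ΔF/F maps
to Na+ falls below rest.  Reported conversions carry both raw values
and convention-rounded ones (mM to the nearest integer, percent
activity to the nearest 5 points, fold changes to the nearest 0.5).

The α3 isozyme has no defensible K½ default (literature activation
curves are not jointly consistent with a single Hill curve at n = 3),
so it must be supplied explicitly in the config when used.

## Synthetic experiment generator

The generator embodies the mechanistic narrative the analysis is built
to test, as a *data generator*, not a biophysical model:

    dCa/dt   = J_ca(t)·block − (k_ncx·[Na_ext] + k_other)·(Ca − Ca_rest)
    dNa/dt   = J_na(t) + c·k_ncx·[Na_ext]·(Ca − Ca_rest) − v_max·(h(Na) − h(Na_rest))
    dNADH/dt = g·v_max·(h(Na) − h(Na_rest)) − k_nadh·NADH

with h the Hill activation, [Na_ext] ∈ {0, 1} gating forward NCX, and
NADH expressed directly in ns of Peredox lifetime change.  Sensor maps:
RCaMP LT = 0.88 ns + 0.6 ns/µM·ΔCa (linear; no lifetime↔[Ca2+] curve is
available, so saturation is deliberately omitted); Peredox LT =
1.63 ns + NADH; SBFI F = F₀·(1 + ΔF/F(Na)) through the calibration
above.  Integration is fixed-step RK4 at 10 ms (the system is
non-stiff at these rates and a fixed step keeps runs bit-reproducible);
negative concentrations abort with advice to reduce the step.
Cumulative NCX Ca2+ clearance and Na+ load are co-integrated so the
3:1-derived proportionality can be asserted to < 0.1 %.

**Parameter choices (set once, from the observed scales).**
Ca2+ clearance 0.7 s⁻¹ total (NCX 0.5, other pumps 0.2) gives the ~1 s
Ca2+ half-decay; stimulus influx rates (3.2 mM/s Na+, 0.5 µM/s Ca2+
for 2 s, i.e. 100 pulses at 50 Hz) and the free-Ca→Na conversion
factor c = 31 mM/µM were chosen so the control peak ΔNa is ~25 mM and
the Ca2+-blocked peak ~8 mM with block factor 0.145; pump v_max =
1.2 mM/s puts the Na+ half-decay in the tens of seconds; NADH gain
0.005 ns per mM pumped and decay 0.012 s⁻¹ put the Peredox peak
(~0.08 ns) about a minute after the stimulus.  The factor c lumps the
strict 3 Na+ : 1 Ca2+ molar stoichiometry with cytosolic Ca2+
buffering (free-Ca2+ changes understate the total Ca2+ flux the NCX
actually moves) and volume terms.

**Noise.**  Per-sample measurement noise is Gaussian, default 0.01 ns
on lifetimes and 1 % on SBFI intensity — the shot-noise scale of
~10⁵-photon frames.  The ±0.05–0.09 ns spreads seen across cells are
modelled instead as log-normal cell-to-cell parameter jitter
(CV = 0.2) applied to influx rates, pump v_max, and sensor gains, with
the same factors reused across both arms of a paired cohort.

**Sampling** mimics acquisition cadence: 15 s frame spacing at rest,
250 ms within (−10, +30) s around the stimulus.

**Photon-level rendering** realises each lifetime sample as a
two-component decay with fixed lifetimes (0.4, 4.5) ns and the long
amplitude solved linearly so the amplitude-weighted mean equals the
sensor lifetime; green→red contamination is binomial thinning at the
configured ratio.  This closes the loop for full-stack tests:
histograms → (unmix) → tau8 fits → traces → transients → calibration.

**What passing tests do and do not show.**  The generator reproduces
the *structure* of the real experiments — timescale ordering (Ca2+ ≪
Na+ ≪ NADH), paired protocol contrasts, exclusion-rule behaviour, and
sensor-map invertibility — so a green suite shows the pipeline
measures what it claims on data of that structure at realistic photon
budgets.  It does not validate the kinetic model against biology:
clearances are linear, Ca2+ pumps are lumped, mitochondrial Ca2+ and
pharmacology are absent, and the NADH→lifetime gain is a modeling
convenience with no measured counterpart.

## Problem sizes

Cohort tests use 13 paired cells (matching the paired-recording design
they emulate) simulated to 150–300 s past the stimulus; photon-level
round trips use 10–12 frames at 10⁵ photons each; fit-recovery tests
use 10⁶ photons (mono-exponential) and 5×10⁵ (biexponential).  The
whole suite runs in a few minutes on one core.

## Known limitations

* No pile-up, afterpulsing, >2-component decays, or phasor analysis.
* The Peredox↔RCaMP unmixing ratio used upstream of this package is
  not known numerically; it is configurable and defaults to 0.
* `bin_and_average` assumes traces share a common stimulus alignment;
  it does not correct clock drift between recordings.
* The ion-substitution protocol is represented only as "Ca2+ load with
  forward NCX disabled"; reverse-mode NCX kinetics are not modelled.
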