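# flimphot

Fluorescence-lifetime photometry analysis for neuronal metabolism
experiments: TCSPC lifetime fitting, two-channel spectral unmixing,
stimulus-evoked transient quantification, SBFI sodium calibration, and
Hill-model Na+/K+-pump activation estimation — with a synthetic
experiment generator that exercises the whole pipeline end to end.

## Who this is for

Labs using two-photon fluorescence-lifetime imaging (FLIM) of
genetically encoded biosensors — Peredox (cytosolic NADH:NAD+), RCaMP
(Ca2+) — together with intensity-mode dyes such as SBFI (Na+) to study
how neuronal stimulation couples ion transport to glycolysis.  The
package takes per-ROI photon-arrival histograms and sensor time series
and turns them into calibrated physiological estimates.

## The models at the core

**tau8 lifetime readout.**  Photon arrival times relative to the 80 MHz
laser pulse (12.5 ns period) are histogrammed and fitted with a
biexponential decay convolved with a Gaussian instrument response
function, restricted to a window up to 8 ns after the histogram peak.
The expected curve uses the closed-form exponential⊗Gaussian
convolution with periodic wrap-around (each excitation inherits the
residue of all previous pulses).  tau8 is the amplitude-weighted mean
lifetime Σᵢ aᵢτᵢ of the windowed fit.

**Spectral unmixing.**  Green-emitting fluorophores bleed into the red
channel by a fixed ratio r (0.053 for SBFI, measured from control
cells); the correction is red − r·green, per histogram bin or per
frame.

**SBFI calibration.**  SBFI fluorescence at 790 nm excitation is
quenched by Na+ with a single-site isotherm (K_d = 26 mM).  With
f(x) = x/(K_d + x) and quench amplitude a = 0.74,

    ΔF/F(Na) = −a·(f(Na) − f(Na_rest)) / (1 − a·f(Na_rest)),  Na_rest = 13 mM,

inverted algebraically to estimate stimulus-evoked Δ[Na+].

**Hill pump activation.**  Na+/K+-pump activity as a function of
intracellular Na+ is v/v_max = Naⁿ/(Naⁿ + K½ⁿ) with Hill coefficient
n = 3 (three transported Na+) and K½ = 13 mM for the α1β1 isozyme.
Transport stoichiometry: the pump moves 3 Na+ out / 2 K+ in per ATP;
forward Na+/Ca2+ exchange imports 3 Na+ per Ca2+ extruded.

## Worked example

```python
from flimphot import (SBFICalibration, HillPump, na_from_dff,
                      hill_fraction, fold_activation)

calib = SBFICalibration()          # Kd 26 mM, rest 13 mM, a = 0.74
pump = HillPump()                  # alpha1beta1: K1/2 13 mM, n = 3

dna = na_from_dff(-0.256, calib)   # peak SBFI dF/F in control solution
print(round(dna, 2))               # 25.55  -> ~25 mM Na+ rise
peak = 13.0 + dna
print(round(100 * hill_fraction(peak, pump), 1))   # 96.4  -> ~95 % of max
print(round(fold_activation(13.0, peak, pump), 2)) # 1.93  -> ~2-fold
```

A quenching of −25.6 % maps to a ~25 mM Na+ rise above the 13 mM
baseline, which drives the α1β1 pump to ~95 % of its maximal activity —
about twice its resting rate.  The same call chain with the
Ca2+-entry-blocked peak (−11.5 %) gives ~8 mM, ~80 % and ~1.5-fold.

The full synthetic pipeline (simulate a paired 13-cell cohort, extract
transients, convert and compare) runs from the command line:

```bash
flimphot run --seed 1 --out results/
flimphot convert-na --dff -0.256
flimphot pump-activity --na-base 13 --na-peak 38
```

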