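# Methods

This note documents the models, measurement conventions, parameter defaults
and numerical choices behind `slicephys`, and what the validation suite does
and does not establish.

## Measurement conventions and units

Voltages are mV as recorded: the liquid junction potential of a
K-gluconate internal against recording aCSF (−13 mV by calculation) is
deliberately never subtracted, and is kept only as a provenance constant.
Currents are pA, resistances MΩ with R[MΩ] = 1000·ΔV[mV]/I[pA], AP kinetics
ms, trace time s. All conversions happen at I/O boundaries.

## Subthreshold features

**Baseline / RMP.** All measurements are referenced to rest. The baseline
window is the 100 ms immediately preceding step onset — long enough to
average noise, short enough to avoid slow drift. When a sweep carries
50–100 ms of pre-step data the window falls back to the 50 ms minimum;
below 50 ms the sweep is rejected. A neuron's RMP is the mean of per-sweep
baselines.

**Deflections.** The steady-state deflection is the mean of (V − RMP) over
the final 100 ms of the 1 s step, far beyond any plausible sag time
constant. The maximum deflection is the extremum of (V − RMP) within the
step, taken in the direction of the step's sign so that wrong-sign noise
extrema cannot be selected. The extremum is located on a 5 ms moving
average of the trace: the raw extremum of signal-plus-wideband-noise over
50 000 samples is biased outward by several tenths of a millivolt, which
would corrupt the sag ratio; a 5 ms window suppresses that bias while
distorting the ≥ tens-of-ms sag peak negligibly. The steady-state measure
uses the raw trace.

**IV fits and the linear portion.** The IV curve uses all steps in
[−150, +50] pA that elicit no detected AP (spiking sweeps are excluded with
an explicit signal, never silently). Both deflection series are fit by
ordinary least squares of mV on pA; R_N is 1000 × slope. "Linear portion"
is realized deterministically: fit everything; while the steady-state fit
has R² < 0.98 and more than three points remain, drop the most
hyperpolarized point (the region where inward rectification bends the
curve). Both fits use the same final subset. Sag ratio is
R_N(max)/R_N(steady-state); the per-sweep extremum bounds the plateau, so
the ratio is ≥ 1 up to fit noise — when the two independent fits dip a hair
below unity for sag-free cells, extraction floors the ratio at 1.0 and
flags `sag_floored_at_unity`.

## Action potentials

**Detection.** dV/dt is computed by central differences on the raw trace
(no smoothing: filtering shifts threshold timing). An event begins at the
first sample of each upward dV/dt excursion past 20 mV/ms. Its peak is the
voltage maximum up to where dV/dt first returns to ≤ 0. Three gates keep
the detector honest under wideband measurement noise, whose derivative at
50 kHz is several mV/ms in SD: (i) a candidate must rise at least 20 mV
from threshold to peak (real APs here are 60+ mV); (ii) accepted events
must be ≥ 2 ms apart; (iii) a new event cannot begin until the voltage has
repolarized below the previous event's threshold. The height gate is this
package's addition to the bare derivative criterion; without it a
20 mV/ms crossing rule false-positives on noise alone.

**Kinetics.** Amplitude is threshold-to-peak. Half-width is the time
between the linear-interpolated upward and downward crossings of
threshold + amplitude/2; when the trace ends before the downward crossing
the half-width is absent and flagged. The AP analyzed for kinetics is the
one fired 40–50 ms after step onset at the lowest qualifying amplitude;
when no sweep qualifies the extractor falls back to the first AP of the
rheobase sweep and flags `kinetics_window_fallback`, preserving the neuron
while marking the protocol deviation.

**Trains.** Among sweeps with 7–13 APs the one closest to 10 is analyzed
(ties to the lower amplitude). SFA = last ISI / first ISI; CV uses the
sample standard deviation (n − 1). ISIs are measured between threshold
times.

## ΔF/F

ΔF/F(t) = (F(t) − F0)/(F0 − FB). The "about 200 ms" baseline is realized
as exactly 200 ms ending at stimulus onset (first 200 ms when no stimulus
is given) for determinism. FB is a per-trace scalar from a designated
background region; background selection, ROI segmentation, bleaching
correction and spike inference are out of scope. Stimulus-response curves
recompute the baseline per bout and take the peak from bout onset to 2.4 s
past bout end (≈3 indicator decay constants). Transient detection
(threshold k·MAD-noise for ≥ 0.2 s, gaps < 0.1 s merged) goes beyond the
source analyses; its parameters are configurable and flagged as such.

## Statistics

Feature-vs-time uses ordinary least squares with r² equal to the squared
Pearson correlation and a two-sided p for zero slope. Two-group contrasts
use Welch's unequal-variance t-test (zero-variance/equal-mean degenerate
case: statistic 0, p = 1, flagged) or the Mann-Whitney U test. U is
computed by the pair-count convention (½ per tie); the reported statistic
is min(U_ab, U_ba); p is exact when the smaller group has ≤ 8 observations
without ties, else the tie-corrected normal approximation. Scipy supplies
the p-value distributions; the U pair count itself is cross-checked in the
tests against an exhaustive double loop. p-values are deliberately raw —
no multiple-testing correction — and every report says so. Neurons are
treated as independent; within-case (per-surgery) correlation is not
modeled, a documented limitation. The tumor-vs-epilepsy contrast is
restricted by default to the 0–12 h post-slicing window (configurable).

## Forward simulators

**Passive sweeps** follow a closed form with a fast charging component
(τm) and a slower opposing sag component (τh > τm): the effective
resistance curve is B(t) = r_ss(1 − e^{−t/τm}) + r_sag(e^{−t/τh} −
e^{−t/τm}), giving steady-state resistance r_ss = r_input − r_sag exactly
and a ground-truth R_N(max) computed as the dense-grid extremum of B.
Defaults: rest −69 mV, r_input 150 MΩ, r_sag 30 MΩ, τm 20 ms, τh 80 ms.

**Spiking sweeps** use an adaptive integrate-and-fire update: the membrane
relaxes toward v_rest + (I − w)·r_ss with τm, spikes at a fixed threshold,
and each spike increments an adaptation current w (default 25 pA ×
`adaptation_strength`, decaying with τw = 250 ms), producing graded
accommodation. Between spikes the system is linear, so it is advanced by
its exact closed-form solution evaluated on the sample grid — an
exponential integrator on a linear system is exact — keeping spike times
grid-aligned and bit-reproducible. At each spike a parametric AP waveform
is spliced in: an exponential rise saturating toward 1.5× amplitude (so
the initial slope equals `upstroke_rate` exactly at threshold) truncated
at the peak, then an exponential fall toward a −12 mV
afterhyperpolarization, its time constant solved analytically so the
continuous waveform's width at half amplitude equals `halfwidth_true`
exactly. Kinetic ground truth is therefore analytic, at the cost of a
slight corner at the peak (sub-sample; the sampled peak underestimates the
true one by well under 1 mV at 50 kHz). Waveforms shorter than the
refractory period raise an internal-consistency error, as do half-widths
geometrically infeasible for the requested upstroke.

**Noise** is additive white Gaussian on the recorded trace only, so spike
times and ground truths are independent of the noise draw. No pink or
synaptic noise is simulated — real recordings are harder than this, and
passing recovery tests bounds algorithmic error, not robustness to every
artifact of patient tissue.

**Fluorescence** is linear summation of per-spike double-exponential
transients (rise 0.1 s, decay 0.8 s, 0.15 ΔF/F per spike — GCaMP6s-like),
mapped to raw counts via F = FB + (F0 − FB)(1 + ΔF/F) + noise at 30
frames/s. No bleaching, motion or nonlinear indicator saturation.

**Cohorts** draw per-neuron parameters from configurable normal
distributions, with optional linear covariate effects on hours
post-slicing (sampled uniformly over 1–75 h, matching the span of an
acute-slice viability study). Defaults: RMP −69 ± 2 mV, r_input 150 ± 20
MΩ, r_sag 30 ± 8 MΩ, threshold −40 ± 2 mV, amplitude 80 ± 5 mV, half-width
1.0 ± 0.1 ms, measurement noise 0.2 mV. Default sweep rate 50 kHz
(data-declared on load; real acquisition rates vary).

## Validation battery and problem sizes

`slicephys.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: a 5×5 (r_input × r_sag) recovery grid at
0.2 mV noise; 500 random AP templates at 50 kHz; 1000 adapting trains
checked against the simulator event log (counts must match exactly; SFA
and CV within the ISI perturbation implied by a few samples of threshold
jitter — under 0.3 mV noise the detected threshold time can move up to ~4
samples); statistics oracles (exhaustive pair-count U, closed-form Welch,
Pearson identity); 1000-run null calibrations of the regression and Welch
tests; 200 cohorts of 100 neurons recovering an imposed 0.1 mV/h RMP drift
end-to-end. The cohort runs use a reduced three-step subthreshold protocol
at 10 kHz: RMP and R_N are baseline/plateau quantities for which the full
12-step 50 kHz protocol adds nothing to the estimand, and the reduction
keeps the 20 000-neuron study tractable on one CPU.

## Known limitations

- The simulators are phenomenological: no conductance-based dynamics, no
  morphology, no synaptic background. A sweep within one step of rheobase
  can transiently exceed threshold through its sag peak without spiking,
  an artifact of separating the passive and spiking generators.
- Inward rectification is only represented through the linear-portion
  dropping rule, not simulated.
- Membrane time constant and capacitance are not extracted.
- Voltage-clamp data, proprietary acquisition formats (ABF, Igor packed
  experiments) and NWB are not read; datasets use the package's HDF5
  container or plain-text fixture dialects.
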