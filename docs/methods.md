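# Methods

## The estimation problem

In a rhythmically active network, a neuron's synaptic input is a
periodic mixture of excitatory and inhibitory conductances. `syncond`
recovers both as functions of the cycle phase from a single intracellular
recording, using the passive current-balance equation

    C dVm/dt = g_leak (E_leak − Vm) + g_i(t) (E_i − Vm)
             + g_e(t) (E_e − Vm) + I_inj(t).

Two assumptions make the problem tractable:

1. **Quasi-static membrane.** The membrane time constant
   τm = C/g_leak (≈10 ms for a leak density of 100 pS/pF) is far shorter
   than the timescale of the synaptic drive, so dVm/dt ≈ 0 and the
   instantaneous I–V relation is a straight line. τm sets the method's
   time resolution — about 1/300 of a 3 s cycle.
2. **Phase-locked drive.** In a periodic network the synaptic
   conductances depend on time only through the cycle phase
   φ(t) = (t − t_k)/(t_{k+1} − t_k), where t_k are reference-burst
   onsets. Samples from many cycles at the same phase are therefore
   exchangeable and can be pooled.

The recording is held at hyperpolarized potentials (−100 to −60 mV) so
voltage-gated currents stay closed and the passive model applies.

## Pipeline

1. **Spike removal** — 0.1 s moving median on the measured channel;
   windows shrink at the trace ends rather than padding.
2. **Downsampling** — block averaging from the acquisition rate
   (12.5 kHz) to the 100 Hz analysis rate; block means anti-alias and
   preserve the trace mean exactly.
3. **Reference processing** — the nerve signal is rectified and
   leaky-integrated (τ = 0.05 s); burst onsets are upward crossings of
   10% of the burst amplitude above the 5th-percentile baseline, with
   amplitude refined once from per-burst peaks and crossings closer
   than half a median period suppressed. Onset times are interpolated
   between samples.
4. **Quality control** — an epoch is analyzed only if the cycle-period
   CV is below 10%, at least 3 distinct current steps are each held for
   at least 5 cycles (a cycle counts toward a step when ≥90% of it lies
   within the step's plateau), and the inter-burst baseline drifts by
   less than 1 mV/min after regressing out the step level.
5. **Phase binning and regression** — the cycle is divided into 100
   right-open bins. Per bin, ordinary least squares of the measured on
   the controlled variable (Vm on I_inj in current clamp, I on Vm in
   voltage clamp) gives total resistance R(φ) and effective resting
   potential V0(φ) with standard errors; G(φ) = 1/R(φ),
   δG = δR/R². Bins need ≥10 samples and ≥2 distinct levels.
6. **Decomposition** — with reversal potentials (E_i, E_e):
   G_i = G(E_e − V0)/(E_e − E_i), G_e = G(V0 − E_i)/(E_e − E_i).
   Dynamic components subtract each component's minimum over the valid
   bins; the sum of the two minima estimates the leak (plus any static
   synaptic) conductance. Errors propagate as
   δΔG(φ) = sqrt(δG(φ)² + δG(φ_m)²) with φ_m the minimizing bin, and a
   one-tailed z-test (ΔG/δΔG, p = 1 − Φ(z), α = 0.05, no
   multiple-testing correction; Benjamini–Hochberg available) marks
   significant bins.
7. **Wedge diagram** — the per-bin trajectory (G, I0) with
   I0 = −G·V0 is bounded above by the zero-excitation line (slope −E_i)
   and below by the zero-inhibition line (slope −E_e). The boundary fit
   enumerates contiguous phase windows of ≥5 valid bins (wrap-around
   allowed). A window is admissible when its line has R² ≥ 0.9, spans
   ≥10% of the trajectory's conductance range, constrains the slope to
   ±3 mV both as realized and as *predicted* from the per-bin I0
   errors (the predicted bound cannot be gamed by
   selected-for-luck residuals), has residuals consistent with those
   errors (rms ≤ 1.3 σ plus a small absolute floor for the membrane-lag
   curvature of noiseless data), and leaves every other point on the
   correct side of the line. The winner maximizes window length over
   the residual scale floored at the measurement error. Three simpler
   scores were tried and rejected during development: length×R² lets a
   long mediocre chord through the wedge interior beat the true
   boundary (E_i off by ~5 mV); length/rms lets a short window aligned
   with noise win on its tiny residual; plain longest-admissible drifts
   into curved edge bins. Each guard above closes one of those failure
   modes. The lower boundary is accepted only when its slope maps to
   E_e within [−30, +10] mV; otherwise E_e defaults to −10 mV.
   User-supplied reversal potentials always win over wedge estimates.
8. **Motif inference** — the cycle splits into inspiration [0, r),
   post-inspiration [r, r+w) and late expiration [r+w, 1) (r from the
   reference duty cycle unless configured; w = (1−r)/2). A window is
   labeled for a synaptic sign when ≥25% of its bins are significant
   *and* the window's peak ΔG reaches ≥10% of that component's cycle
   maximum; the source population is the phenotype activity template
   best correlated with the windowed ΔG waveform (ties within 0.05
   report all candidates, recurrent self-edges allowed). Inferred edges
   carry sign only — never transmitter identity or source location.

### Why the relative-peak floor in motif labeling

An error of a few mV in E_i leaks a scaled copy of the inhibitory
profile into the excitatory component (and vice versa). Over a 50-cycle
epoch the per-bin standard errors are small enough that this few-percent
leakage is statistically significant, so a purely significance-based
window rule would assert spurious wrong-signed connections. The 10%
relative-peak floor encodes the qualitative practice of reading only
substantial conductance components as synaptic inputs.

## Voltage-window selection

The hyperpolarized analysis window ([−100, −60] mV) is applied per
(bin, level): a current level enters a bin's fit only when its median
voltage in that bin lies inside the window. Admitting individual
samples instead would let different levels sample different sub-ranges
of the bin's phases wherever a level's voltage straddles a window edge,
which measurably biases the pooled fit.

## Simulator and synthetic data

The simulator integrates the current-balance equation with forward
Euler at the protocol sample rate (80 µs at 12.5 kHz, checked against
τm/10) for current clamp, and computes the holding current analytically
for voltage clamp. Defaults: C = 100 pF, g_leak = 10 nS (τm = 10 ms),
E_leak = −60 mV, E_i = −90 mV, E_e = −10 mV; 3 s cycles with a 0.33
inspiratory fraction; 5 current levels from −250 to −50 pA (voltage
clamp: −100 to −60 mV), each held 10 cycles. Noise is additive white
current noise scaled so its stationary voltage sd equals the requested
mV value — matching the regression's residual term without committing
to an unstated biological noise model. Spiking is an optional
threshold/reset add-on whose only role is to exercise the median
filter; the method itself assumes hyperpolarized, non-spiking operation.
The synthetic reference nerve signal is a sharp-onset, augmenting burst
envelope over the inspiratory window plus small noise, so the 10%
onset-detection latency stays below half a phase bin.

Phenotype fixtures compose the synaptic drive of the six canonical
respiratory firing phenotypes (pre-I/I, ramp-I, early-I, late-I,
post-I, aug-E) as weighted sums of the same activity templates the
motif stage matches against — one shared definition, so fixture and
inference cannot drift apart. The templates are piecewise linear in
phase with a 0.05-wide circular Hann smoothing: convergent populations
of imperfectly synchronized neurons produce kink-free envelopes, and
kinks would excite the membrane's low-pass filter in ways the
quasi-static analysis cannot represent.

The *standard recovery fixture* uses smooth half-sine components (an
expiratory inhibitory bell of 8 nS over phases 0.30–0.95 and an
inspiratory excitatory bell of 3 nS over 0.00–0.45). Its slopes keep
τm·|dg/dt| well below 1% of each peak, so the noiseless recovery error
measures the estimator rather than the membrane's filtering. The
phenotype fixtures are deliberately sharper (abrupt burst ends); their
noiseless recovery floor is ≈1.5% of peak — the τm resolution limit,
not an estimator defect.

### What the generator does not emulate

Real recordings add electrode series-resistance artifacts, h-current
and other subthreshold nonlinearities, slow drift in cell properties,
synaptic shot noise, and space-clamp attenuation of the measured
reversal potentials. Passing recovery tests on the simulator therefore
demonstrates correctness of the estimator under the model's own
assumptions, not robustness to every biological confound; the epoch
comparison and reversal-sensitivity scans probe the latter only
partially.

## Numerical choices and degenerate inputs

- Canonical units mV / pA / s / nS / MΩ, converted in one place
  (1 mV/pA = 1 GΩ; 1 pA/mV = 1 nS; nS·mV = pA).
- Rank-deficient bins (one current level), thin bins (<10 samples) and
  non-positive fitted resistances invalidate the bin (NaN + flag);
  invalid bins propagate as flagged missing values and are never
  interpolated into statistics.
- Negative G_i or G_e (V0 outside [E_i, E_e]) are flagged, not clipped:
  they are the signature of mis-specified reversal potentials.
- Ties in minimizing bins break to the first bin index; pipeline runs
  are deterministic given (recording, configuration).
- Samples within 50 ms (≈5 τm) after a step change are excluded.
- δG = δR/R² overestimates the per-component errors (the total is the
  sum of both), which makes the z-test conservative. The minimizing
  phase φ_m is taken from the data; under very low dynamic range the
  empirical-minimum selection biases ΔG slightly upward, so the
  calibration property is checked with independent reference draws.

## Known limitations

- Static synaptic conductance is inseparable from leak; the "leak"
  estimate is their sum.
- The wedge E_e estimate needs a genuinely inhibition-free phase range;
  most profiles default to E_e = −10 mV.
- Phase resolution is bounded by τm; features faster than ~1/300 of the
  cycle are attenuated and slightly lagged.
- No correction for electrotonic attenuation of reversal potentials is
  attempted.
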