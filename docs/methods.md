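# Methods

## The measurement being modeled

A dual-gate drift-tube ion mobility spectrometer can be operated as a
Fourier-transform instrument: both Bradbury–Nielsen gates are driven by the
same 50%-duty square wave, and the gate frequency is programmed through a
range.  An ion swarm of drift time `td` passes the exit gate only to the
extent that the gate state at arrival matches the state at injection, so the
time-averaged transmission is the overlap of two square waves delayed by
`td` — a triangular function of the phase `phi = frac(f * td)`:

```
g(f, td) = duty - min(phi, 1 - phi)        clipped at 0,  duty = 0.5
```

Recording the averaged detector current at each frequency yields an
interferogram in which each ion contributes a triangle wave of frequency
"period" `1/td`; an FFT over the frequency axis returns a drift-time
spectrum.  Compared with the classical pulsed single-gate (SG) experiment
(duty 0.1–0.5%), FT mode runs at 50% duty, which is where its
signal-to-noise advantage originates.

The package implements the *asynchronous stepped* variant: the frequency
grid is stepped (not chirped), each step dwells a fixed time, and the data
window at each step is software-timed — started a nominal 0.5 ms after the
frequency change, with no hardware synchronization between gate phase and
acquisition.  The transimpedance amplifier is modeled as a single-pole
low-pass with `tau = rise_time / ln 9` (the exact first-order 10–90%
relation).  With the FT-mode rise time of 100 ms — tens to hundreds of gate
periods — the amplifier output is a steady DC level with sub-percent ripple,
so the placement of the averaging window is irrelevant.  That claim is not
assumed: `simulate.time_domain_record` builds the explicit gate trains,
convolves them with each ion's Gaussian arrival distribution, chops the
result with the exit gate, filters and samples it; the test suite checks
that windowed means match the analytic steady state within 1–2% and that
sliding the window across a full gate period moves the mean by < 1%.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| `f_min, f_step, f_max` | Hz | 10, 5, 4000 | the optimized stepped protocol; resolution is set by the span `f_max − f_min`, duration by the step count |
| `n_avg` | – | 1–4 | dwell per step = `n_avg / f_min` (time-based averaging keyed to the slowest frequency, constant across steps) |
| `trigger_offset` | s | 0.0005 | data-window start after a frequency change; applies to the window only, never to gate phase |
| amplifier `rise_time` | ms | 100 (FT), 0.1 (SG) | sets `tau = rise_time / ln 9`; FT-mode asynchrony is valid once `tau` spans ≳ 10 gate periods |
| ion `sigma` | ms | 0.15 | intrinsic arrival-time spread; 0.1–0.2 ms reproduces the resolving powers (≈ 40–90) typical of this instrument class |
| cell constant `C = td·K0` | ms·cm²V⁻¹s⁻¹ | 43.137 | fitted as the mean SG `td·K0` product over the four tetraalkylammonium calibration salts in the bundled benchmark; geometry mode (`L, E, T, P`) is available when the cell is known |
| `window_name` | – | rectangular | magnitude spectrum of the raw FFT; Hann available (see below) |
| `zero_pad_factor` | – | 8 | keeps measured FWHMs free of bin quantization |
| noise `white_rms` | signal units | 0 | per-raw-sample white SD; interferogram points receive `white_rms / sqrt(dwell · 1000 Hz)` — the dwell-averaging gain at a fixed nominal 1 kHz equivalent bandwidth |

## Reconstruction choices

The interferogram is mean-subtracted (each ion carries a DC term ≈ duty²
per unit abundance), apodized, zero-padded and magnitude-FFT'd.  The axis
mapping uses the grid spacing only: bin `k` sits at `td = k/(N_fft·f_step)`
and the largest representable drift time is `1/(2·f_step)`; frequencies
below `f_min` are treated as absent, with no extrapolation toward 0 Hz.
Magnitude (not real part) is reported because the phase is arbitrary under
asynchronous triggering.

Because the gate correlation is triangular, every true peak has odd-harmonic
companions at `3·td, 5·td, …` with `1/k²` amplitudes (1/9, 1/25).
`reconstruct.flag_harmonics` annotates fitted peaks matching that pattern
(odd multiple within one bin, height < 20% of the parent).

**Rectangular vs Hann.**  The rectangular default matches raw-FFT
presentation and gives the narrowest main lobe, and all transform-limited
resolution results use it.  For *multi-component center accuracy*, however,
apodization matters: real ions' Gaussian arrival spread damps the
interferogram toward high frequency, leaving the effective window maximal at
the low-frequency band edge; that sharp edge throws `1/Δtd` skirts across
the axis, and neighbouring peaks can pull each other's centers by more than
a bin.  With the Hann window the recovery error for random 1–4 ion mixtures
drops to ~0.03 bins.  The package therefore reports mixture-recovery
properties under Hann and recommends it whenever drift-time accuracy, rather
than the narrowest possible peak, is the goal.

## Peak fitting and figures of merit

Peaks are local maxima with prominence above `min_prominence` times the
global maximum (default 0.2; ties resolve leftmost-first via the drift-time
sort).  Each is refined by a Gaussian fit over ± 2 preliminary half-widths,
which supplies center and height; the reported `w_half` is instead measured
directly from linearly interpolated half-maximum crossings, so it remains
correct for window-transform line shapes a Gaussian only approximates.
Resolving power is `Rp = td / w_half`.  RMS noise is the population RMS
`sqrt(Σ(H_i − H̄)²/n)` (a `ddof=1` sample variant is available), taken over
a region that must clear every fitted peak by 3 half-widths; the default
region is the final 20% of the axis, shifted left in whole region-lengths if
a peak lives there.  `S/N = height / mu_RMS`; a noiseless spectrum reports
`inf`.  Summary percent increases in SG-vs-FT comparison reports use the
ratio of column means (the mean of row-wise ratios is a different statistic
and is deliberately not used); the paired t statistic over per-compound
deltas is reported descriptively.

## What the synthetic data does and does not emulate

The generator reproduces: the triangular gate correlation and its Gaussian
arrival-time averaging, time-based dwell averaging and its noise gain,
per-step white noise with deterministic per-step substreams, the single-pole
amplifier, the finite SG gate-pulse broadening (added in quadrature as
`pulse_width/2.355`), and quasi-static linear chirps.

It does **not** model space charge, gate depletion or field penetration —
the ~95% signal loss real instruments show toward 8 kHz has no counterpart
here, so simulated high-frequency studies overstate achievable signal.
Ion chemistry (clustering, transient "bridging" species) is outside the
model; consequently instrument-measured resolving powers and S/N magnitudes
for real compounds are *not* reproduced — only the protocol arithmetic,
comparison statistics and scaling laws, which is what the tests assert.
Samples within a dwell are combined by the mean (not the sum); per-device
ADC rates are abstracted into the fixed 1 kHz noise-equivalent bandwidth.

## Numerical choices and degenerate inputs

- Gaussian-averaged gate correlation: numerical quadrature of the exact
  triangle against N(td, σ²) on a ±8σ, 1601-point grid (σ = 0 short-circuits
  to the closed form).  Quadrature error is far below the 1–2% simulation
  tolerances.
- Time-domain records pad the gate train by `max(td) + 6σ + 7τ` before t = 0
  so convolution edges and the filter transient never reach the data window;
  fractional drift-time delays use two-tap linear interpolation.
- Transform-limited FWHM constants: rectangular `1.20671/B` (|sinc| half
  point at πBt = 1.89549), Hann `2/B` exactly, with `B = f_max − f_min`.
- Stepped grids stop at the largest grid frequency ≤ `f_max` (never rounded
  up) so the FFT axis stays uniform; step-count arithmetic uses a 1e-9
  relative guard against float droop.
- `switch_overhead` defaults to 0: reported wall-clock times of real runs
  imply per-step software overhead that varies by DAQ hardware, so durations
  are exact dwell sums unless the user supplies an overhead.
- Degenerate inputs: an empty ion list is valid everywhere (baseline/noise
  only); zero-width flanks that never cross half maximum fall back to a
  bin-width estimate; single-step plans are legal but reconstruction needs
  at least two frequency points.

## Problem sizes used in the test suite

Simulated studies use 399–2000 frequency steps, 8–50 time-domain records of
≤ 25 k samples, 100-trial recovery sweeps at 799 steps, and triplicate study
replicates — sizes chosen so every scaling law is measured over at least a
factor of 4 in its controlling variable while the whole suite stays
interactive.
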