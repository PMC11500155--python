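# Methods

This note documents the models behind `conepulse`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
does and does not emulate.

## Spray model

The generator treats the spray as a continuous-time emission process
sampled onto a fine uniform grid (step 4 µs; the step divides the 20 µs
oscilloscope interval, both frame periods — 200 µs at 5 kfps online,
20 µs at 50 kfps offline — the 0.8 ms dwell and the 4 ms event, so every
downstream resampling is exact index arithmetic, never interpolation).

Voltage map (`make_preset`):

| voltage (kV) | mode | notes |
|---|---|---|
| < 2.22 | no_spray | onset voltage; zero flux, no cone |
| 2.22 – 3.0 | burst | Poisson bursts, 20 s⁻¹, 2 ms long, 50 % amplitude jitter |
| 3.0 – 5.0 | pulsating | frequency from the voltage table below; line offset interpolated 50→30 px |
| > 5.0 | cone_jet | persistent cone, constant flux |

Voltage→frequency table (kHz, linearly interpolated, configurable):
3.0 → 1.6, 3.5 → 2.0, 4.0 → 1.92, 4.5 → 1.95, 5.0 → 2.0.  Only the 4.0 kV
value is pinned by measurement; the 3.5→4.0 drop encodes the slow-down as
the spray approaches the cone-jet transition.

Pulsating mode draws, independently per cycle:

* cone duty *d_k* ~ N(0.5, 0.2²), clipped to [0.02, 0.98].  Per-cycle duty
  variability is what couples occupancy to emitted charge; 0.2 reflects a
  near-transition pulsating spray whose cone lifetime varies visibly from
  cycle to cycle while remaining periodic.
* burst amplitude *A_k* lognormal with mean `emission_amplitude` (default
  1000 flux units) and CV 0.25 — droplet bursts of similar but not equal
  size.

Flux is *A_k* while the cone is present and zero otherwise; the cone-state
invariant (flux only when the cone exists) is enforced by the container.
No slow drift terms are included: the offline traces this emulates are
stationary over the 1–30 s windows analyzed, and a slow *duty* drift would
survive the carryover filter and manufacture correlation the real
experiment does not show.

## Rendering and detection

Frames are 8-bit shadowgraphs (bright 255 background, dark 0 silhouette;
origin top-left, x along the spray axis, 0-based).  The emitter is a
40-px-thick bar ending at the tip anchor (default x = 100, y = center);
when the cone is present a triangle with apex half-angle 49.3° (Taylor's
angle) extends 12 px past the reference line, darkening ~27 line pixels.
Pixel noise is additive Gaussian (default sd 5 of 255), clipped.

Stacks are rendered lazily — a 30 s online stack is 150 000 × 256 × 256
uint8 ≈ 9.8 GB and is never materialized.  Indexing renders single frames
(per-frame RNG streams keyed by `(seed, frame)`), and a vectorized
accessor serves just the reference-line column to the detector; the column
path draws from its own seeded stream, so both paths are reproducible per
seed though their noise realizations differ.

Detection thresholds default to mid-gray (128) for "black" and 10 of 120
line pixels for presence; both are mandatory, logged configuration.  With
a noiseless margin of 128 gray levels and noise sd ≤ 10, misclassification
requires a >12 σ excursion, which is why round-trip accuracy is exact
without noise and ≥ 99 % with it.  The tip anchor is an input;
`propose_tip` suggests one from the silhouette but is never applied
implicitly.

## MS signal chain

`ChainParams` defaults: transit delay 1 ms (droplet travel to the gate
region), carryover time constant τ = 5 ms (a single causal exponential —
the simplest mixing-volume model of ion retention in the atmospheric
interface and ion guides; 5 ms makes the blending span more than one
acquisition event), dwell 0.8 ms of each 4 ms event (the instrument's
smallest settings), detector gain 2500 counts per flux·s and detector
noise sd 500 counts.  With the default emission amplitude the mean
pulsating-mode event intensity is ≈ 1000 counts, so the noise floor is
50 % of signal — matching the broad scatter and sporadic high peaks that
SIM traces of a pulsating source show.  Dwell is placed at the start of
each event; the instrument's internal event phase is unpublished.
Intensities are clipped at zero after noise.

The discrete carryover kernel (1−α)αʲ with α = exp(−dt/τ) sums exactly to
one, so gate plus mixing conserve flux up to the truncated tail; a guard
rejects grids coarser than τ/5.

`sample_continuous_events` is the idealized sampler used for mechanism
attribution: full-event integration, no detector noise, and an event grid
phase-shifted by the known transit delay.  The phase shift matters:
nearest-event matching on a 4 ms grid cannot compensate a 1 ms delay, and
the idealized sampler exists precisely to remove chain artifacts — grid
phase included.

## Correlation analysis

Occupancy bins are 20 frames (4 ms at 5 kfps, one MS event), stamped with
the first frame's time; the trailing partial bin is dropped.  Spearman's ρ
is computed from explicit average ranks (Pearson on ranks), so tie
handling is visible; a constant series yields NaN — flagged missing, never
coerced to zero, so zero-signal voltages cannot fabricate correlations.
The shift scan (default −2…+10 ms, 0.2 ms steps, covering droplet transit
plus instrument lag) matches each bin to the nearest MS event at
`bin_time + shift`; with both series on 4 ms grids the pairing — and hence
ρ — changes only when the shift crosses a half-event boundary, so ρ is
blockwise constant in shift.  Shift-localization claims are therefore
asserted at half-event (2 ms) resolution.

## RTC simulation

The control loop is modeled as: stream frames, classify each with the
single-frame detector, and on the first frame satisfying the condition
open the gate after `loop_latency + jitter + set_delay` for 1 ms.  Latency
defaults to 0.44 ms with Gaussian jitter (sd 0.02 ms, truncated at zero —
a no-op in practice since latency ≫ jitter).  The run's single intensity
is the maximum SIM event intensity over the run window, mirroring the
one-signal-per-run readout of an acquisition stopped at gate closure.
Calibration regresses elapsed time on set delay (OLS); with zero jitter
the fit is exact and R² is reported as exactly 1.  The positive/negative
comparison adds a two-sided 95 % bootstrap interval for the mean
difference — overlapping error bars become a testable statement.
Timeout defaults to 5 s of frames.

## Spectra

Spectra are one-sided magnitudes of the mean-subtracted, Hann-windowed
trace (window choice moves peak heights, not isolated peak locations).
Peaks are searched above 100 Hz to exclude DC and drift; no sub-bin
interpolation by default (quadratic refinement is available) since the
estimates are quoted at ~10 Hz precision anyway.  An undersampling
warning fires when the sampling rate is below twice a declared expected
frequency, or when the peak lands within one bin of Nyquist — the reason
the 5 kfps online channel is binned rather than Fourier-analyzed, while
the 50 kfps offline channel supports clean 1.92 kHz estimates.

## Problem sizes and determinism

The shipped analyses use 30 s runs (150 000 frames, 7500 events) for
correlation studies, 1 s at 50 kfps (50 000 frames) for spectra, and
replicate counts of 9 (correlation) / 5–20 (RTC) — the sizes at which the
estimates are stable to well within the asserted margins.  All randomness
flows through `numpy.random.default_rng` seeded via `SeedSequence`
hierarchies; identical seeds give identical outputs per access path, and
every CLI run writes its resolved config and seed next to its outputs.

## What the synthetic data does not emulate

* Electrohydrodynamics: cone shape dynamics, jet break-up, droplet size
  distributions and their field dependence are out of scope; the cone is
  a binary geometric primitive.
* The instrument's internal optics: ring-electrode focusing is treated as
  unit transmission, and the carryover kernel is a one-parameter stand-in
  for a cascade of mixing stages.
* Slow drifts (flow-rate, temperature, fouling) and frequency wander of
  the pulsation; traces are stationary by design.
* Absolute intensities: gain and noise are arbitrary-unit choices, so
  only relative/statistical statements (correlations, frequencies,
  indistinguishability) transfer to real data.  Passing tests show the
  analysis machinery and the proposed chain mechanism are coherent — not
  that a particular instrument's constants are correct.
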