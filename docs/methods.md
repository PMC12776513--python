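# Methods

Models, estimator details and parameter defaults, in analysis order. All
times are seconds, lengths µm, speeds mm/s, pO2 mmHg; windows are half-open
[t0, t1); frames are 0-based. Default acquisition geometry: 1 kHz line rate
(instrument range 0.8–1.3 kHz), 3.8 Hz frame rate, 0.994 µm pixels.

## Vessel diametry

**FWHM.** The background level of a transverse profile is the mode of its
lower quartile (robust against RBC shadows); half-max is midway between
background and peak, and both crossings are located with linear sub-pixel
interpolation. Flat profiles or edge-touching lobes raise
`VesselNotFoundError`.

**Projection diametry (vessel in plane).** The dominant axis is estimated
once on the time-averaged image by searching the rotation that maximizes the
variance of the column-averaged profile (coarse 5°, fine 0.5°; isotropic
images are rejected). Every frame is rotated to horizontal and the FWHM of
the averaged transverse profile is reported per frame.

**TiRS (vessel cross-section).** The frame is Radon-transformed over 0–179°;
each angle's projection is binarized at 0.5 of its own maximum; the binary
sinogram is back-projected *without* a filter, thresholded at 2/3 of the
reconstruction maximum, and the equivalent-area diameter 2·√(A/π) is
reported. The 2/3 value is exact for an ideal disk: half-max binarization
keeps the chord |s| < (√3/2)·r, whose plain backprojection at radius ρ equals
(2/π)·asin(w/ρ) of the center value and crosses 2/3 precisely at ρ = r. A
filtered backprojection with the commonly used empirical 0.2 threshold left a
−2 px bias on our rendered disks at 20–26 px, violating the 1-px FWHM/TiRS
agreement requirement, which motivated the unfiltered closed-form variant.
Multiple comparably sized blobs (second ≥ 25% of largest) raise
`AmbiguousVesselError`.

**Stimulus-locked metrics.** Baseline is the mean diameter over the 5 s
before stimulus onset; peak dilation is the maximum percent change during
stimulation; latency is the interpolated time to half of the maximum
dilation. For 30 s stimulation the first peak (max, 1–4 s post onset) and
shallow peak (mean, 20–30 s) are reported additionally. Segment onset order
ranks latencies; exact ties break capillary-first and set a tie flag.

## RBC flow

**Radon velocimetry.** Windows of 0.04 s (step = half window) are searched
for the streak angle of maximal projection variance (coarse 1°, fine 0.02°,
angle measured from the time axis); displacement per line is u = tan θ and
speed = u · pixel_size · line_rate / 1000 (signed; vertical streaks → 0).
Windows whose best-angle variance is below 2.5× the median over all angles
are isotropic and yield NaN; the 2.5 cut was calibrated against the measured
regimes (pure-noise windows stay below ~2.0, the faintest genuine streak
windows exceed ~4.4 across 0.1–10 mm/s).

**Flux.** The kymograph is cut into consecutive 500-line frames; the middle
column is binarized at the Otsu threshold and connected sub-threshold runs of
≥ 2 lines are counted as RBC passages. Summary statistics use every other
frame, mirroring manual counting practice. Uniform frames count 0; frames
with > 90% sub-threshold pixels raise `DegenerateContrastError`. Flux
heterogeneity across capillaries reports sample STD (ddof = 1) and CV.

**Stalls.** A segment stalls when its windowed |speed| stays below
0.05 mm/s for at least 1 s (both explicit parameters). NaN windows carry no
motion evidence and are not scored as stalled. The stall fraction counts
segments with ≥ 1 stall over all segments.

## Calcium ensembles

**ΔF/F.** F0 at frame i is the mean of the lowest 25% of samples in a 15 s
window centered on i (truncated at the edges).

**Event detection.** Traces are zero-phase low-pass filtered (4th-order
Butterworth, 0.5 Hz). Baseline mean/SD come from iterative 3-SD clipping of
the *raw* ΔF/F: thresholding the smoothed trace at 2 SD of the raw
sub-threshold residuals keeps the false-positive rate on pure-noise traces
at ~0.03% of frames (a filtered-trace SD gave ~2.3%). On noiseless traces
(clipped raw SD exactly 0) the filtered-trace SD is used with a floor of 5%
of the filtered dynamic range, because zero-phase filter pre-ringing (~3% of
a transient) would otherwise masquerade as baseline noise. Events switch on
above baseline + 2 SD, off below baseline + 0.5 SD, and the activation time
backdates along the run of frames whose derivative exceeds 0.5 SD of its own
clipped baseline.

**Ensemble threshold.** Each of 1,000 surrogates circularly shifts every
cell's binary activity by an independent uniform lag; the chance level is the
99.9th percentile of the pooled surrogate co-activity, expressed as percent
of cells. Contiguous supra-threshold runs of the measured ensemble trace are
significant events. Under an independent-cell null with p = 0.1 and 50 cells
the threshold sits at the binomial 99.9% tail (13 cells = 26%), giving
empirical coverage ≈ 99.94%.

**Connectivity and behavior.** Pairwise Pearson correlations (≥ 2 cells,
≥ 30 frames; zero-variance cells excluded and flagged); behavior summaries
average ensemble activity within the five states (rest, whisk, whisk+motion,
puff, puff+motion).

## Neurovascular coupling

A significant ensemble event is *paired* when the diameter rises ≥ 2% above
its local 5 s pre-event baseline within 4 s of event onset (window and
criterion are explicit parameters; the underlying experiments do not pin them
down). The NVC index is dilation % / ensemble %. The group comparison fits
OLS `dilation ~ ensemble * C(group)` (statsmodels); the interaction
coefficient is the slope difference, and the non-reference slope CI uses the
linear-contrast SE from the coefficient covariance.

## Oximetry

**Decay fitting.** Single-exponential A·exp(−t/τ) + b by bounded nonlinear
least squares over the 290 µs collection window (1 µs bins), initialized
from a log-linear fit of the background-subtracted histogram. Degenerate
histograms (flat, empty, < 10 bins) raise `DecayFitError`.

**Stern–Volmer.** 1/τ = 1/τ0 + kq·pO2. Probe constants are instrument- and
batch-specific in practice, so τ0 = 40 µs and
kq = 3.65·10⁻⁴ (µs·mmHg)⁻¹ are engineering defaults chosen to span lifetimes
of ~12–40 µs over 0–160 mmHg; `calibrate()` fits both constants from
(τ, pO2) pairs, and all conversions accept a custom `OxyCalibration`.
Lifetimes above τ0 clip to pO2 = 0 with a warning.

**Saturation and extraction.** Hill SO2 = pO2ʰ/(pO2ʰ + P50ʰ) with h = 2.59
and P50 = 40.2 mmHg; OEF = (SO2_A − SO2_V)/SO2_A. The hypoxic threshold is
strictly below 18 mmHg.

**Distance classes.** Euclidean distance transforms of the arteriole and
venule masks define near-arteriole / near-venule classes within 50 µm
(nearer vessel wins; exact ties go to near-arteriole and are flagged) and
in-between beyond.

**Schedules.** The intravascular protocol (7 ROIs × 100 cycles, 140 repeats,
pairwise averaging) yields 70 time points per ROI; the 32 × 32 tissue grid
yields 1,024 ROIs. Respirometry reports RCR = state3/state2 and ADP:O (O in
nmol of oxygen atoms).

## NADH metabolism

The artifact coefficient β is fit by least squares of NADH on SR101 over the
pre-stimulus baseline, where the metabolic component is flat and the shared
hemodynamic artifact dominates; the corrected trace is NADH − β·SR101,
re-zeroed on the baseline (a ratiometric variant divides linearized
fluorescence ratios). β is estimated rather than fixed at 1 because channel
gains differ. Dip = minimum in the 5 s after onset − baseline; overshoot =
mean over [onset+20 s, onset+40 s] − baseline (window configurable). Both are
baseline deltas and therefore invariant to constant offsets.

## Synthetic scenes

All generators draw from per-stream `SeedSequence((seed, stream))`
generators, so scenes are reproducible and mutually independent.

- **Kymographs.** RBC arrivals are a renewal process with a physical dead
  time (minimum headway 1.6 cell widths) at the requested mean rate — pure
  Poisson arrivals merge overlapping streaks into single valleys and bias
  flux counting ~10% low at 15–20 RBC/s. Cells are ~6 µm Gaussian shadows
  (contrast 0.6) on a bright plasma background. During stalls the motion
  clock freezes and a stuck mid-segment cell is guaranteed (a stall *is* a
  stuck cell; otherwise the segment simply empties and the stall is
  invisible).
- **Vessel movies.** Bands (in-plane, optional rotation) or disks
  (cross-section) with error-function edges and a time-varying diameter.
- **Segment scenes.** Six segment classes with capillary-first latencies
  (1st-order capillary → sphincter → penetrating → pial); a tau-like variant
  scales all amplitudes ×0.5 and delays all latencies +0.6 s.
- **Calcium populations.** Independent per-cell Poisson spikes plus shared
  latent events joined with probability `loading` (rate multiplied during
  air-puff epochs), convolved with a difference-of-exponentials kernel
  (0.1 s rise, 0.8 s decay).
- **Decays.** Poisson photon counts over 290 µs with configurable
  photons/cycle and cycle counts; `photons_per_cycle=inf` returns the
  noiseless expectation.
- **Tissue maps.** pO2 decays exponentially with distance to the nearest
  arteriole (scale 60 µm), re-centered so the map mean equals a per-animal
  draw N(group mean, SD).
- **NADH pairs.** SR101 carries the hemodynamic artifact (stimulus transient
  plus 0.5% vasomotion at 0.1 Hz, which keeps β identifiable from ~16
  baseline frames at 1.087 Hz); NADH adds the metabolic dip/overshoot plus
  `artifact_gain` times the same artifact.
- **Coupled scenes.** Ensemble events at regular intervals; each paired
  event adds a *causal* gamma-shaped dilation (zero before onset, peak at
  onset + 1 s) with amplitude = coupling gain × event magnitude. An earlier
  Gaussian transient leaked ~19% of its amplitude into the pre-event
  baseline and biased the NVC index ~20% low.

## Pipeline and problem sizes

`run_pipeline` spawns one seed per stage from the root seed (all derived
seeds < 2³¹), simulates and analyzes every scene, and writes `report.json`,
`config.yaml` and per-segment tables; bundles are byte-identical for
identical seeds. Default scene sizes (10 s kymographs, 300 s calcium at 30
cells, 1,000 shuffles, 200 decay cycles) are package choices that complete a
full run in ~4.5 min on one CPU; the acceptance determinism test uses a
reduced, structure-preserving configuration to stay within test budgets.

## Numerical notes

- Radon transforms use scikit-image (`radon`/`iradon`); filtering uses
  SciPy `butter`+`filtfilt` (zero phase); OLS uses statsmodels; distance
  transforms use SciPy ndimage.
- ΔF/F is vectorized with sliding windows and partial sorts; the surrogate
  co-activity pool scatters active-frame indices with `bincount` over the
  flattened (shuffle × frame) axis, keeping 1,000 shuffles of a
  50 × 2,000 matrix at ~0.5 s.
- The velocimetry two-stage angle search (1° coarse, 0.02° fine) keeps the
  worst-case speed error < 4% over 0.1–10 mm/s on noiseless scenes, within
  the 5% oracle-agreement requirement.
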