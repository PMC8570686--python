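# Methods

## Evoked-potential model and feature definitions

A dentate-gyrus evoked potential is modelled as a positive-going field
EPSP with superimposed negative population spikes. The synthetic
generator uses an alpha function for the fEPSP,
`A · (t/τ) · exp(1 − t/τ)` starting one synaptic delay (1.5 ms) after
the stimulus, and Gaussian notches for the spikes; both are scaled by a
logistic function of stimulation intensity (the input/output relation).
These shapes were chosen because they are smooth, differentiable and
have analytically known landmarks, so every downstream feature has a
closed-form ground truth; they are not biophysical models of granule
cell currents. A biphasic saturating square deflection (±8 mV, 0.4 ms)
at stimulus onset stands in for the stimulus artifact so that
artifact-blanking logic is genuinely exercised.

Feature definitions:

* **fEPSP slope** — OLS fit to the raw samples between the first
  crossings of 20% and 80% of the peak amplitude of the post-stimulus
  rise (`rise_lo`/`rise_hi`, configurable). The window is delimited on
  a lightly smoothed copy of the trace (0.5-ms boxcar): a raw noisy
  trace crosses any amplitude level many times, and window bounds tied
  to local extrema turned out to bias small (suppressed) responses
  downward, so the bounds depend only on level crossings toward the
  window's global maximum. The fit itself always runs on raw samples;
  for noiseless input the estimate is exact for linear ramps and
  invariant to DC offsets and to uniform amplitude scaling.
* **PS area** — for every detected trough, the tangent is the straight
  line joining the flanking positive-peak samples and the event area is
  the trapezoidal integral of `max(tangent − V, 0)` between them, in
  mV·ms; multiple spikes are summed. The "coastline" of the spike is
  taken to be the waveform trace itself (the alternative, a cumulative
  path length, has mixed units and is not an area). The integrand is
  clipped at zero so areas are non-negative by construction.
* **Landmarks** — peak/trough search uses local extrema with a minimum
  prominence (0.1 mV default) inside a 2–15 ms post-stimulus window on
  the smoothed copy; the fEPSP peak is the first qualifying positive
  maximum (the rise to it is the uncontaminated rising phase), the
  onset the first sample above 5% of peak amplitude after 1 ms of
  artifact blanking. Both the prominence and the onset threshold are
  raised to 6× and 4× the pre-stimulus noise SD respectively when the
  trace is noisy; without this, white noise at 20 kHz fabricates
  spurious spikes on small responses. Noiseless behaviour is unchanged
  (the floors are then 0).

## Session aggregation

Input/output curves are arithmetic means and SDs over repetitions per
(intensity, pulse). The reference intensity is the grid intensity whose
baseline conditioning-pulse PS area is closest to 75% of the maximal
repetition-mean area — closest match, not interpolation, because the
protocol evaluates responses only at tested grid intensities; ties go
to the lower intensity. "Maximal response" means the maximum of
repetition means, not the largest single sweep, which is far less noise
sensitive. The two post-clozapine sessions are averaged into one
clozapine estimate (configurable to use either alone); the PS/slope
ratio is formed from session means before division, so single sweeps
with near-zero slope cannot blow up the ratio. Zero baselines flag the
affected metric as undefined (NaN) instead of aborting the animal.

## Multiunit chain

Band-pass: 3rd-order Butterworth 500–5000 Hz applied forward–backward
(zero phase), so spike troughs are not displaced; the squared response
gives ≥ 40 dB attenuation at 100 Hz. Threshold: −6.5 × the median
absolute deviation, computed per channel because noise varies with
electrode depth (for Gaussian noise MAD ≈ 0.6745 σ, so the threshold
sits near −4.4 σ). Detection: each downward crossing is stamped at the
local minimum within 1 ms and a 1-ms lockout suppresses re-triggers.
Rates: 60-s bins from t = 0, trailing partial bin dropped; every bin
entirely before the clozapine injection (baseline and vehicle epochs
pooled) forms the baseline; the bin containing the event belongs to
neither epoch. Spike sorting is deliberately out of scope — externally
sorted unit tables run through the same binning
(`rates_from_unit_table`).

## Morphometry

Volume uses the slab estimator Σ (area − damaged area) × spacing over
eight slices 0.6 mm apart, without inter-slice interpolation; hyper-
and hypointense regions enter as "damaged" and are excluded. Manual
delineation is an input contract (areas or binary masks), not an
algorithm of this package. Staining intensities are arbitrary units
with no cross-exposure correction. Transduction is scored 0–5 for
granule cell layer and hilus; a total of 0 excludes the animal from
the electrophysiological analysis only — morphometry still runs.

## Statistics

`paired_t` and the exact Wilcoxon signed-rank are implemented directly
(the signed-rank null distribution by dynamic programming over doubled
mid-ranks, exact up to n = 25, normal approximation with tie and
continuity corrections beyond; zero differences dropped). Holm's
step-down adjustment is `adj_(i) = max_{j≤i} (m−j+1)p_(j)` capped at 1.
Which p-values form an adjustment family is an explicit choice
(`per_metric` across groups by default, or `global`). Omnibus and
assumption checks (Kruskal–Wallis, Levene, Shapiro–Wilk, one-way ANOVA)
delegate to scipy. Dispersion is mean ± SD for t-based contrasts and
median + IQR for rank-based ones.

## Synthetic study conditions and their limits

Defaults (chosen once as realistic for in-vivo DG recordings): 3 mV
fEPSP (τ = 2 ms), one 4 mV PS at 4.5 ms (0.8 ms FWHM), logistic I/O
with midpoint 300 µA and slope 0.01/µA over the grid
{25…1000} µA, paired-pulse factor 0.6 at the 10-ms interval, 0.1 mV
trace noise, 20 kHz sampling, 5 repetitions. The high-expression regime
scales fEPSP and PS amplitudes by 0.2; the low-expression regime adds
one population spike (2.5 ms after the last, 0.6× its amplitude),
scales PS by 1.3 and raises the paired-pulse factor by 0.25. Broadband
recordings: 8 channels at 30 kHz, dorsal rates 50–20 Hz and ventral
8–10 Hz, post-injection factors 0.2 dorsally and 1.5 ventrally, a
−100 µV biphasic template in 10 µV noise. Morphometry: 8.5 mm² slices
(≈ 41 mm³ per hippocampus); the high-expression injected side carries
3.2 mm²/slice of damage (≈ −15.4 mm³ deficit).

The generator emulates waveform composition, Poisson firing with a step
rate change, and area bookkeeping — not electrode drift, bursting or
refractory structure, spike-waveform overlap across channels,
non-stationary noise, or imaging segmentation error. Passing tests
therefore demonstrate correctness of the measurement chain under known
ground truth, not robustness to every pathology of real recordings.

Problem sizes are desk-scale by design: unit-recording simulations use
60–300 s at 1–8 channels, and end-to-end recovery uses 20 replicates of
the full 4-session × 9-intensity × 5-repetition × 2-pulse grid.

## Numerical and design choices

* Sweep determinism: every trace is a pure function of (parameters,
  session, intensity, pulse, repetition, seed) via seed-sequence
  spawning, so datasets are bit-reproducible.
* Broadband files are int16 at 0.195 µV/bit (the ±6.4 mV, 16-bit
  front-end convention), channel-interleaved little-endian with a JSON
  sidecar.
* The 75% rule is applied to the conditioning pulse (EPa): the
  conditioning response defines the I/O curve; the test pulse is a
  read-out of inhibition.
* Tie-breaks: earliest extremum for equal peaks, lower intensity for
  equidistant reference candidates, stable sorts everywhere.
* Degenerate inputs raise named errors (`DegenerateSignal`,
  `DegenerateDifferences`, `TooShort`, …) rather than producing
  numbers; zero-baseline ratios flag NaN.

## Known limitations

* PS-area tangents anchor on peak apexes; if a flanking peak is missing
  (monotone trace beyond the trough) the maximal sample on that side is
  used, which slightly inflates areas near the analysis-window edge.
* The normal-approximation Wilcoxon branch (n > 25) is asymptotic, as
  in standard practice.
* Expression-score generation in the study simulator is categorical
  per group; it does not model graded transduction variability.
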