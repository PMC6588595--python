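# Methods

This note documents the models, estimators and numerical conventions behind
`scnburst`: what each stage computes, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the design choices
made where more than one reasonable convention exists.

## Time and phase conventions

All timestamps are seconds from recording start.  Circadian phase is
expressed in hours or in circadian time (CT), with **CT12 anchored to the
PER2 peak** (`rhythms.to_ct`): `CT(t) = (12 + 24·(t − t_PER2peak)/(3600·τ)) mod 24`.
In the synthetic presets, generator time 0 is CT0, the multiunit firing-rate
peak sits at CT8 (the phase of highest activity in cultured SCN slices), and
the PER2 peak at CT12.  Image stacks use row 0 = dorsal, so a
dorsal-to-ventral line scan runs down the rows.

## Burst definition and spike-train statistics

The operational burst criterion is a multiunit firing rate **above 35 Hz in
a 100-ms bin**.  Bins are left-closed/right-open from time zero; a partial
trailing bin is dropped so a 10-min record in 100-ms bins is exactly 6000
bins.  Spike times intended to fall exactly on a bin edge are kept in the
later bin by adding a 10⁻⁶-bin epsilon before flooring — float
representation of, say, 120.1 s would otherwise leak such spikes into the
earlier bin.

* `bin_ratio_distribution` pools 100-ms bins over SCN electrodes within a
  window (default 10 min at the activity peak) and reports the histogram as
  % of total bins plus the fraction strictly above 35 Hz.
* `BurstDetector` takes maximal runs of supra-threshold bins and fuses runs
  separated by at most `merge_gap_s` (default 0.5 s): bursts last seconds,
  so sub-second dips belong to one event.  The slice-level catalog is the
  interval union over SCN electrodes, merged the same way.
* `band_decomposition` classifies each 1-min bin of the electrode-mean rate
  as burst-containing iff it overlaps a slice-level event, and reports band
  means and their gap per 24-h day.  A day without burst minutes reports the
  gap as absent (NaN), not zero.
* `synchrony_matrix` is the Pearson correlation of 100-ms rate series over
  all SCN electrode pairs (default window: 10 min at CT8).  Zero-variance
  series yield undefined entries that are excluded from the off-diagonal
  mean.
* `burst_phase_profile` counts supra-threshold bins of the electrode-mean
  rate in 10-min windows centered every 4 CT hours, averages across cycles,
  and normalizes by the mean across windows, so a phase-independent burst
  process gives a flat profile at 1.

## Chi-square periodogram

`ChiSquarePeriodogram` implements the Sokolove–Bushell statistic.  For a
candidate period of `P` samples the series is truncated to `K = ⌊N/P⌋`
complete blocks and folded into a `K × P` array with column means `M_h` and
grand mean `M`:

    Qp = K · (K·P) · Σ_h (M_h − M)² / Σ_i (x_i − M)²

Under a white-noise null, Qp ~ χ²(P−1); the significance line is the
pointwise upper-α quantile (α = 0.01 by default) with no multiplicity
correction, matching the conventional plotted threshold.  The reported best
period is the Qp argmax among supra-line periods; a constant series is
flagged arrhythmic.  The period grid steps one sample of folded length
(1-min series → 0.0167-h resolution), searched over 20–28 h, and at least
three full cycles of data are required at the longest tested period.
Because the threshold is pointwise, scanning ~500 candidate periods on pure
noise crosses the line somewhere in a substantial fraction of realizations;
the calibrated property is the pooled per-period exceedance rate (~α), and
that is what the null-calibration test asserts.

## Cosinor, Rayleigh and amplitude metrics

`Cosinor` fits `M + A·cos(2π(t − φ)/τ)` by linear least squares on
cosine/sine regressors at fixed `τ`; with `τ` free it profiles the residual
sum of squares over 20–28 h (0.1-h grid plus bounded scalar refinement).
The acrophase φ is the fitted peak time wrapped to `[0, τ)`.  Goodness of
fit is the fraction of variance explained.

`rayleigh_stats` maps phases to angles `2π·phase/τ` and reports the
circular mean and mean vector length `r = |Σ exp(iθ)|/n` (1 = perfect
synchrony, 0 = uniform dispersion).

`amplitude_metrics` smooths the series with a centered 2-h moving average —
enough to suppress burst-band contamination of 1-min rate series without
materially shifting circadian phase — then takes per-cycle peak/trough of
the smoothed series and reports the standardized amplitude
`(peak − trough)/peak`.  The damping ratio is a declared convention:
cycle-6 over cycle-1 standardized amplitude.  A non-positive peak leaves
the cycle undefined.

## Pixel-level rhythm maps and kymographs

`pixel_acrophase_map` fits every pixel with a cosinor at a single
slice-level period (per-pixel free periods destabilize the fits and the
acrophase map is defined at one τ anyway), vectorized as one least-squares
solve for all pixels.  Pixels below a goodness-of-fit threshold (default
0.1 of variance explained — the exclusion rule for non-rhythmic pixels is a
declared default, configurable) are masked; the relative map subtracts the
circular mean phase of the rhythmic pixels.  The map is time-shift
equivariant: delaying the stack by Δ shifts all acrophases by Δ (mod τ) and
leaves the relative map unchanged.

`line_scan` samples intensities along an integer pixel line per frame
(position × time); widths > 1 average parallel one-pixel lines offset
perpendicular to the dominant direction.

## Calcium-transient detection

Traces are detrended by a running median (window 180 s, ≥10× a transient
duration) with a second pass that masks gross positive excursions (>2
robust SD against the first-pass baseline) and interpolates across them, so
frequent transients cannot drag the baseline or the noise estimate upward.
The residual is correlated with a causal exponential kernel (time constant
15 s, unit L2 norm) matched to the fast-rise/exponential-decay transient
shape; this integrates the transient's full energy instead of thresholding
single samples.  The noise scale is 1.4826×MAD over unmasked residuals.
Events are runs of at least 2 matched-filter samples above `k = 4` noise
SDs, fused across gaps ≤ 10 s (a decaying tail may straddle the threshold);
events below ΔF/F = 0.02 are discarded as baseline curvature.  ΔF/F is
defined against the running-median baseline.  Event onset is taken from the
raw residual (first sample carrying ≥ half the peak), since the
matched-filter response can lead the transient by a sample.

Measured operating characteristics at the defaults (0.33 fps, Gaussian
noise): false-positive rate ≈ 0.6 events per 24 h on pure noise; detection
essentially exact for transients ≥ ~8× the noise SD (the generator default
is 20×), and ≈ 90% sensitivity at exactly 5× the noise SD.  A per-sample
detector that is reliable at a 5× amplitude with a 4σ criterion and < 1
false event/day does not exist — the matched filter is how the detector
approaches that corner, and tests assert exact counts at the default
amplitude plus ≥85% sensitivity at the 5× floor.

`burst_ca_coincidence` reports, both ways, the fraction of event onsets
within a tolerance of an onset in the other catalog; the tolerance should
cover the calcium sampling interval (the pipeline uses
`max(2 s, frame interval)`).  Empty lists leave fractions absent, not zero.

## Actogram analytics

`OnsetDetector` uses a 6 h/6 h contrast template: the onset of each cycle is
the earliest minute maximizing mean activity in the following 6 h minus the
preceding 6 h, searched within ±6 h of the expected onset (previous onset
plus the period guess).  The template is a declared, configurable stand-in
for unpublished commercial onset detectors.  Cycles without activity in the
search window are skipped.  A least-squares line through onsets vs cycle
number gives the free-running period (slope) and the cycle-to-cycle
variability (residual SD in minutes, 2 degrees of freedom removed).  On the
synthetic square-wave actograms the detector localizes onsets to ~0.5 min,
so the residual SD recovers injected onset jitter essentially unbiased
(tested at 5–40 min over 28 cycles).

`activity_partition` under LD sums counts per light/dark of each 24-h day;
under DD the subjective night is the 12 h following each detected onset
(onset := CT12 for behavior, consistent with nocturnality) and the
subjective day the remainder of the cycle.  `behavior_period` runs the
chi-square periodogram on 1-min counts over the trailing 28 days of
constant darkness.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
per preset:

* **wt** — per-electrode inhomogeneous spiking whose rate follows a
  circadian sinusoid between 2 Hz (trough) and 18 Hz (peak at CT8), period
  23.86 h, with a 35-ms absolute refractory period.
* **gaba_deficient** — the same baseline plus slice-wide bursts: regular
  spiking at 60 Hz (admissible 35–80) for 5 s, start-to-start gaps i.i.d.
  uniform on [120, 180] s, the first burst at t = 0, identical timing on
  all electrodes, independent of circadian phase.

Baseline spiking is generated by thinning a homogeneous Poisson stream and
enforcing a non-paralyzable dead time `r`.  The thinning targets the
dead-time-corrected intensity `λ_p = λ/(1 − λ·r)` so that the *realized*
rate equals the nominal sinusoid (a naive thinned-plus-refractory process
would run ~28% slow at the 18-Hz peak); this requires `peak_rate·r < 1`,
which the configuration validates.  The refractory period caps any 100-ms
window at ⌊0.1/r⌋ + 1 = 3 spikes, i.e. 30 Hz, which is why wild-type
recordings can never cross the 35-Hz burst criterion.  Intra-burst spiking
is a regular grid, not Poisson, so every 100-ms bin fully inside a burst
holds exactly `burst_rate/10` spikes and the burst criterion is exactly
testable.

PER2 image stacks emit, per pixel,
`M + A·d^(t/τ)·cos(2π(t − φ_i)/τ) + noise` with per-pixel acrophases
wrapped-normal around CT12 (SD 0.5 h by default), damping `d = 0.9` per
cycle, hourly frames.  Calcium traces are a circadian baseline (peak CT6)
plus a one-frame-rise, 15-s-decay transient at every scheduled burst;
default transient amplitude is 20× the noise SD (the detector assumes at
least 5×), frames every 3 s.  Actograms are nocturnal square waves (active
12 h per cycle at 18 counts/min vs 2 at rest, a 9:1 ratio), period 23.7 h
under DD with per-cycle Gaussian onset jitter, Poisson counts, 1-min bins;
under LD, onsets lock to lights-off.

All randomness derives from a single seed through named
`numpy.random.SeedSequence` substreams (schedule / spikes-per-electrode /
image / calcium / actogram), so a fixed seed reproduces every modality
bit-identically and modalities are statistically independent.

What the generator does **not** emulate: biophysical membrane or GABA
receptor dynamics, optical point-spread functions or photon statistics,
electrode geometry, spike-sorting noise, inter-electrode rate
heterogeneity, or slice-to-slice biological variance in period and
amplitude.  Tests passing on these synthetics therefore validate the
*operational definitions and estimators*, not biological effect sizes; the
periods, correlations and variability magnitudes of real slices include
biological variance the presets deliberately exclude.

## Problem sizes

The test suite and acceptance script choose sizes that exercise the methods
at full statistical strength while staying desk-scale: the wild-type
reference simulation is 5 circadian cycles across 12 electrodes (≈4.3
million spikes per electrode); burst/synchrony checks use minutes-long
windows; recovery suites use 12–200 replicates per condition; actogram
analyses use 28 simulated days.

## Known limitations

* The periodogram significance line is pointwise; across a ~500-period grid
  a global test would need a familywise correction, which is deliberately
  not applied (the plotted-line convention).
* The onset template assumes roughly nocturnal, step-like activity;
  crepuscular or fragmented patterns would need different template widths.
* Calcium ΔF/F is defined against a running-median baseline; slow drifts
  faster than the baseline window would bias amplitudes.
* `cosinor_fit` is single-component; waveforms far from sinusoidal fold
  harmonic power into the residual, lowering the reported goodness of fit.
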