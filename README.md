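# scnburst

Burst-firing and circadian-rhythm analysis for recordings of the
suprachiasmatic nucleus (SCN), the hypothalamic master circadian clock.

GABA is expressed by nearly all SCN neurons, and fetal SCN tissue lacking
GABA signaling (e.g. VGAT or GAD65/67 deletion) fires in slice-wide
synchronized **bursts** — multiunit rates of 35–80 Hz lasting a few seconds,
recurring every 2–3 min at all circadian phases — while the molecular
PER2 clock keeps oscillating normally.  `scnburst` packages the analysis
needed to quantify that phenotype end to end, for people working with
multi-electrode array (MED) slice recordings, bioluminescence/fluorescence
image stacks, and behavioral actograms:

* **spikes** — binning to firing rates, the bin-ratio distribution around
  the operational burst criterion (rate > 35 Hz in a 100-ms bin), burst
  catalogs, burst/non-burst band decomposition, pairwise synchrony
  (Pearson correlation matrices), and the circadian phase profile of burst
  occurrence;
* **rhythms** — Sokolove–Bushell chi-square periodogram
  `Qp = K·N·Σ_h(M_h−M)² / Σ_i(x_i−M)²` with a pointwise χ²(P−1)
  significance line at p < 0.01, single-component cosinor
  `y = M + A·cos(2π(t−φ)/τ)`, Rayleigh circular statistics (mean vector
  length r), standardized amplitude `(peak−trough)/peak` and damping
  ratio, and circadian-time conversion with CT12 anchored to the PER2
  peak;
* **imaging** — per-pixel acrophase maps of PER2::LUC stacks, line-scan
  kymographs, ROI series, matched-filter calcium-transient detection, and
  burst/calcium coincidence fractions;
* **behavior** — actogram activity-onset detection, cycle-to-cycle onset
  variability, daily activity profiles, light/dark (or subjective
  day/night) activity partition, and the 28-day free-running periodogram;
* **synth** — a synthetic-data generator that emulates wild-type and
  GABA-deficient recordings (spike trains, image stacks, calcium traces,
  actograms) with known ground truth, so every stage is testable without
  any data download.

Core statistics are exposed as scikit-learn-style estimators
(`BurstDetector`, `ChiSquarePeriodogram`, `Cosinor`,
`CalciumSpikeDetector`, `OnsetDetector` — `fit` plus fitted `_`
attributes), with plain functions (`detect_bursts`, `chisq_periodogram`,
`cosinor_fit`, ...) as thin wrappers.  See `docs/methods.md` for the full
model and parameter documentation.

## Worked example

Run the full pipeline on a simulated GABA-deficient slice (3 days,
12 electrodes, hourly PER2 frames, 3-s calcium frames):

```sh
scnburst report --preset gaba_deficient --seed 7 --duration-h 72 --outdir ko_run
```

`ko_run/report.json` then contains (abridged):

```
frac_above_35hz_pct        3.88
mean_offdiag_correlation   0.637
n_burst_events             1726
median_interburst_s        151.1
burst_phase_profile_rel    [1.005, 1.006, 1.063, 0.923, 1.003, 1.000]
coincidence_ca_near_burst  1.0
coincidence_burst_near_ca  1.0
rayleigh_r                 0.992
per2_cosinor.period_h      23.70
per2_cosinor.rsq           0.991
```

Reading the numbers: in the 10-min window at the circadian activity peak
(CT8), 3.9% of 100-ms bins exceed 35 Hz — above the >3% level that
distinguishes GABA-deficient from wild-type tissue, where the refractory
ceiling keeps every bin at or below 30 Hz and this fraction at exactly 0.
The electrode pairs are strongly correlated (mean off-diagonal 0.64)
because bursts hit every electrode simultaneously; 1726 burst events recur
with a median spacing of 151 s (within the 2–3 min range); the burst phase
profile is flat near 1, i.e. bursting is independent of circadian phase;
every detected calcium transient coincides with a burst and vice versa;
and despite all of this the PER2 rhythm is intact — pixel acrophases are
tightly synchronized (Rayleigh r = 0.99) with a clean ~23.7-h cosinor fit.
The same command with `--preset wt` reports zero burst events and a
supra-35-Hz fraction of 0.

The run directory also holds the generated raw data (`spikes.tsv`,
`per2_stack.tif` + YAML sidecar, `calcium.csv`, `actogram.csv`), derived
tables (`band_summary.csv`, `synchrony_matrix.csv`, `kymograph.csv`), a
log, and `manifest.yaml` echoing every parameter and the SHA-256 of every
output, so a run is reproducible from its manifest.

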