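# Methods

## Signal model of the synthetic cohort

Each subject's recording is a sum, per channel, of

* a pink (1/f-amplitude) background, SD 4 µV;
* one band-limited Gaussian oscillator per canonical band (delta 1–4, theta
  5–9, alpha 10–13, beta 14–32, low gamma 33–52 Hz), synthesized directly in
  the frequency domain (independent complex-Gaussian coefficients inside
  `[lo − 0.5, hi + 0.5]` Hz so each periodogram bin of the band is covered);
* a 60 Hz sinusoid (amplitude = background SD by default, random phase per
  channel);
* sporadic artifacts: 0.15-s transients at 8 × channel SD, 1.5-s slow
  (~2 Hz) movement waves at 6 × SD, and 1.5-s broadband bursts at 5 × SD
  across all channels, at Poisson times (2/min by default). Ground-truth
  labels mark the 1-s epochs in which the injected waveform reaches at least
  3 × the channel SD — epochs merely grazed by a tapered tail are not
  artifacts in any operational sense.

Oscillators are narrowband *noise*, not sinusoids, so per-epoch periodograms
have realistic sampling variance and the group t-tests see non-degenerate
within-group spread.

### Band-power calibration

The study conditions are expressed as group-level *relative band powers*
(band bin-sum / all-band bin-sum of the normalized PSD): high-ESS
delta .294, theta .208, alpha .260, beta .087; low-ESS .239/.181/.318/.112.
The four reported bands sum to ≈ 0.85 in both groups, and the remainder
(≈ 0.15) is assigned to low gamma. Oscillator variances are initialized
proportional to the target fractions and refined by ≤ 10 fixed-point
iterations (`v ← v · target/measured`) against a 900-s calibration
realization measured through the *exact* downstream chain (high-pass, notch,
epoching, periodogram, normalization), stopping when every band is within
0.002. The calibration realization is built by the same component
constructor as subject synthesis, because the narrowband PAC components have
different band-edge leakage than broadband oscillators and would otherwise
bias theta by ~0.01.

Two band statistics coexist deliberately. The per-feature path
(`bandwise_psd`) is the mean of the band's normalized bins — the quantity
the t-test grids and the 30 band × channel features use. The group-summary
path (`band_power_fractions`) is relative band power, which is invariant to
the normalization range and is the only scale on which the published group
means are arithmetically possible (a mean-bin theta of 0.208 over five bins
inside a range whose bins sum to 1 would require the band alone to carry
1.04 of the total). The generator calibrates, and the acceptance script
reports, relative band power.

### Between-subject variation

Each subject multiplies every band variance by a mean-one lognormal jitter
(σ = 0.12 on the log scale). This yields group SDs of ~0.01–0.03 on the band
fractions — smaller than the published between-patient spread, which keeps
desk-scale replicate tests stable; consequences: group contrasts are cleaner
than clinical reality and classifier accuracy saturates near 1 rather than
at the published ~0.8. What the passing tests show is that the pipeline
*recovers what the generator encodes*, not that real EEG separates this
well.

### Coherence and PAC structure

For bands with a coherence target c (delta and theta of the O2–C4 pair;
c = 0.5 high, 0.2 low), both pair channels receive `α·shared +
√(1−α²)·own` with α = c^{1/4}; for unit-variance components the
magnitude-squared coherence of the mix is α⁴ = c. The per-epoch Welch
estimator adds its positive small-sample bias (~0.14 for independent
signals at 8 Hamming segments), so measured values sit above c; only the
group contrast and the placement (configured pair ≫ all other pairs) are
contractual.

PAC uses equal depth 0.2 in both groups: half of the phase band's variance
is a narrowband component at `phase_hz ± 1` whose Hilbert phase φ modulates
a narrowband carrier (`carrier_hz ± 2`, half of the carrier band's
variance) as `(1 + d·cos φ)/√(1 + d²/2)`. When a band is both
coherence-mixed and PAC-structured (theta, by default), the shared source
replaces only the broad half — otherwise the group-specific mixing weight
would dilute the coupling differently per group and manufacture a spurious
PAC group difference, which the design explicitly forbids (the emulated
finding is a PAC null).

Covariates are drawn independently of the EEG (truncated normal age/BMI,
Bernoulli sex, per-group moments from the study's cohort table; ESS uniform
on [20, 24] / [0, 4]). A `leakage` knob in [0, 1] shifts the high-ESS
covariate distributions to make the confounds genuinely informative for
confound-analysis stress tests.

## Preprocessing and estimator choices

* Filters: 4th-order Butterworth, applied forward–backward (zero phase) —
  phase integrity matters downstream for PAC. The high-pass corner is 1 Hz,
  the band-stop 57.5–62.5 Hz.
* Epochs start at integer seconds from the lights-out annotation. The
  "cleanest 3 minutes" are the 180-epoch window minimizing the count of
  flagged (epoch, channel) cells, earliest window on ties.
* Artifact flags are per channel. Single-channel features drop that
  channel's flagged epochs; pair features drop epochs flagged in either
  channel. A channel with > 50 % flagged epochs inside the selected window
  is dropped for that subject and its features become missing values.
* The artifact detector is a standardized linear SVM on four per-epoch
  features (log peak amplitude, log variance, 1–8 Hz power fraction,
  45–80 Hz power ratio), trained on generator ground truth; its threshold is
  fixed at training time.
* Coherence: Welch magnitude-squared coherence per 1-s epoch with Hamming
  windows, 8 segments, 50 % overlap (segment length fs/4.5), epoch-averaged,
  then linearly interpolated onto the integer-Hz grid. An all-pairs fast
  path shares one STFT per channel and is test-verified to be numerically
  identical to the per-pair reference.
* PAC band-pass + Hilbert: realised spectrally — the FFT of each clean run
  is weighted by the squared magnitude response of an order-4 Butterworth
  band-pass (zero phase) and negative frequencies are zeroed; 0.5 s is
  trimmed from each run end. Phase bandwidth ±2 Hz, amplitude bandwidth
  ±center/4. The order-4 skirts keep both modulation sidebands inside the
  amplitude band of the true carrier, so the MI grid peaks at the generating
  (phase, carrier) cell.
* Low-gamma amplitude centers are {33…51}, medium-gamma {45…54}; the
  overlap is retained because the medium-gamma bounds have no authoritative
  definition. Grid orientation is phase (10) × amplitude (9).
* Rank-sum tests use exact enumeration for combined n ≤ 10 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction (identical samples still give p = 1). PSD/coherence cells use
  unpaired Welch t tests — with 31 vs 41 subjects a paired design is
  impossible, and Welch is robust to the unequal group variances the
  generator produces.
* GLM: own IRLS with ridge 1e-6 on non-intercept coefficients. If the fit
  diverges or |β|∞ > 20 (complete separation, common in 14-subject folds)
  the ridge escalates to 1e-2 and the fit is flagged. McFadden pseudo-R² is
  the default (Cox–Snell and Nagelkerke are available); statsmodels serves
  as the independent oracle in tests, never as the implementation.
* kNN score = (weighted) fraction of the k nearest training neighbours
  labelled high; predicted label = score ≥ 0.5 with ties toward the positive
  class; AUC is the rank (Mann–Whitney) statistic with ties averaged.
  Hyperparameter search is nested (inner stratified 3-fold per training
  fold) by default; a "global" single-search mode exists for comparison.

## Family-level PAC null

The equal-PAC condition is checked at the family level: 48 rank-sum cells
are strongly correlated within a cohort, so "no cell significant" would fail
by chance too often to be a meaningful criterion. A replicate passes when
its flagged-cell count does not exceed the binomial(48, 0.05) 99.5th
percentile (7 cells); the threshold was fixed from the null model before any
measurement.

## Problem sizes

Cohort-level tests run 72-subject cohorts in a 200–220-s recording container
(the 180-s analysis window plus annotation margins; the container length is
a free parameter of the generator, 600 s by default). Replicated
calibration checks use 25 replicates (t-test power, flag rates, classifier
power/chance) and 4 replicates (PAC family null, with the full MI grid per
channel). The acceptance script uses the full 600-s default container.

## Known limitations

* The generator is stationary within a recording: no drowsiness drift,
  eye-state changes, microsleeps, or montage/reference artifacts; the
  artifact taxonomy is schematic.
* Between-subject variability is narrower than clinical cohorts, so
  classifier metrics saturate; only calibration-, ordering- and
  null-properties are meaningful at desk scale.
* Coherence targets are nominal mixing parameters, not calibrated
  closed-loop like band powers.
* EDF support covers what the package itself writes and reads (16-bit,
  1-s records, plain-text event sidecars), not the full EDF+ specification.
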