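# Methods

This note documents the models, conventions and numerical choices behind
`sleepcortex`, and what the synthetic-data generator does and does not
emulate.

## Sleep macrostructure

A hypnogram is a sequence of AASM stages (W, N1, N2, N3, REM), one per 20-s
scoring epoch (configurable), with explicit lights-off/lights-on bounds.
Conventions, chosen where the standard definitions leave room:

- **Sleep onset (SO).** Clinically, SO is an event-level definition (first
  K-complex or >0.5 s spindle), which cannot be recovered from stages alone.
  The `Hypnogram` therefore accepts an explicit `so_marker` from event
  scoring; absent that, SO falls back to the first non-wake epoch after
  lights-off. Deterministic, and exact whenever event scoring is available.
- **REM latency** is measured from SO (not lights-off), consistent with the
  SO-latency definition and standard PSG practice.
- **WASO** counts wake epochs strictly between SO and the last sleep epoch;
  terminal wake is excluded, keeping WASO an intra-sleep quantity and making
  the awakening count (ISA: number of maximal wake runs inside WASO)
  consistent with it.
- Stage percentages are relative to total sleep time; SEI = TST/TBT × 100
  with TBT the lights-off→lights-on interval.

Degenerate inputs are defined outcomes, not crashes: an all-wake record has
missing latencies/WASO/ISA, TST = 0 and SEI = 0; a record without REM has a
missing REM latency and REM% = 0.

## Spectral analysis

- **Preprocessing.** Scalp channels are re-referenced to the averaged
  mastoids (A1+A2)/2 when mastoids are present, then band-passed 0.33–30 Hz
  with a zero-phase filter.
- **Filter.** The default filter multiplies the full-record spectrum by the
  squared magnitude response of a digital order-6 Butterworth band-pass —
  exactly the zero-phase response that forward–backward (`filtfilt`)
  filtering approximates, at about half the cost on long records;
  `method="filtfilt"` is available. With the default edges the response is
  flat to <1 dB on [0.66, 24] Hz and >20 dB down at 0.165 Hz and 60 Hz.
  Near-Nyquist high cuts (hi ≳ Nyquist/2) cannot meet such a stopband
  template with any reasonable filter; the high cut must simply be below
  Nyquist, and the template is guaranteed for hi ≤ ~0.5·Nyquist.
- **Periodogram.** Non-overlapping 4-s windows aligned to epoch starts (five
  per 20-s epoch), restricted to epochs of the requested state inside the
  lights interval, minus artifact-masked windows. Each window is
  mean-removed, optionally tapered (rectangular default — a pure
  periodogram; Hann available, normalized to unit mean-square so broadband
  power is preserved), and Fourier transformed at the native 0.25 Hz bin
  spacing. Power is scaled so the positive-frequency spectrum sums to the
  window's mean square (Parseval); an on-bin sinusoid of amplitude A carries
  A²/2 in its bin. Only ratios matter downstream, so the absolute scale is a
  convention.
- **Normalization.** State spectra (mean over windows) are converted to
  percentage power over the *whole topography*: each (channel, bin) cell is
  divided by the sum over 19 channels × 98 bins (0.50–24.75 Hz). This
  removes between-subject differences in absolute power while preserving the
  spatial distribution. Normalization is per state; a bin belongs to a band
  (and to the denominator) iff its center frequency lies in the printed
  closed interval. The five bands partition the 98 bins (18+12+16+16+36) and
  the six clusters partition the 19 channels (4+3+3+3+4+2), so band/cluster
  tables always sum to 100.
- **Missing states.** A subject with no artifact-free windows in a state
  (commonly REM in short recordings) gets NaN for that state's indexes and
  is excluded pairwise from the affected correlation cells, with the
  realized n recorded per cell.

## Association statistics

For each (region, hemisphere) — 34 Desikan regions plus the hemispheric mean
thickness as its own pseudo-region — the thickness vector is correlated with
all 18 index cells (3 indexes × 6 clusters): two-tailed Pearson tests
(p from t = r√(n−2)/√(1−r²) with n−2 df), then Benjamini–Hochberg step-up
adjustment *within the fixed 18-test family*, separately per hemisphere;
significance means adjusted p ≤ α (default 0.05). Cells with fewer than four
complete pairs are reported as missing but the family size stays 18 (their
p enters the adjustment as 1). Partial correlations for significant records
residualize both variables on [intercept, age, sex] (sex coded F=1/M=0; the
coding only flips a regression sign and leaves residuals unchanged) and use
t with n−2−k df; constant covariate columns are dropped with a warning and k
adjusted. A variable exactly explained by the covariates yields
(partial r, p) = (0, 1) — nothing left to correlate.

BH adjustment is delegated to statsmodels, Pearson to scipy; both are pinned
by oracle tests (exhaustive step-up enumeration; numeric integration of the
t density). The partial correlation is computed directly via least-squares
residuals and is cross-checked against pingouin in the test suite.

## Synthetic data generator

The generator supplies every input the pipeline consumes, with known ground
truth. It emulates the *statistical structure* of an AD-like sleep study,
not the physiology.

- **Hypnogram.** First-order Markov chain whose stationary stage mix equals
  the target percentages. From stage i the chain leaves with a per-stage
  switch rate (W 0.09, N1 0.50, N2 0.30, N3 0.30, REM 0.20 per epoch, scaled
  by a global `fragmentation` factor) and re-draws the next stage from
  q ∝ target × rate, which preserves the target mix while giving wake long
  consolidated bouts and N1 brief transitional ones. The default AD-like
  in-bed targets (W 28.5, N1 5.0, N2 53.1, N3 0.4, REM 13.0 percent) yield a
  sleep efficiency near 71%, N2 near 74% of TST, near-absent N3, and on the
  order of 20 awakenings per night. At 1350 epochs the realized stage mix
  tracks its targets to within ~3 percentage points on average. Limitation:
  the chain is stationary, so sleep-onset latency is geometric (a few
  minutes) rather than the longer clinical values, and there is no ultradian
  REM cycling.
- **Signal.** Per channel, Gaussian background with PSD ∝ (f+0.5)^(−γ) plus
  a white floor (γ = 1), synthesized in the frequency domain at 128 Hz
  (default) and scaled to 15 µV RMS; content above 35 Hz is not synthesized
  since the analysis band-pass would remove it. State-gated oscillatory
  bursts are added synchronously over a component's channels: raised-cosine
  envelopes of 0.5–1.5 s, frequency jittered within the component bandwidth,
  with a deterministic burst count per epoch fixing the duty cycle. Defaults:
  13±0.5 Hz sigma bursts (9 µV, duty 0.25) at frontal/central/parietal sites
  during N2, and 2±1 Hz delta bursts (25 µV, duty 0.5) at
  frontopolar/temporal sites during REM — producing elevated central
  NREM sigma and the frontotemporal REM delta dominance characteristic of
  EEG slowing. Mastoids are low-amplitude white noise; artifact windows
  (optional rate) receive a 400 µV transient and are flagged in the mask.
  The measured cluster × band table of a pure background matches the
  analytic PSD integral within 5% relative. Signals are emitted as float32;
  all analysis accumulates in float64.
- **Cohort.** Per-subject index and thickness values are drawn from a joint
  Gaussian whose correlation matrix is the identity plus the planted
  (index, region) correlations; positive semi-definiteness is verified
  (eigendecomposition, so planted |r| = 1 is admitted exactly). Index means
  are plausible percentage-power values (REM delta dominant), thickness
  means plausible per-region mm with 0.25 mm SD; the hemispheric mean is a
  latent variable of its own rather than the average of the sampled regions,
  so links to it can be planted directly. Ages are N(73.2, 6.2²) clipped at
  40, with 12/23 female by default.
- **Signal-level coupling.** `simulate_linked_study` draws a latent z per
  subject, multiplies the *power* of the sigma bursts by g = 1 + spread·z
  (amplitude × √g, so the measured band power is linear in z; the measured
  parietal sigma index correlates with z at ≈ 0.99), and sets the linked
  region's thickness to mean + sd·(r·z + √(1−r²)·ε). The planted r is thus
  carried to the *measured* index with minimal attenuation, which is what
  makes end-to-end recovery tests meaningful.

**What passing tests do not show:** the generator has no ultradian
structure, no realistic artifact taxonomy, no spatial correlation between
channels beyond shared bursts, and index/thickness distributions are
Gaussian by construction — results on real recordings depend on properties
(non-stationarity, outliers, reference contamination) the synthetic data do
not exhibit.

## Problem sizes and numerical choices

- End-to-end recovery checks use 200 replicates of 23-subject studies with
  30-minute recordings sampled at 64 Hz (every analyzed bin is below the
  32 Hz Nyquist); full-night, 128 Hz settings are exercised in the
  module-level tests. With the planted |r| = 0.67 at n = 23 inside an
  18-test BH family, the theoretical detection probability is ≈ 0.84, so the
  ≥ 0.80 acceptance threshold is expected to hold with margin over 200
  replicates; the sign of the recovered correlation is essentially always
  correct (P(r̂ > 0) > 0.999).
- Null calibration: under the global null BH makes the per-family
  probability of any significant record equal to α; 2000 simulated families
  bound the Monte-Carlo error at ~0.5 percentage points.
- Tolerances: conservation identities and spectral-path equivalence are
  asserted at 1e-9 (float64); EDF round trips at the 16-bit quantization
  step (±2000 µV range, ~0.061 µV); stochastic calibrations at the margins
  stated in the tests.
- All generators are pure functions of their seed (numpy `default_rng`);
  every CLI and pipeline entry point takes an explicit seed and records it
  in the run manifest.

## Known limitations

- The EDF writer is minimal (16-bit, 1-s records, fixed physical range,
  fixed synthetic start date) — sufficient for synthetic studies and
  round-trip-tested against mne's reader, not a general-purpose exporter.
- FreeSurfer `aparc.stats` files are supported only through their tidy
  long-form export (subject, hemisphere, region, thickness_mm); the reader
  normalizes FreeSurfer region spellings but does not parse raw stats
  blocks.
- Hemispheric mean thickness, when absent from the input, is approximated
  as the unweighted mean of the 34 regions (surface-area weights are not
  available from thickness-only input) and flagged as approximated.
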