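# Methods

## Model

The package models resting-state posterior EEG as a sequence of 2-s epochs,
each dominated by a single oscillatory component whose frequency (the
dominant frequency, DF) moves on a 0.5 Hz grid between 1 and 12 Hz. The
clinically meaningful signal is not the spectrum of any single epoch but
the *trajectory* of the DF across epochs: its mean location, its
variability, and how the epochs distribute over four bands —

- delta: [1, 4) Hz
- theta: [4, 5.5) Hz
- pre-alpha: [5.5, 8) Hz
- alpha: [8, 12] Hz

Band edges are half-open on the right except alpha, which is closed, so
every grid frequency in [1, 12] belongs to exactly one band.

### Spectral estimation

Each 2-s epoch is Hann-windowed and transformed with a real FFT. Power is
normalized so that the sum over retained bins equals the epoch variance
(window power correction `U = mean(w²)`; one-sided doubling except at
Nyquist; DC dropped). Bins are retained between 0.5 and 70 Hz. With 2-s
epochs the bin spacing is exactly 0.5 Hz regardless of sampling rate.
Parseval consistency is enforced by test to within 1% for band-limited
signals.

Epochs whose peak absolute amplitude exceeds a configurable limit
(default 100 µV) are flagged as artifacts; the first 90 clean epochs are
analyzed. Channel spectra are averaged over a region (default the
posterior derivations Pz, P3, P4, O1, O2) before descriptor extraction.

### Descriptors

- **DF** — frequency of maximal power within 1–12 Hz; ties resolve to the
  lowest frequency. Undefined (error) if no in-band power exists.
- **DF mean** and **DF range** (min, max) over the 90 epochs.
- **DFV** — dominant-frequency variability. The default estimator is the
  range width (max − min); standard deviation and mean successive
  difference are available alternatives. The range width dominates the
  standard deviation for any sample, which makes the default the most
  sensitive of the three to transient excursions.
- **FP** — frequency prevalence: percentage of epochs whose DF falls in
  each band.
- **BI** — band inscription: percentage of epochs containing a
  supra-noise local spectral maximum in each band, where the noise
  reference is the epoch's mean power over 1–12 Hz.
- **Frequency ratio** — power in the dominant fast band divided by the
  summed power of all slower bands; undefined (error) when the denominator
  is zero.

### Pattern classification

Six deterministic rules over the descriptors, evaluated in a fixed
precedence order: 1, 3, 1plus, 2, 5, 4. Each rule is a conjunction of
thresholds on DF mean, DFV, FP and BI (see `csaeeg/classify.py`; the rule
trace of every decision is recorded in the returned object). Pattern 5 is
tested before pattern 4 because the two rules overlap: any diffusely
slowed trajectory confined to delta/theta satisfies the unstable
pre-alpha conditions as well, so testing 4 first would make 5 unreachable.
Discriminating between them uses the longest run of consecutive epochs
with a fast (pre-alpha or alpha) DF: pattern 5 requires that run to be at
most 2 epochs.

Descriptor combinations matched by no verbatim rule are resolved by a
fallback that maps the dominant band and DFV onto the nearest pattern, so
classification is total; fallback decisions are tagged as such in the rule
trace and surfaced as warnings by the pipeline.

An EEG is **abnormal** when the pattern is not 1 *and* (DF mean < 8 Hz or
DFV > 1.5 Hz). Pattern 1 predicts an AD-like outcome; all other patterns
predict a DLB-like outcome. The predictor never predicts non-conversion.

## Synthetic generator

Each pattern has an archetype: a DF center and spread, a band-occupancy
mixture, a dominant-component amplitude (20 µV), an optional secondary
component, and a 1/f-amplitude Gaussian-phase background (2 µV RMS by
default). Generation proceeds in two stages:

1. **Trajectory** — band epoch counts are apportioned from the mixture by
   the largest-remainder method, so occupancy matches the target within
   ±1 epoch deterministically (a multinomial draw would mis-occupy bands
   often enough to flip rule thresholds at n = 90). Within each band, DFs
   are drawn uniformly from the grid points inside the center ± spread
   window. For pattern 5 the sequence is reshuffled until no fast run
   exceeds 2 epochs.
2. **Signal** — each epoch is a sinusoid at its DF plus the optional
   secondary component and background noise. Posterior channels share the
   same trajectory with independent phases and noise; other channels are
   attenuated by 0.4.

**Realism limits.** The generator produces idealized stationary epochs:
no within-epoch frequency drift, no spindles or paroxysms, no volume
conduction or channel covariance structure, no eye/muscle artifacts
(artifacts can be injected only as amplitude spikes), and a noise floor
far below clinical EEG. It is a test harness for the analysis chain, not
a biophysical model; recovery rates on synthetic data are upper bounds.

## Reference cohort

`reference_cohort()` builds a 42-subject cohort of archetype-generated
trajectories: 20 MCI-to-DLB converters (9 × pattern 1plus, 10 × 2, 1 × 3),
14 MCI-to-AD converters (13 × 1, 1 × 2) and 8 non-converters (5 × 1,
2 × 1plus, 1 × 2), with early-DLB clinical feature flags for 15, 2 and 2
subjects per group respectively. Per-subject seeds are spawned from a
root `SeedSequence`, so the cohort is reproducible. Cohort descriptors
are computed at trajectory level (noiseless idealization), which keeps
the composition exact; signal-level recovery is validated separately.

## Numerical choices

- Percentages in report tables are rounded half-up to one decimal
  (`Decimal`), matching clinical-table conventions; all underlying values
  are kept unrounded.
- Correspondence analysis is a plain SVD of the standardized residual
  matrix with principal coordinates; total inertia equals the Pearson
  chi-square statistic divided by the grand total (tested to 1e-10).
  Zero-margin rows/columns are dropped with a warning.
- EDF output uses a minimal 16-bit writer with 1-s records and a fixed
  header date so identical recordings produce byte-identical files;
  reading goes through `mne` so round-trips are verified against an
  independent parser.
- Group statistics delegate to `scipy.stats` (ANOVA, Kruskal–Wallis,
  Welch t with Bonferroni correction, Spearman, Fisher exact).

## Open design decisions

- The DFV estimator is configurable; only the range width is wired to the
  classification thresholds, which were defined against it.
- The fallback mapping for unmatched descriptor combinations is a design
  choice; alternative resolutions (e.g. nearest-rule distance) would be
  defensible. The rule trace makes fallback use auditable.
- The 0.5–70 Hz spectral retention range discards DC and very-high
  frequencies; Parseval identities therefore hold only for band-limited
  content.

## Limitations

- Threshold rules are brittle near their boundaries by construction;
  descriptor values falling exactly on a threshold follow the stated
  open/closed conventions of each rule.
- The package evaluates predictors on fixed cohort compositions; it does
  not perform cross-validation or estimate uncertainty of the predictive
  values beyond exact counts.
- No preprocessing beyond amplitude-based artifact flagging is provided
  (no filtering, re-referencing, or ICA); inputs are assumed to be
  referenced, filtered clinical EEG in microvolts.
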