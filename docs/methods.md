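# Methods

This note records the scientific and numerical choices behind
`bgsleep`: what is modelled, which knobs matter, what the synthetic
data do and do not emulate, and where the design was genuinely open.

## Preprocessing contract

All decoding operates on a fixed signal contract: mains-notched,
200 Hz, 30-s epochs.

* **Notch** — 4th-order Butterworth band-stop, ±2 Hz around the mains
  frequency and every harmonic below the post-downsample Nyquist
  (for 50 Hz mains and a 200 Hz target this is the 50 Hz fundamental
  only). Filtering is zero-phase (forward–backward), doubling the
  effective order, because downstream waveform features (skewness,
  zero crossings, fractal dimensions) should not inherit phase
  distortion. The stop-band width and order are our choice; only the
  filter family is dictated by the recording convention.
* **Downsampling** — polyphase FIR resampling with its built-in
  anti-alias low-pass (`scipy.signal.resample_poly`); for the common
  integer ratios (1000 or 2000 → 200 Hz) this reduces to filtered
  integer decimation. No upsampling is permitted.
* **Montage** — bipolar traces are first-listed minus second-listed
  contact, contacts ordered deepest-first. Polarity is a convention:
  every implemented feature except skewness is sign-symmetric, and
  skewness enters the decoder symmetrically across classes.
* **Epoching** — one epoch per hypnogram entry; a trailing partial
  epoch is discarded; a recording shorter than its hypnogram is an
  error, not a truncation.

## Feature set

The 28 local features per epoch divide into 18 frequency-domain and 10
time-domain values; dual-site rows append 18 coherence features.
Spectra use Welch's method with 4-s Hamming windows and 50% overlap:
0.25 Hz resolution resolves the 1 Hz delta edge while averaging 14
segments per 30-s epoch. Choices worth recording:

* **Total power** is the log10 of the summed power over the seven
  analysis bands. Defining the base this way makes the seven relative
  powers sum to exactly 1 and keeps the 45–55 Hz notch region and
  >90 Hz out of every feature.
* **Power ratios** put the lower-frequency band in the numerator
  (delta/theta, not theta/delta), matching the field's naming of the
  delta/theta ratio as the canonical NREM/REM contrast. Canonical beta
  and gamma aggregate their sub-bands by summed power; canonical
  coherences aggregate by bin-mean over the union of sub-band bins.
* **Moments** — standard deviation uses the n−1 denominator; skewness
  and kurtosis are biased (population) standardised moments, kurtosis
  in excess (Fisher) form. Hjorth parameters use population variances
  (the convention cancels in the ratios).
* **Permutation entropy** — order 3, delay 1, normalised by log 6.
  Ordinal ties are broken by sample position (stable ranking), so the
  measure is well defined on quantised data.
* **Fractal dimensions** — Higuchi with k_max = 10 (least-squares
  slope of log curve length against log 1/k); Petrosian from the sign
  changes of the first difference. These orders/depths follow the
  defaults of widely used EEG staging feature sets.
* **Coherence** — magnitude-squared coherence from Welch auto/cross
  spectra with the same segmentation; the peak coherence frequency is
  the argmax over 1–90 Hz excluding the 45–55 Hz notch gap.
* A zero-variance (flat) epoch has no defined spectrum or entropy; it
  raises an error in the per-epoch API and is dropped (and logged) in
  matrix assembly.

The entire feature block is validated against an independent naive
re-implementation (direct formulas, shared no code) to 1e-8 relative
error, and against closed forms: a monotone ramp has permutation
entropy 0 and Petrosian dimension 1; a sine of frequency f sampled at
fs has Hjorth mobility 2·sin(πf/fs); self-coherence is 1.

## Decoder

`SleepStageDecoder` wraps a LightGBM gradient-boosted tree ensemble in
the scikit-learn estimator contract.

* **Imbalance** — sleep cohorts are dominated by NREM (~60% of
  epochs). SMOTE (k = 5 neighbours, convex combinations of same-class
  neighbour pairs) grows every minority class to the majority count.
  It is applied inside training folds only — the inner-CV scorer
  resamples each inner training fold, never validation or test data.
  Degenerate classes fall back gracefully: fewer neighbours for
  classes smaller than k+1, jittered duplication for singletons, both
  logged.
* **Hyperparameter search** — nested cross-validation with 4 outer
  and 4 inner stratified folds and a 50-round Bayesian search scored
  by balanced accuracy is the reference protocol. The search is a
  Gaussian-process surrogate (Matérn 5/2) with expected-improvement
  acquisition over a unit-cube encoding of learning rate, leaves,
  estimator count, depth, child samples, subsampling, column
  sampling, and L2 regularisation; the exact space is our choice.
  With `search_rounds=0` the backend defaults are used — the
  evaluation-level functions default to this because the synthetic
  cohorts are insensitive to tuning while the 800-fit search budget
  is not.
* **Evaluation** — cross-subject contexts always hold out whole
  subjects (LOSO); the training pool is restricted by the context's
  grouping (same disease, same target, cross-all, …), subjects never
  appear on both sides (asserted), and every channel of the held-out
  subject is scored with the best channel reported (ties keep the
  deepest pair). Individualized mode runs stratified k-fold within
  one subject-night. Balanced accuracy averages recall over classes
  present in the true labels; the mislabeling rate is
  (1 − accuracy) × 60 min/h for 30-s epochs.
* **Attribution** — LightGBM's native TreeSHAP (`pred_contrib`)
  supplies exact additive attributions (they reproduce the raw margin
  row by row); global importance is the mean absolute attribution
  over rows and classes.
* **Persistence** — a JSON bundle of the booster model string, class
  list, feature-name contract and configuration hash; reloading
  reproduces predictions bit-identically. Prediction rejects feature
  matrices whose column names or order deviate from the contract.

## Optimal decoding map

Channel selection for unseen subjects works entirely from lead
coordinates: each bipolar channel (coordinate = midpoint of its two
contacts) becomes a 5-mm spherical seed of lattice voxels; the seed's
mean time series is correlated with each of 166 parcel series to give
a connectivity profile; per parcel, a rank-based (Spearman) partial
correlation of connectivity with decoding accuracy — controlling any
supplied covariates, e.g. sleep fragmentation count — yields the map.
Unseen channels are ranked by Spearman similarity of their profile to
the map. Only adjacent-referenced channels should enter map
construction (sandwich channels have a different recording-field
geometry). Rank-based correlation was chosen for both steps for
consistency and robustness; voxel-to-parcel aggregation is by mean.
Maps can be exported volumetrically to NIfTI by painting parcel values
into a declared grid.

The normative connectome is an interface (`parcel_series` +
`voxel_series`). The shipped `SyntheticConnectome` is a synthetic
stand-in: parcel centres scattered in a ±50 mm box, voxel series a
Gaussian distance-weighted (σ = 12 mm) mixture of parcel series plus
voxel-private noise, deterministic per seed. A real normative
connectome plugs in by implementing the same two members.

## Synthetic data: what it emulates, what it does not

The generator exists so that every pipeline property is testable
without patient data. Defaults are fixed once and shared by the test
suite and the acceptance script.

* **Hypnograms** — semi-Markov nights: each stage receives an epoch
  budget from the target structure (defaults: N1/N2/N3/REM =
  9.8/62.2/10.1/17.8% of sleep, efficiency 72.8%, a movement-disorder
  cohort profile), split into geometric bouts (mean dwell 4/2/12/9/9
  epochs for W/N1/N2/N3/REM) and shuffled. Realized proportions match
  targets to bout rounding at any night length.
* **Signals** — per-epoch spectra are shaped white noise: a 1/f^1.5
  background (normalised to 10 µV RMS) times stage-specific band
  gains. NREM is delta-dominant (N2 gain 3.5, N3 gain 7), REM
  theta-elevated (2.1), wake alpha/beta-tinged (2.0/1.6). Band-shaped
  noise rather than pure sines ensures the entropy and fractal
  features carry class information too. Between-subject variability
  is a log-normal multiplier per band, deliberately anisotropic
  (σ = 0.08 for delta vs 0.42–0.55 for theta/alpha/beta): wake and
  REM signatures vary across patients far more than the NREM delta
  signature, so cross-subject decoders recover NREM best — the
  ordering seen in patient cohorts. Channel quality decays
  geometrically with contact index, emulating distance to the target
  nucleus. An optional shared theta source gives paired cortical
  channels a controllable coherence; an optional ~1.1 Hz spike train
  emulates ECG contamination (off by default).
* **Connectome studies** — subjects' leads cluster (σ = 8 mm) around
  a designated parcel chosen to be centrally located and spatially
  isolated; contacts are spaced 6 mm along a random trajectory;
  accuracy is an affine function of each channel's connectivity to
  the Gaussian network (σ = 12 mm) around the designated parcel after
  removing the channel's mean connectivity level. With zero noise the
  optimal map recovers the designated parcel exactly and
  similarity-ranked channel selection beats the channel mean in the
  large majority of subjects.
* **Not emulated** — sleep microstructure (spindles, K-complexes,
  slow-wave morphology), stage-transition semantics (our shuffled
  bouts ignore the W→N1→N2 grammar), disease-specific pathophysiology
  (no beta-burst dynamics), non-stationarity within epochs, and real
  referencing artifacts. Passing tests therefore demonstrate that the
  pipeline recovers programmed structure at realistic SNR — not that
  real patients decode at these accuracies.

## Problem sizes and numerical choices

The standard test cohort is 8 subjects × 600 epochs × 2 channels
(≈ 9,600 epochs), the scale at which the chance-level and recovery
properties are stable; the acceptance script uses 8 × 600 × 1 with
equal class counts and 5 permutation seeds. All randomness flows from
explicit integer seeds (numpy `SeedSequence` for per-subject streams);
identical seeds give identical cohorts, searches and predictions.
LightGBM runs single-threaded for determinism. Correlation of a
constant vector is treated as an error (similarity, map construction)
or a logged zero (individual map parcels with degenerate profiles).

## Known limitations

* The five-class (N1/N2/N3) problem is supported end to end but the
  default generator separates NREM substages only weakly — by design,
  substage boundaries are graded in real data too.
* The Bayesian search space covers the conventional LightGBM ranges;
  it was not tuned against any external benchmark.
* The optimal-map machinery is validated on synthetic connectomes
  only; plugging in a real normative connectome changes the profile
  distributions and may require covariate choices we cannot test
  here.
* EDF export is not provided (reading is); the generator writes
  delimited signal tables.
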