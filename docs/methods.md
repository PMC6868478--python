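# Methods

This note documents the models, defaults, and design choices behind
`cogload`, and what the synthetic-data results do and do not demonstrate.

## Task and data model

The emulated study is an interactive VR n-back task: per participant,
3 workload conditions (n = 0, 1, 2) presented as blocks in seeded-random
order, 4 runs per condition, 20 four-second ball trials per run, recorded
from 8 scalp electrodes (F3, Fz, F4, C3, C4, P3, Pz, P4) at 256 Hz.
Ball colors are drawn uniformly from five colors and resampled until the
run contains at least 2 n-back targets (for n = 0 a target is a red ball;
for n ≥ 1 a color match at lag n). Runs are separated by 2 s of
marker-free signal (the inter-run pause is short in this paradigm; its
exact length affects nothing downstream). The last trial of each run is
excluded at segmentation, mirroring the recording-software truncation in
this kind of setup: 240 markers → 228 analyzed trials, which divide evenly
into 4 cross-validation folds (76 trials per class, 19 per class per fold).

### Synthetic EEG

Each trial and channel is a sum of independent components, in µV:

* **Oscillations** — for each band b ∈ {θ, α, β, γ}: unit-variance white
  noise band-pass filtered to the band (4th-order zero-phase Butterworth),
  scaled by `exp(log A_b + s_{c,b} · n)`, where A_b is the baseline RMS
  amplitude (θ 4, α 5, β 2.5, γ 1.2 µV) and s_{c,b} the per-(channel, band)
  log-amplitude slope per workload level. The band-filtered-noise forward
  model was chosen for spectral controllability; it makes no claim of
  physiological realism.
* **EMG** — 20–110 Hz band-limited noise (baseline RMS 1.5 µV) with
  log-amplitude `log 1.5 + s_EMG · n + ε`, ε ~ N(0, 0.1²) drawn per trial
  and shared across channels (scalp-muscle tension is spatially broad).
  The 20–110 Hz support makes EMG bleed into β/γ and dominate HF
  (70–100 Hz), which is the premise of the HF-suppression stage.
* **Background** — 1/f-amplitude noise, per-channel SD 2 µV.
* **Impulses** — single-sample spikes of ±200 µV at Poisson times
  (default 0.1/s), hitting all channels at the same sample (a wireless
  frame glitch); injected positions are returned for filter validation.
* **Movement bursts** — 0.5-s Hann-windowed 2 Hz bursts of 30 µV at trial
  start and end (reach and place movements). These sit below 5 Hz and are
  excluded by the band definitions; the optional 5 Hz highpass addresses
  them in the time domain.

Controller positions are drawn per trial as N(bias_n, 0.25²) with default
bias 0.25 (right-of-center resting position) identical across levels, so
hand position carries essentially no workload information (r² ≈ 0).

### Default effect sizes

No physical-unit effect sizes are available for this paradigm, so the
defaults were calibrated once so that within-participant accuracies land in
a plausible 60–90 % range rather than at ceiling: frontal θ +0.05,
parietal α −0.05, frontal β +0.03, frontal/parietal γ +0.03 log-units per
level, EMG slope 0.06. With these, typical single-participant accuracies
(θ–γ features) are ≈ 0.87 for 0 vs 2 (≈ 0.80 after HF suppression), ≈ 0.69
for 0 vs 1, and ≈ 0.59 for 0 vs 1 vs 2 — reproducing the qualitative
ordering that extreme levels separate best. `randomize_effects` flips slope
signs per participant (per feature or globally) to emulate the strong
individual differences this paradigm exhibits; the pipeline's
`heterogeneous` mode (default) uses per-feature flips.

## Preprocessing choices

* **Hampel filter** — "five standard deviations" is interpreted through the
  Gaussian-consistent robust SD = 1.4826 · MAD, the standard Hampel
  identifier. The window is `round(window · rate) // 2` samples to either
  side (257 samples total at the 1-s/256 Hz defaults, the nearest odd
  span), shrunk at the sequence boundaries rather than padded. All
  statistics are computed on the original signal, so replacements never
  cascade. A window whose MAD is 0 (locally constant signal) flags any
  deviating sample — the limit of the rule. The rolling median uses a C
  median filter; the rolling MAD is exact via chunked sliding windows.
* **Bipolar montage** — default pairs F3-Fz, Fz-F4, F3-C3, F4-C4, C3-P3,
  C4-P4, P3-Pz, Pz-P4: the set of 8 adjacent right-to-left /
  anterior-to-posterior derivations over the 8 electrodes. Polarity is
  recorded in the channel name and is irrelevant downstream (amplitude
  spectra are sign-invariant). The montage is configurable.
* **Highpass** — 4th-order zero-phase Butterworth, default *off*: the
  band definitions already exclude sub-5-Hz content, and the filter is
  provided for time-domain use cases.

## Spectral features

Welch estimates use a 256-point FFT, 50 % overlap, and the periodic
Hamming window (a 1024-sample trial averages 7 windows; 1 Hz resolution).
"Spectral amplitude" is the square root of the Welch power density, then
natural-log transformed with amplitudes floored at 1e-12 so degenerate
(all-zero) segments stay finite; switching to log-power would scale every
feature by 2 and change no rank-based or LDA decision. Band averages are
arithmetic means over bins with lo ≤ f ≤ hi, edges inclusive, which at
integer-Hz bins leaves no orphaned bins between β(…30) and γ(31…).

## HF suppression

Each low-band feature is regressed on the *same channel's* HF feature
(univariate OLS; no cross-channel or cross-band regressors) and replaced by
its residual; HF itself is never modified (an "HF after suppression" is
undefined, and the univariate result tables list 9 band variants: θ, α, β,
γ, HF, θ*, α*, β*, γ*). A constant regressor degenerates to slope 0 /
intercept = feature mean and is flagged in the model.

Because the fit uses no labels, suppression may be performed within any
partition. The default cross-validation mode is `per-partition` — fit and
apply independently within the training and the test fold — with
`fit-on-train` (apply training-fold coefficients to the test fold)
available as an option; the two differ only in how the test-fold
coefficients are estimated, and both are leakage-free.

## Statistics

Spearman correlations are computed trial-wise within participant across all
228 trials with average-rank tie handling; note that with only three
distinct label values, label ties cap |ρ| below 1 even for a feature that
separates the classes perfectly unless the feature shares the tie pattern.
The rank-sum test uses the normal approximation with tie and continuity
correction (76 trials per class); an exact-enumeration mode exists for
small samples. Prevalence is the fraction of participants with p below the
Bonferroni threshold α/72.

## Classification

The discriminant uses the pooled within-class covariance (denominator
n − K) shrunk toward its diagonal: Σ(γ) = (1 − γ)Σ + γ·diag(Σ). This
target preserves per-feature variances while attenuating correlations; at
γ = 1 the classifier reduces to a naive diagonal discriminant. Only this
single shrinkage parameter is regularized — no feature-elimination or
threshold parameter. γ is selected by stratified inner 4-fold CV on the
training partition over the fixed grid {0, 0.05, …, 1.0}, ties broken
toward smaller γ (less regularization at equal evidence); a singular fit at
γ = 0 scores −∞. Outer folds are stratified seeded-random splits; trial
counts not divisible by the fold count are trimmed per class with a
warning. Permutation nulls shuffle the label vector uniformly and rerun the
entire procedure (fold assignment, suppression, shrinkage optimization)
per replicate. Transfer learning trains one model on all-but-one
participant (shrinkage optimized on the pooled training trials) and tests
on the held-out participant.

## Problem sizes

Default test and acceptance runs use: one full default participant
(228 trials) for the permutation-calibration checks (100 replicates per
comparison); 50 seeded sessions for the EMG-confound property; 100 sessions
for Spearman sign recovery and 20 for the comparison-ordering property;
10 participants for the heterogeneity/transfer property; 1000 ball
sequences per level for the task constraint; 1000 random signals for the
Hampel oracle. Sessions for the many-seed properties are generated without
impulse artifacts and skip the Hampel stage (a near-no-op in that regime),
which exercises the identical downstream path at a fraction of the cost;
the Hampel stage runs at full scale in the oracle suite and in the
acceptance script. The confound-only scenario uses an EMG slope of 0.3
with all oscillatory effects zero, so the confound is unambiguously
decodable before suppression.

## What passing tests show — and what they do not

The synthetic generator reproduces the *statistical skeleton* the analysis
relies on: workload-dependent log-amplitude modulation, a broadband EMG
confound correlated with both workload and HF, impulse artifacts, balanced
trial counts, and individual differences. It deliberately omits real-EEG
features such as 1/f slope variation, non-stationarity, eye-blink/ECG
artifacts, electrode drift, volume-conduction correlation structure, and
behavioral errors. Passing tests therefore validate the implementation and
the internal consistency of the method — e.g. that HF suppression removes
an EMG-borne workload signal, or that transfer fails under sign-flipped
physiology — not the real-data effect sizes, which depend on recordings
this package does not ship. A known small artifact: leave-one-participant-
out transfer on a population with random effect signs sits slightly
*below* chance, because the held-out participant's effect is subtracted
from the pooled training average.

## Limitations

* The forward model is additive band-limited noise; no dipole/head model.
* EMG is modeled as a single broadband component with one global workload
  slope; real scalp EMG is multi-source and spatially patterned.
* EDF files can be read (via the optional mne dependency) but not written;
  the native interchange formats are TSV/JSON/NPZ.
* The exact regularization protocol of proprietary rLDA implementations is
  not reproduced; the grid-search shrinkage optimizer documented above is
  used instead.
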