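# cogload

EEG-based cognitive-workload estimation for an interactive VR n-back task.

`cogload` is a tested re-implementation of a passive workload-monitoring
pipeline: participants wearing an 8-channel EEG cap (F3, Fz, F4, C3, C4, P3,
Pz, P4; 256 Hz) under a VR headset sort colored balls in an n-back
working-memory task at three load levels (n = 0, 1, 2), and the pipeline
decodes the load level from spatio-spectral EEG features. Because such
recordings are rarely shareable, the package ships a first-class synthetic
session generator with the statistical structure the analysis assumes, so
every stage is testable end to end without any data download.

It is intended for BCI / neuroergonomics researchers who want a reproducible
reference implementation of this analysis chain, or a controllable testbed
for artifact-suppression and decoding methods.

## The pipeline

1. **Simulation** (`cogload.simulate`) — 3 conditions x 4 runs x 20
   four-second trials per participant. Trial EEG sums band-limited
   oscillations (θ 5–7, α 8–14, β 15–30, γ 31–55 Hz) whose log-amplitudes
   vary linearly with workload per (channel, band) slope, a broadband
   20–110 Hz EMG component co-varying with workload, 1/f background,
   impulse artifacts, and sub-5-Hz movement bursts. Ball sequences respect
   the task constraint of ≥ 2 n-back targets per 20-ball run.
2. **Preprocessing** (`cogload.preprocess`) — Hampel outlier filter
   (1-s centered window; replace a sample deviating from the window median
   by more than 5 robust SDs, robust SD = 1.4826 · MAD); bipolar
   re-referencing over 8 adjacent electrode pairs; optional zero-phase 5 Hz
   highpass; segmentation into 4-s trials with the last trial of each run
   excluded (240 → 228 trials).
3. **Features** (`cogload.features`) — Welch spectra per trial and bipolar
   channel (256-point FFT, 50 % overlap, Hamming), log spectral *amplitude*
   `log √Pxx` averaged over the five bands θ, α, β, γ and HF (70–100 Hz,
   above typical scalp EEG, a scalp-muscle EMG proxy): a 228 × 40 table.
4. **HF suppression** (`cogload.suppression`) — per (channel, band ∈ θ..γ)
   OLS regression of the band amplitude on the same channel's HF amplitude;
   the residual replaces the feature. Removes EMG bleed-through at the risk
   of discarding genuinely task-correlated high-frequency EEG.
5. **Statistics** (`cogload.stats`) — trial-wise Spearman ρ of each feature
   with workload; two-sided Wilcoxon rank-sum between n = 0 and n = 2;
   across-participant prevalence at the Bonferroni threshold
   α / (9 bands × 8 channels) = 0.05/72 ≈ 6.94 × 10⁻⁴; controller-position
   bias check (r² of position vs load).
6. **Classification** (`cogload.classify`) — regularized LDA with shrunk
   pooled covariance Σ(γ) = (1 − γ)Σ + γ·diag(Σ), γ chosen by inner 4-fold
   CV on the training partition (grid 0, 0.05, …, 1; ties to smaller γ);
   stratified 4-fold cross-validation with fold-wise HF suppression;
   100-replicate label-permutation nulls; leave-one-participant-out
   transfer learning.

## Worked example

```python
import numpy as np
from cogload import (SessionSpec, generate_session, hampel_filter, to_bipolar,
                     segment_trials, extract_features, crossval_classify,
                     spearman_feature_correlation)
from cogload.simulate import Recording

spec = SessionSpec(participant_id="P01", seed=42)
recording, controller, sequences = generate_session(spec)

cleaned = np.stack([hampel_filter(ch) for ch in recording.samples])
recording = Recording(cleaned, recording.sampling_rate,
                      recording.channel_labels, recording.markers)
trials = segment_trials(to_bipolar(recording))
features = extract_features(trials, participant_id="P01")

rho, _ = spearman_feature_correlation(features)
low = ("theta", "alpha", "beta", "gamma")
rng = np.random.default_rng(0)
res = crossval_classify(features, "0v2", bands=low, suppression="off", rng=rng)
res_s = crossval_classify(features, "0v2", bands=low,
                          suppression="per-partition", rng=rng)
```

prints, via the obvious `print` statements:

```
markers: 240
trials after last-trial exclusion: 228
feature table: 228 trials x 40 features
Spearman rho  F3-Fz:theta = +0.393   P3-Pz:alpha = -0.465
0 vs 2 accuracy (theta-gamma): 0.901 (chance 0.50); after HF suppression: 0.868
```

Reading: frontal θ amplitude rises and parietal α falls with workload (the
planted fronto-parietal pattern, recovered with the expected signs), and a
linear classifier on the four low-frequency bands separates the extreme
workload levels well above the 50 % chance level, dropping somewhat once
EMG-correlated activity is regressed out.

The same flow is scriptable from the shell:

```bash
cogload run-all --seed 1 --out study/     # full simulated 15-participant study
cogload summarize study/report.json --out study/summary.tsv
```

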