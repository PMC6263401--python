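# engage-fuse

Recognition of cognitive **engagement** (a binary high/low state of
sustained attention during a task) from a *low-density* hybrid sensor set:
two EEG electrodes (Fz, Pz), one ECG lead, and two fNIRS channels (Fp1,
Fp2) — the kind of minimal wireless montage that is practical outside the
lab. The package is aimed at researchers in physiological computing and
passive BCI who want a fully testable, end-to-end reference pipeline:
because no human recordings are distributed with it, a seeded synthetic
session generator with a *known* latent engagement state stands in for the
data, so every stage — labeling, feature extraction, selection,
classification, validation — can be exercised and falsified offline.

## The method

**Auto-labeling from ocular physiology.** Ground truth comes not from
self-report but from two per-window indices measured against a 90-s
neutral baseline:

```
Z_pupil = (μ_baseline − μ_task) / sd_task        (task = one 10-s encoding window)
Z_blink = (μ_baseline − rate_window) / sd_rates  (blinks per window duration)
```

A dilated pupil (`Z_pupil ≤ 0`) and reduced blinking (`Z_blink ≥ 0`) each
score +1, the opposite signs −1. Total > 0 ⇒ **high** engagement, < 0 ⇒
**low**, 0 ⇒ unlabeled (dropped).

**59 multimodal features per window.** Per EEG electrode: Hjorth
activity/mobility/complexity, a Lempel–Ziv (LZ76) Kolmogorov-complexity
proxy, per-band (θ, α, β, γ) maximum PSD and PSD integral, per-band
relative power from a 6-level Daubechies-8 wavelet decomposition, and
normalized spectral entropy (17 × 2 = 34). ECG: Hjorth triple, LZ76,
spectral entropy, heart rate `HR = 60/median(RR)`, and high-frequency
(0.15–0.4 Hz) HRV power (7). NIRS: the Hjorth triple of oxy-, deoxy- and
total-hemoglobin at each site (18).

**Learning stack.** Classes are rebalanced so each carries equal total
instance weight (grand total preserved). Feature subsets `S` (k features)
are scored by the CFS merit

```
M_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)
```

(mean |feature–class| over mean |feature–feature| correlation) and searched
with forward best-first expansion, stopping after five stale expansions.
Classification is k-nearest-neighbor (k = 9, Euclidean on min-max
normalized features) with instance-weighted voting. Validation: contiguous
70/30 per-participant hold-out, stratified 10-fold CV, and
leave-one-participant-out, with a per-class panel of TP/FP rate,
precision, recall, F-measure, ROC area, PRC area and MCC.

## Worked example

`python examples/03_extract_features.py` simulates one participant,
labels the windows from blinks and pupillometry, and extracts the hybrid
feature table:

```
20 windows x 59 features
label                    high      low
eeg_relative_alpha_fz   0.287    0.438
eeg_relative_beta_fz    0.348    0.192
ecg_hr                 78.126   65.395
ecg_hf                 89.821  221.717
nirs_activity_oxy_fp1   1.815    0.292

relative band powers sum to [1.]
```

Engaged windows show the expected physiology: an alpha→beta EEG shift,
faster heart rate with vagal (HF) withdrawal, and larger hemodynamic slow
waves. `python examples/05_full_experiment.py` then runs balancing + CFS +
KNN under 10-fold CV for the hybrid table and each stand-alone modality
and prints the accuracy (mean ± sd over folds) plus the per-class metric
panel. The other examples cover session simulation/IO, labeling, and
feature selection in isolation.

A thin CLI mirrors the stages
(`engage-fuse simulate|label|extract|select|run-all`); see
`engage-fuse --help`.

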