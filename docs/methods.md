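# Methods

This note documents the models, conventions and design choices behind
`engage_fuse`, in the order the pipeline runs them. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic sessions (`engage_fuse.simulate`)

The generator emulates the recording protocol the analysis expects: a
90-s neutral baseline, then `n_trials` encoding windows of 10 s separated
by 4-s answer gaps that are never analysed. A latent binary engagement
state runs over the encoding windows in blocks of geometric length (mean
5 windows — engagement persists across adjacent trials), with a marginal
prior of 0.62 for the engaged state. All randomness flows from one named
generator per (seed, participant), so identical inputs give bit-identical
sessions.

Each state is a `StateProfile`; the baseline and gaps use the elementwise
midpoint of the two profiles, which is what makes the baseline-referenced
sign rules of the labeling stage informative. Streams:

* **EEG (Fz, Pz @ 500 Hz)** — sum of four band-limited unit-variance
  noise carriers (θ 4–8, α 8–13, β 13–30, γ 30–65 Hz), scaled per segment
  so the band-power fractions match the active profile at a total sd of
  20 µV.
* **ECG (@ 500 Hz)** — a Gaussian-bump PQRST template placed at beat
  times; RR = 60/HR plus a 0.3 Hz sinusoid whose variance equals the
  profile's HF power (ms²) plus 4 ms white jitter.
* **EOG (@ 500 Hz)** — blink transients (250–350 µV Gaussian bumps,
  ~±140 ms support) at the profile's Poisson rate with a 0.4-s minimum
  separation, on 10 µV background noise.
* **Pupil (@ 30 or 60 Hz)** — a smoothed (σ = 0.3 s) noise process around
  the profile's mean diameter; every blink blanks ~150 ms of the trace
  (NaN), exercising the labeling stage's gap handling.
* **NIRS (Fp1, Fp2 @ 10.2 Hz)** — a 0.06 Hz slow wave plus per-segment
  linear drift and smoothed noise for oxy-Hb; deoxy-Hb is the inverted,
  attenuated wave; total-Hb is exactly oxy + deoxy at every sample. The
  profile's `noise_sd["nirs"]` scales both the slow-wave amplitude (×2)
  and the noise, so states with different values differ in hemodynamic
  variance (Hjorth activity).

**Default profiles are fiction.** No quantitative effect sizes of
engagement on any of these signals are published for this protocol. The
defaults encode the qualitative physiology — engaged ⇒ α→β/γ shift,
higher heart rate with vagal withdrawal (HF 300 vs 900 ms²), 5 vs 20
blinks/min, 4.4 vs 3.6 mm pupil, larger hemodynamic slow waves — at
magnitudes chosen once to be strongly separable. Passing end-to-end tests
therefore show that the pipeline *recovers a known signal of this form
and finds nothing under the matched null*; they say nothing about effect
sizes, artifacts (motion, ocular contamination of EEG, Mayer waves),
nonstationarity, or inter-subject variability in real recordings.

Sessions round-trip losslessly through a plain-text directory format
(one file per stream with a two-line header, `windows.tsv`, `truth.tsv`;
floats written with 17 significant digits).

## Labeling (`engage_fuse.labeling`)

EOG is linearly detrended and band-passed 0.1–20 Hz (order 4, zero-phase);
blinks are maxima above 50 µV with a 200-ms refractory separation (one
physiological transient is never counted twice). The pupil trace is
linearly interpolated across tracker gaps, low-passed at 4 Hz (pupil
dynamics live below ~2 Hz; the smoothing cut-off is a design choice), and
gap runs longer than 500 ms are excluded from all means.

The Z statistic is `(μ_baseline − μ_task)/sd_task` — baseline-referenced
numerator, *task-period* denominator — implemented verbatim despite the
asymmetry. Per window, the pupil Z uses the window trace's own mean and
sd; the blink Z uses the window's count with the across-window sd of task
rates (a single count has no internal spread), all rates expressed per
window duration. Baseline statistics are computed once per participant
from the 90-s neutral segment. Boundary zeros score +1 for both indices;
a zero total leaves the window unlabeled and it is dropped downstream —
the two indices disagreed.

A consequence worth knowing: on *discrete* blink counts the sign rule is
not symmetric (the median of a Poisson count sits below its mean), so
even the null simulation yields an imbalanced labeled corpus (~60/40
high/low) — an emergent analogue of the published corpus imbalance. The
class balancer exists precisely to absorb this.

## Features (`engage_fuse.features`)

EEG windows are band-passed 0.5–65 Hz (3rd-order Butterworth,
zero-phase). Conventions, where the method's description leaves room:

* **Hjorth mobility** is per-sample (dimensionless):
  `sqrt(var(Δy)/var(y))`; multiply by fs/(2π) for Hz. Constant windows
  raise a degenerate-signal error for mobility/complexity (activity 0).
* **Band powers** come from the 6-level db8 DWT; at 500 Hz the detail
  levels realize the dyadic subbands D6 3.9–7.8 (θ), D5 7.8–15.6 (α), D4
  15.6–31.25 (β), D3 31.25–62.5 Hz (γ) — the nearest dyadic alignment of
  the conventional bands. Band power is the **sum** of squared detail
  coefficients (band energy; the DWT is orthogonal). A per-level *mean*
  would weight narrow low bands by their coarser coefficient grid (8× for
  θ vs γ) and break the relative-power arithmetic. Relative powers share
  one denominator and sum to exactly 1. Tests show the estimator is
  calibrated to ±0.05 on its own dyadic grid; against the nominal edges
  the dyadic alignment carries a structural bias (mean ~+0.06 on α, since
  D5 swallows 13–15.6 Hz), bounded at 0.10 by a periodogram oracle.
* **Max PSD / PSD integral** per band are read off a Welch estimate (2-s
  segments, 50% overlap) over the nominal band edges — they are
  densities, so the spectral estimator is the natural reading.
* **Kolmogorov complexity** is the LZ76 production-history length of the
  median-binarized window, normalized by n/log₂n (~1 for random, →0 for
  periodic). If strict median thresholding degenerates (two-valued
  signals), a ≥ fallback keeps the binarization informative.
* **Spectral entropy** is Shannon entropy of the normalized Welch
  spectrum divided by log(#bins) ∈ [0, 1].
* **R peaks** come from a derivative–square–integrate energy detector
  (band-pass 5–20 Hz, 150-ms integration, adaptive threshold, 250-ms
  refractory), refined to the band-passed waveform maximum. Windows with
  fewer than two R peaks lose their cardiac features and are dropped with
  a warning. `HR = 60/(median RR in s)`; HF power integrates the
  periodogram of the 4-Hz-resampled, detrended tachogram over
  0.15–0.4 Hz (ms²).
* **ECG waveform features** (Hjorth, LZ76, entropy) are computed on the
  0.5–40 Hz filtered waveform, not on the RR series — they sit alongside
  the other waveform descriptors in the feature inventory.
* **NIRS** windows are mean-subtracted and band-passed 0.01–0.5 Hz before
  Hjorth computation, isolating hemodynamics from drift and offset.

All 59 features are invariant to constant offsets of their source
streams (asserted in tests). Stand-alone modality tables reuse the hybrid
extraction's rows by column subsetting, so modality comparisons are
paired on identical windows.

## Learning stack (`engage_fuse.model`)

* **Balancing**: instance of class c gets `N_total/(n_classes·N_c)`;
  per-class totals equalize, the grand total is preserved.
* **CFS correlations** are absolute Pearson, with the class coded {0, 1}
  (point-biserial) — chosen over symmetric uncertainty on discretized
  features to avoid a discretization layer; selected-subset composition
  may differ from implementations that discretize. Correlations are
  computed on the raw training rows; balancing weights enter only the
  classifier's vote. Zero-variance columns are excluded before search.
* **Best-first search** starts from the empty set, expands the
  best-merit unexpanded subset by one feature, and stops after 5
  consecutive expansions that fail to improve the best merit; ties break
  lexicographically, so selection is deterministic.
* **KNN (k = 9)**: min-max normalization to [0, 1] from training bounds
  only; Euclidean distance; all rows tied with the k-th distance are
  included; votes are weighted by instance weight (not by distance — the
  plain-vote reading); a tied vote falls back to the single nearest
  neighbor. The positive-class weighted vote share is the ROC/PRC score.

## Evaluation (`engage_fuse.evaluate`)

Hold-out takes the first `floor(0.7·n)` windows of each participant in
time order (261 → 182/79, matching the protocol description) with the
contiguous remainder as test — respecting serial dependence. K-fold is
stratified by class with a seeded shuffle; LOSOXV leaves one participant
out per split. Balancing and CFS are re-fit inside every training split
(tests assert the selection never sees a test instance), and the selected
features' per-split frequency is reported. Accuracy is reported as mean ±
sd over splits/folds; the per-class panel (TP/FP rate, precision, recall,
F-measure, ROC area by threshold integration, interpolated-precision PRC
area, MCC) is computed from pooled predictions, with NaN + warning when a
single-class truth makes ROC/MCC undefined.

## Problem sizes and numerical choices

The end-to-end suites run at desk scale, chosen once: the separable
corpus uses 11 simulated participants (the emulated protocol's cohort
size) × 95 trials; the null corpus 11 × 60 (identical profiles drop
~half the windows as score-0 ties, and the chance band needs ≥300 labeled
windows to be a ~2σ statement). `scripts/acceptance.py` uses 11 × 60 for
both. The CFS-vs-exhaustive oracle check uses 10-feature tables (2¹⁰
subsets × 50 seeds). Float comparisons in tests use explicit tolerances
noted inline; merit ties and KNN distance ties use 1e-12 slack.

## Known limitations

* Simulator effect sizes are invented; absolute accuracies on synthetic
  corpora (often ~100% under the strongly separable defaults) do not
  transfer to human data, where the corresponding published figure is
  ~72%.
* No artifact model (motion, EMG, optode drift beyond linear), no
  eye-tracker device emulation, no EDF/BDF container support.
* The Pearson-based CFS and plain-vote KNN are one concrete reading of
  the method; implementations built on discretized information measures
  or distance-weighted votes will select and score somewhat differently.
* Score-0 (index-disagreement) windows are dropped; no published count
  adjudicates that choice.
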