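# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic data generator does and does not emulate, and
the interpretation decisions taken where the analysis recipe left room.

## Paradigm and data model

The analysis targets a cue-paced brain-switch experiment with four trial
types — motor imagery of right-hand grasping (MI), sensory-threshold
somatosensory electrical stimulation alone (SES), their combination
(MI_SES), and rest (REST). A trial is a 1 s preparation cue followed by a
4 s task period; in stimulated conditions the stimulator switches on 2 s
into the task; inter-trial intervals are uniform on 3–5 s; each condition
contributes 40 trials (four runs of ten, order randomized within run).
All analysis windows are anchored to the preparation cue: baseline
[−1, −0.2] s, decoding window [1, 5] s, task quantification window [3, 5] s.
The cue-relative anchoring of the printed windows is an interpretation
(the alternative would anchor [3, 5] to task onset); it follows the
time-frequency figure captions, which mark [1, 5] s as the task period.

## Synthetic EEG generator

The generator produces continuous multichannel EEG (µV) on a standard
10-10 montage (35 channels: the 30 fronto-parietal connectivity channels
plus the midline), with:

* **Background**: one pink-noise (1/f) source per electrode, spatially
  mixed by a distance-based Gaussian kernel (row-normalized,
  length scale 4 cm), scaled to 9 µV per channel, plus 1.5 µV white sensor
  noise. Electrode coordinates come from MNE's idealized 10-05 montage.
* **Sensorimotor rhythms**: alpha (10 Hz) and beta (20 Hz) carriers under
  C3 and C4 with Gaussian spatial spread (3 cm). Carriers are
  constant-amplitude phase-diffusion sinusoids (Wiener phase,
  2.5 rad²/s, ≈0.4 Hz linewidth) under a slow log-normal amplitude
  modulation (cutoff 0.05 Hz, σ = 0.15). Because the modulation is
  effectively constant within one trial, a trial's task/baseline power
  ratio equals the squared ERD amplitude factor almost exactly — this is
  what makes closed-form ERSP expectations testable — while the
  trial-to-trial power spread keeps single-trial decoding imperfect, as in
  real subjects.
* **ERD**: a multiplicative envelope on the C3 carriers. MI-type trials
  reduce amplitude by the profile's ERD fraction from task onset; from
  stimulation onset, MI_SES multiplies in an additional gain and SES a
  smaller "attention" reduction. All transitions ramp over 100 ms
  (sensory-threshold stimulation produces no broadband artifact edge).
  Per-trial fractions carry mean-one log-normal jitter whose σ
  (`erd_consistency`) models subjects who cannot hold a stable ERD.
* **Fronto-parietal coupling**: a source pair at F3/P3 with constant total
  power but a condition-dependent phase-coherent fraction; the coherent
  component reaches P3 with a fixed phase lag (default π/2). Constant
  power is deliberate: it makes the connectivity manipulation invisible to
  variance-based decoding (as in the study, where decoding is carried by
  ERD) while the wPLI sees it directly.

### Performer profiles

Defaults were calibrated once so that synthetic cohorts land on the
study's group-level accuracy structure, and then frozen:

| parameter | HIGH | LOW |
| --- | --- | --- |
| alpha ERD fraction (MI) | 0.65 | 0.32 |
| beta ERD fraction (MI) | 0.45 | 0.18 |
| ERD consistency σ | 0.15 | 0.45 |
| st-SES ERD gain (MI_SES) | 0.0 | 0.50 |
| SES attention ERD | 0.35 | 0.15 |
| coupling band / strongest condition | beta / MI | alpha / MI_SES |

With these defaults the 10+10 cohort pipeline yields group mean accuracies
near 0.90 (High, MI:Rest) and 0.67–0.71 (Low), with the Low group gaining
and the High group not gaining from stimulation — the qualitative pattern
the analyses are meant to detect. The SES attention component is a free
parameter (nothing in the underlying experiment pins its spatial extent or
size); it is deliberately independent of the MI_SES gain so that a profile
can show stimulation-evoked ERD without any MI_SES benefit.

### What the generator does not emulate

No ocular/EMG artifacts (the optional pluggable artifact-removal stage is
a no-op on synthetic data), no realistic forward head model (spatial
structure is a smooth kernel, not a lead field), no stimulation-current
artifacts, no non-stationarities beyond the slow amplitude modulation, and
no inter-subject variability beyond profile jitter. Passing tests
demonstrate that the estimators recover what the generator injects under
realistic noise; they do not certify performance on real EEG with
artifacts and volume conduction from a true head model.

## Preprocessing

Two branches, as in the study design: decoding (8–28 Hz band-pass,
resample to 250 Hz) and analysis (0.5–100 Hz band-pass, 50 Hz notch,
resample to 250 Hz, Hjorth surface Laplacian, peak-to-peak trial
rejection).

* Band-pass: Butterworth order 8 in second-order sections, applied
  forward-backward (zero phase). Order 8 is used because the
  forward-backward pass must keep passband sines within 1% at 10 Hz for
  the 8–28 Hz band; order 4 droops 2% there.
* Notch: linear-phase FIR (~2 s kernel), applied as a centered
  convolution, which is zero-phase for a symmetric kernel.
* Resampling: polyphase (`resample_poly`) after filtering.
* Laplacian: Hjorth scheme, each channel minus the mean of its k = 4
  nearest neighbours by Euclidean distance on the template montage. The
  variant is unspecified in the underlying recipe; Hjorth is the minimal
  published scheme.
* Trial rejection: automatic peak-to-peak threshold (default 150 µV) as a
  deterministic surrogate for visual inspection.
* The analysis-branch epoch window is [−2, 5.5] s so that every 256-sample
  STFT window centred in the baseline or task interval lies fully inside
  the epoch.

## Decoding

Per-trial covariances are trace-normalized before class averaging
(standard CSP practice; equalizes trial power). The joint diagonalization
is solved by whitening the composite covariance and eigendecomposing the
whitened class-A covariance — numerically stabler than a direct
generalized eigenproblem; a test enforces equivalence with the direct
solution to |cos| > 1 − 1e−6 per component on random SPD pairs.
Features are z-scored with training-fold statistics before the SVM
(unstated in the recipe; standard and leakage-safe). CSP is refit inside
every leave-one-out fold — the leakage-free reading of the evaluation
scheme. The fold plan pairs trials randomly (seeded); with unequal counts
after rejection, min(n_A, n_B) pairs are formed and surplus trials join
every training set. Inside the fold loop, log-variance features are
computed as log(w′Σw) from cached per-trial covariances, which is
numerically identical to projecting the raw trials and ~50× faster; a test
pins the equivalence against naive refitting.

A note on calibration: leave-one-out folds share training data, so fold
outcomes are positively correlated and cohort-level accuracy is
overdispersed relative to a Binomial(80, ½): empirically SD ≈ 0.08 across
null cohorts versus 0.056 binomial. Calibration is therefore asserted on
the mean accuracy across 50 null cohorts (which sits well inside the 99%
binomial band), not on pooled fold counts.

## ERSP and r²

STFT with Hanning taper, 256-sample windows, 25-sample hop (0.1 s at
250 Hz; only the window length is prescribed by the recipe). Power is
averaged over trials per (frequency, time) bin, converted to dB, and the
mean baseline-window dB value per frequency is subtracted (additive
baseline in dB = power ratio, the convention of the originating toolbox).
Edge bins whose window crosses the epoch boundary are computed on
zero-padded data, flagged, and excluded from band averages and from the
baseline mean. r² uses power (squared magnitude), consistent with the
squared-spectra definition of ERSP; per-bin squared point-biserial
correlations are averaged over the band × window box.

## Sample entropy

Richman–Moorman estimator: template pairs i ≠ j with both start indices in
1..N−m (so the length-(m+1) template exists for every counted index),
Chebyshev distance, self-matches excluded. The printed per-template
normalizations 1/(N−m) and 1/(N−m−1) cancel in the ratio B_{m+1}/B_m and
are not materialized. Tolerance r = g·SD is computed per analysis window
on the band-limited series (the series actually being measured — the
alternative, a whole-epoch SD, is a one-line change). B_{m+1} = 0 yields
+∞ with a warning and the trial is dropped from condition means; B_m = 0
raises. An exhaustive enumeration oracle pins the counts exactly.

## wPLI and permutation testing

Observations for the wPLI expectation are (trial × in-band frequency bin)
cross-spectral estimates from one Hanning-tapered Fourier transform per
trial over the stated window — the repetition convention of the
originating toolbox. The estimator is the unsigned wPLI (not
debiased-squared). Denominators below machine tolerance (a genuinely
zero-lag pair) report 0 with a degeneracy flag. Baseline z-normalization
needs a baseline spread, which a single window cannot provide; it is
estimated by bootstrap resampling of trials within the baseline window
(100 resamples, seeded) — the minimal added assumption.

Edge significance permutes trial condition labels and recomputes the wPLI
difference (2000 permutations by default; p = (1 + #{|d*| ≥ |d|})/(1 + n));
a per-trial decomposition of wPLI does not exist, so a trial-level
t-statistic is not defined and the difference itself is the exchangeable
statistic. A subject-level mode (`paired_t_permutation`) uses the paired
t-statistic over subjects with sign-flip permutations. Neither is claimed
to be the exact original procedure, which did not specify its permutation
unit. Multiple comparisons across the 435 pairs are handled only by the
fixed 0.005 threshold, matching the original analysis.

## Group statistics

The Shapiro–Wilk gate (α = 0.05) is applied to both samples *and* their
paired differences, choosing the non-parametric test if any check fails —
the conservative reading of "only if normality was satisfied". The
repeated-measures ANOVA applies Greenhouse–Geisser correction when
Mauchly's test rejects sphericity (the fractional degrees of freedom in
the original report imply such a correction). Degenerate inputs (all-zero
paired differences; identical condition columns) raise or return F = 0,
p = 1 explicitly rather than propagating NaNs.

## Problem sizes and runtime choices

Simulations for tests and the acceptance script run at 250 Hz (any
positive multiple of 250 Hz is supported; 1000 Hz is the recording-rate
default) with the full 40-trials-per-condition paradigm; condition subsets
(e.g. MI/REST only) are used where an experiment only addresses those
conditions. The pipeline's per-edge permutation count defaults to 400 in
cohort runs (resolution 1/401 ≈ 0.0025 < 0.005) and 2000 in the dedicated
type-I-error calibration. These sizes were chosen so a full cohort
analysis completes in minutes on one CPU core.

## Known limitations

* The EDF writer emits plain EDF (not EDF+ annotations); events travel in
  a TSV sidecar. The final data record is zero-padded to a whole second.
* Band-averaged null ERSP at a single channel over 40 trials has sampling
  noise of roughly 0.15–0.2 dB; null checks at that scale are meaningful
  for map-level averages and for fixed seeds, not for arbitrary single
  boxes.
* Group statistics on synthetic cohorts validate calibration and
  direction-of-effect only; the original subject-level values are not
  public, so no numerical group statistic can be compared directly.
* ICA-based artifact removal is exposed as a pluggable hook but is not
  exercised by the synthetic data, which contains no ocular/EMG artifacts.
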