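# mises

EEG analysis of motor imagery (MI) under sensory-threshold somatosensory
electrical stimulation (st-SES), built for brain–computer interface (BCI)
research on why peripheral stimulation helps some users and not others.
The package implements the complete analysis chain used to compare
high- and low-performing MI-BCI users across four conditions (MI, SES,
MI-SES, Rest), together with a synthetic EEG generator that emulates the
paradigm, so every stage is testable without access to raw recordings.

## What it computes

- **Brain-switch decoding** — common spatial patterns (CSP) spatial
  filtering with log-variance features of the first and last four
  components, classified by a linear SVM (C = 1). CSP solves the joint
  diagonalization of the two class-mean covariances: filters `w` maximize
  `w'C_A w / w'(C_A + C_B)w`; features are `log(w' Σ_trial w)`. Accuracy is
  estimated by a paired leave-one-out scheme (forty sets, one trial per
  class; CSP, scaler and SVM refit per fold) over the 8–28 Hz band and the
  cue-relative 1–5 s window. Users above 80% MI-vs-Rest accuracy are
  stratified as High performers.
- **ERSP / ERD** — event-related spectral perturbation
  `ERSP(f,t) = (1/n) Σ_k |F_k(f,t)|²` from Hanning-tapered STFTs (256-sample
  windows), in dB relative to the −1…−0.2 s pre-cue baseline, band-averaged
  over alpha (8–13 Hz) and beta (14–28 Hz) in the 3–5 s task window at C3;
  plus per-channel r² (squared point-biserial correlation between class
  labels and single-trial spectral power) discriminability topographies.
- **Sample entropy** — `SampEn(x, m, r) = −ln(B_{m+1}/B_m)` with Chebyshev
  template matching, m = 2, r = 0.1·SD, self-matches excluded; reported as
  the relative change of the 3–5 s task window versus the pre-cue baseline
  on the 8–28 Hz band-limited C3 series.
- **wPLI connectivity** — weighted phase lag index
  `|E[imag(S_xy)]| / E[|imag(S_xy)|]` over trials × in-band frequency bins
  for the 30 fronto-parietal channels (F1–F6, FC1–FC6, C1–C6, CP1–CP6,
  P1–P6), z-normalized against a bootstrap of the baseline window, with
  trial-permutation significance at p < 0.005 per edge.
- **Group statistics** — Shapiro–Wilk-gated paired t / Wilcoxon tests,
  one-way repeated-measures ANOVA with Greenhouse–Geisser correction and
  Bonferroni post-hocs.
- **Synthetic cohorts** — multi-subject EEG with lateralized alpha/beta ERD
  at C3, an st-SES ERD gain switching on 2 s into the task, a phase-lagged
  fronto-parietal coupled source, pink-noise background, and distinct
  high-/low-performer effect profiles; written as EDF + TSV events or used
  in memory.

## Worked example

```python
from mises import (simulate_subject, low_performer_profile,
                   preprocess_decoding, preprocess_analysis, loo_accuracy,
                   stratify_performers, ersp, band_average, relative_sampen)
from mises.spectral import ALPHA_BAND

record, events = simulate_subject(low_performer_profile(), fs=250.0, seed=3)

dec = preprocess_decoding(record, events)          # 8-28 Hz branch
acc_mi, _ = loo_accuracy(dec.select("MI"), dec.select("REST"), seed=3)
acc_mises, _ = loo_accuracy(dec.select("MI_SES"), dec.select("SES"), seed=3)
print(f"MI vs Rest accuracy:       {acc_mi:.3f}  -> {stratify_performers(acc_mi)} performer")
print(f"MI-SES vs SES accuracy:    {acc_mises:.3f}")

ana = preprocess_analysis(record, events)          # 0.5-100 Hz + Laplacian
for cond in ("MI", "MI_SES"):
    tf = ersp(ana, condition=cond, channels=["C3"])
    db = band_average(tf, ALPHA_BAND, (3.0, 5.0), "C3")
    _, rs = relative_sampen(ana, cond)
    print(f"{cond:7s} C3 alpha ERSP {db:+.2f} dB   relative SampEn {rs:+.3f}")
```

prints

```
MI vs Rest accuracy:       0.775  -> LOW performer
MI-SES vs SES accuracy:    0.812
MI      C3 alpha ERSP -2.78 dB   relative SampEn +0.082
MI_SES  C3 alpha ERSP -5.83 dB   relative SampEn +0.108
```

This low-performer subject decodes better when stimulation accompanies
imagery (0.812 vs 0.775), shows a deeper alpha desynchronization at the
contralateral motor cortex under MI-SES (−5.83 vs −2.78 dB), and a larger
task-related rise in signal irregularity — the pattern the analysis chain
is designed to expose.

A command-line interface mirrors the stages:

```
mises simulate --profile low --seed 3 --out subj.edf
mises preprocess subj.edf subj_events.tsv --out subj.h5
mises decode subj.h5 --pair MI:REST
mises report --seed 0 --out report.json       # full 20-subject pipeline
```

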