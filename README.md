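# pulsescreen

Contact-free screening for major depressive disorder (MDD) from facial
video.  An ordinary web camera (30 frames/s, 256 tones per channel) records
a subject through a three-period protocol — pre-rest (140 s), a
random-number-generation mental task (100 s), post-rest (120 s).  Arterial
pulsation modulates the green channel of a landmark-defined facial region
of interest; from that trace the package extracts a blood-volume-pulse
(BVP) signal, beat-to-beat intervals, task-evoked heart-rate-variability
(HRV) features, and a logistic screening decision.  A reference single-lead
ECG channel supports agreement validation, and a synthetic-session
simulator makes every stage testable without clinical recordings.

## Method

1. **ROI green trace** — face detection, motion tracking, three smoothed
   landmarks (left cheek A, right cheek B, chin-top C) spanning a rectangle
   over facial-artery territory; the per-frame green mean is the raw signal.
2. **BVP extraction** — shift-invariant wavelet multiresolution analysis
   (order-4 symlet, level 4), summing the components overlapping the
   cardiac band, followed by a zero-phase 4th-order Butterworth band-pass
   at 0.6–2.0 Hz.
3. **Beats** — adaptive-elevation peak detection with parabolic sub-frame
   refinement (30 fps would otherwise quantize intervals to 33 ms), then
   artifact rejection (intervals outside 300–2000 ms or >30% off the local
   median are excluded).
4. **HRV features** — per period, Welch spectra of the 4 Hz-resampled
   interbeat intervals give the band powers LF (0.04–0.15 Hz) and
   HF (0.15–0.4 Hz) in ms²; the candidate vector holds LF, HF, LF/HF for
   the three periods plus percent changes %ΔX₍A⇒B₎ = 100·(X_B − X_A)/X_A
   for the Pre-R⇒MT and MT⇒Post-R transitions — 15 features in all.
   A healthy autonomic system suppresses HF (parasympathetic activity)
   during the task; a flat HF response is the depressive signature.
5. **Screening** — minimum-redundancy-maximum-relevance (MRMR) ranking,
   cross-validated model-size selection, and an unpenalized logistic model

   ```
   logit = log p/(1−p) = β₀ + β₁x₁ + … + β_m x_m,   logit ≥ 0 ⇒ suspected MDD.
   ```

   The shipped published model is the fitted four-variable equation

   ```
   logit = −1.2895 + 0.0013·HF_MT + 0.0051·%ΔLF(Pre-R⇒MT)
           − 0.0001·%ΔHF(Pre-R⇒MT) − 0.0004·%ΔHF(MT⇒Post-R)
   ```

6. **Agreement** — Pan-Tompkins-style ECG R-peak detection, nearest-
   neighbor beat pairing (the ~120 ms pulse transit time to the face
   cancels in interval differencing), Pearson r, RMSE, and Bland–Altman
   limits of agreement (bias ± 1.96 σ).

## Worked example

Cross-validated screening on a simulated cohort with the clinical group
sizes (26 depressive, 27 healthy):

```sh
$ python examples/04_screen_cohort.py
subjects: 53, selected model size k* = 3
accuracy vs k: [0.718 0.755 0.793 0.793 0.774]
confusion (tp fp / fn tn): 21 6 / 5 21
sensitivity = 0.81, specificity = 0.78, PPV = 0.78, NPV = 0.81
AUC = 0.88, Youden-optimal cutoff = -0.14
```

21 of 26 depressive and 21 of 27 healthy subjects are classified correctly
out-of-fold; `accuracy vs k` is the mean of the four proportions as the
model grows along the MRMR ranking, and the cutoff is the logit threshold
maximizing Youden's J.  Camera-vs-ECG agreement on one session
(`examples/05_validate_against_ecg.py`) prints r = 0.998, RMSE = 3.2 ms and
Bland–Altman limits of ±6.3 ms for a clean low-noise recording; with
default sensor noise the CLI `validate` command reports r ≈ 0.97.

The other examples cover session simulation (`01`), pulse/IBI extraction
(`02`), and ROI recovery from rendered frames (`03`).  The same
functionality is available from a shell via the `pulsescreen` CLI
(`simulate`, `simulate-cohort`, `extract`, `bvp`, `features`, `score`,
`cohort-eval`, `validate`).

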