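# Methods

## The screening problem

Task-evoked autonomic responses separate depressive from healthy subjects
better than resting-state heart-rate variability (HRV), which varies widely
between individuals.  During a demanding mental task a healthy autonomic
system withdraws parasympathetic drive, visible as a drop in the
high-frequency (HF, 0.15–0.4 Hz) HRV band power; depressive subjects tend
to respond flatly.  `pulsescreen` measures this response without contact
sensors: remote photoplethysmography (rPPG) reads the cardiac pulse from
the green channel of a facial region of interest in ordinary web-camera
video, and a logistic model on task-evoked spectral features produces a
screening label.

## Signal model and pipeline

**ROI trace.**  Pixel coordinates are 0-based, origin top-left, boxes
half-open.  The face is detected on the first frame and tracked by
centroid displacement; landmarks A (left cheek), B (right cheek) and
C (chin-top) are placed at fixed fractions of the tracked box, smoothed by
a centered moving average of `round(0.3 s × fps)` taps forced odd (9 at
30 fps, shrinking symmetrically at the edges), and define a rectangle from
A.x–B.x and min(A.y, B.y)–C.y inset 5% per side.  The inset avoids
background bleed at the ROI edge and is configuration, not anatomy.  All
ROI pixels are averaged per channel; only the green mean feeds the pulse
path.  Frames where the face is lost are linearly interpolated when the
gap is at most 1 s, otherwise the session is rejected — longer gaps corrupt
the HRV spectrum rather than merely one beat.

Face detection, tracking and landmarking are pluggable backends.  The
shipped backends operate on synthetic renderings (uniform background, face
ellipse); production deployments would wire a Haar-cascade detector, a
median-flow tracker and a learned landmark model behind the same
protocols.  No detector models are bundled or trained here.

**BVP extraction.**  The green trace is inverted (systolic inflow absorbs
green, so a beat is a luminance dip), decomposed with an undecimated
wavelet multiresolution analysis (order-4 symlet, level 4, reflection
padding; implemented on PyWavelets' shift-invariant SWT-based MRA, whose
components sum exactly to the input), and the components whose octave
bands intersect 0.6–2.0 Hz are summed — at 30 Hz these are D3
(1.875–3.75 Hz), D4 (0.9375–1.875 Hz) and the level-4 approximation.  A
zero-phase band-pass then applies the exact magnitude response of a
4th-order Butterworth at 0.6–2.0 Hz in the frequency domain (reflection
padding against wrap-around).  The frequency-domain form was chosen
deliberately: running an order-2 section through `filtfilt` squares the
magnitude response and pushes the composite below −3 dB at 1.9 Hz,
violating the passband contract the pipeline is designed to meet (unity
±3 dB across 0.7–1.9 Hz, ≥20 dB attenuation at 0.2 and 4 Hz).  The
composite is linear and deterministic.

**Beat detection.**  A 0.75 s moving-average baseline is raised by an
elevation drawn from {5, 10, …, 50}% of the signal range; each contiguous
supra-threshold region contributes its maximum as one peak.  The elevation
minimizing the interbeat-interval (IBI) standard deviation, subject to an
implied mean heart rate within 40–180 bpm, wins; ties go to the lower
elevation.  Peaks are refined by a 3-point parabolic fit, giving sub-frame
timing (a raw 30 fps grid quantizes IBI to 33 ms, which would dominate the
agreement error budget).  If the best candidate's relative IBI spread
exceeds 0.30 the signal is declared non-pulsatile: clean pulse traces sit
near 0.1 while band-limited noise sits near 0.5, so the gate separates the
two regimes with margin on both sides.

**IBI cleaning.**  Intervals outside 300–2000 ms, or deviating more than
30% from the median of their 11 nearest accepted neighbors, are rejected
(never interpolated).  The relative rule iterates to a fixed point, which
makes cleaning idempotent.  Sessions with more than 20% rejections warn;
more than 50% aborts.  These thresholds follow common HRV-artifact
practice and are configurable.

**HRV features.**  Intervals are assigned to the protocol period
containing their ending beat (half-open boundaries; an interval ending
exactly at the Pre-R/MT boundary belongs to MT).  Each period needs at
least 20 accepted intervals.  Accepted (time, IBI) samples are
cubic-spline resampled to 4 Hz, mean-removed, and Welch-estimated (Hann
window, segments of at most 240 samples = 60 s, 50% overlap) — a standard,
well-conditioned estimator for 100–140 s segments; the estimator choice is
config-switchable in principle but Welch is the default and the only one
shipped.  Band powers are trapezoidal integrals of the density over the
half-open bands LF [0.04, 0.15) and HF [0.15, 0.4) Hz, in ms²; 0.15 Hz
belongs to HF only.  Percent changes use the earlier period as the
denominator: %ΔX₍A⇒B₎ = 100 (X_B − X_A)/X_A; a zero denominator raises an
explicit error.  The feature order is the nine period values (LF, HF,
LF/HF × Pre-R, MT, Post-R) followed by the six deltas (Pre-R⇒MT triple,
then MT⇒Post-R triple).

**Screening.**  MRMR uses the greedy quotient scheme — first pick maximal
relevance MI(f; label), then maximal MI(f; label) / (mean MI(f; selected)
+ 1e−12) — with mutual information on equal-frequency quartile bins; ties
break by higher relevance, then input order; constant features are
excluded with a warning.  Logistic fitting is plain maximum likelihood via
IRLS (tolerance 1e−8 on the largest coefficient update, 100 iterations
cap); a coefficient magnitude exceeding 50 during iteration is reported as
complete separation rather than silent divergence.  Model size is the
smallest k maximizing 5-fold stratified cross-validated accuracy (mean of
sensitivity, specificity, PPV, NPV) along the MRMR ranking, with k capped
by the ten-observations-per-predictor rule of thumb (n // 10); a k whose
folds separate is marked ineligible rather than aborting the sweep.  CV
metrics come from the single pooled out-of-fold confusion matrix at logit
cutoff 0 (≥ 0 ⇒ suspected, taking the boundary literally).  ROC AUC is the
trapezoidal area (equal to the tie-corrected concordance probability);
the optimal cutoff maximizes Youden's J, lowest threshold on ties.  The
shipped published model carries the fixed four-variable equation with
intercept −1.2895 and coefficients (0.0013, 0.0051, −0.0001, −0.0004) over
(HF_MT [ms²], %ΔLF₍Pre-R⇒MT₎, %ΔHF₍Pre-R⇒MT₎, %ΔHF₍MT⇒Post-R₎); HF_MT is
taken to be in ms², inferred from the coefficient magnitude.

**Agreement.**  ECG R peaks: 5–15 Hz band-pass, squared derivative, 150 ms
moving-window integration, refractory-spaced candidate peaks thresholded
at 30% of their 90th-percentile height (scale-invariant), apex refinement
on the raw signal with a parabolic sub-sample fit.  Beats are paired
nearest-neighbor within 500 ms — wide enough for the ~120 ms pulse transit
time plus jitter — one-to-one, and only strictly consecutive matched
intervals are compared, so a constant camera-side delay cancels.  Limits
of agreement use the n−1 sample SD and exactly 1.96.  (A published
Bland–Altman interval whose half-range is about half of 1.96 σ for the
stated σ exists in this literature; the standard definition is implemented
and no attempt is made to reproduce that inconsistency.)

## The synthetic-session generator

No public recordings of this protocol exist, so the generator defines the
study conditions.  Beats come from an integral pulse frequency modulation
(IPFM) model: the instantaneous rate r(t) = (mean_hr/60)(1 + m(t)) is
integrated on a 64 Hz grid and a beat fires at each integer crossing
(linear interpolation between grid points).  The modulation m(t) is a sum
of an LF sinusoid (0.10 Hz) and an HF sinusoid (0.25 Hz) with
period-specific amplitudes, plus Gaussian noise smoothed over 0.25 s and
rescaled to `noise_sd` (default 0.02).  |m| ≥ 1 is rejected.  IPFM is the
standard HRV simulation mechanism because its spectral content is
analytically controllable: with zero modulation the IBI is exactly
60000/mean_hr ms, and HF band power scales with the squared modulation
amplitude.

Default period amplitudes (Pre-R, MT, Post-R): LF (0.05, 0.07, 0.05) for
both groups; HF (0.08, 0.02, 0.08) for healthy — the task suppresses
parasympathetic modulation — and (0.05, 0.05, 0.05) for the depressive
profile.  These produce the qualitative group contrast (healthy
%ΔHF₍Pre-R⇒MT₎ ≈ −90%, depressive ≈ 0%) while keeping |m| well below 1.
No quantitative clinical effect size is available for the healthy HF
reduction; the values are tunable configuration, not measurements.

The reference ECG places a narrow positive Gaussian (σ = 8 ms, ~20 ms
wide) at each beat on a flat baseline — morphology is irrelevant since
only R-peak times are consumed.  The RGB trace puts a Gaussian systolic
waveform (σ = 0.11 s) peaking 120 ms after each beat, subtracted from the
green baseline with amplitude 1.5 tones, plus slow sinusoidal drift
(0.03/0.07 Hz, 2 tones) and white sensor noise (0.2 tones) on all
channels.  Rendered frames are 320×180 (desk-scale, not 1920×1080; fps
stays 30): a face ellipse carrying the quantized trace values on a uniform
background, optionally swaying sinusoidally.

Cohorts draw Zung SDS scores from truncated normals — healthy N(33, 5)
below the cutoff 48, depressive N(53, 5) at or above it — anchored to the
reported clinical group means.  Per-subject heterogeneity: lognormal
jitter (σ = 0.3) on every modulation amplitude, mean HR ~ N(70, 8) clipped
to [55, 95] bpm, and a minority of atypical responders (15% of healthy
with blunted task suppression, 20% of depressive with partial
suppression).  The atypical fractions were chosen once to emulate the
imperfect separability seen clinically (sensitivity/specificity in the
70–85% range) rather than a perfectly separable toy problem; they also
keep logistic fits away from complete separation in small folds.

**What the generator does not emulate:** realistic skin optics, lighting
changes, respiration-driven amplitude modulation of the pulse waveform,
arrhythmias, large sudden movements, or the true covariance between
symptom severity and autonomic response within groups (SDS is linked to
the profile only through group membership).  Passing tests therefore
demonstrate internal consistency of the pipeline under the stated
autonomic model — not clinical performance on real faces.

## Problem sizes and numerical choices

Tests and the cohort evaluation run sessions at trace level (signal path
only; frames are rendered only in the ROI tests, at 320×180 for ≤ 600
frames).  The cohort analogue uses the clinical group sizes (26 + 27) over
20 seeds, chosen as a balance between Monte-Carlo stability of the median
and a suite that runs comfortably on one CPU.  "Clean session" fixtures
use sensor noise 0.05 tones (good lighting); the cohort generator keeps
the default 0.2.  IPFM integrates on a 64 Hz grid — timing error from
linear interpolation is far below the 33 ms camera frame and the 10 ms ECG
sample.  Welch mean-removal precedes windowing; spectra are in ms²/Hz.
Band integrals interpolate the density onto the band edges so adjacent
bands tile exactly.  The IRLS weight floor is 1e−10; ROC thresholds
descend, so tie-breaking "lowest threshold" takes the last argmax.

## Known limitations

- The shipped detector/tracker backends only understand the synthetic
  renderings; real-video use requires plugging in production backends.
- The published model's coefficients are fixed constants from the original
  clinical fit; they cannot be re-derived here because the underlying
  recordings are not available, and the cohort metrics in this package are
  simulator-calibrated analogues, not reproductions of clinical accuracy.
- Welch on spline-resampled IBI slightly smears spectral peaks at period
  boundaries; segments shorter than ~80 s give noisy HF estimates.
- The peak detector assumes a single dominant pulse per cardiac cycle;
  dicrotic or arrhythmic waveforms are out of scope.
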