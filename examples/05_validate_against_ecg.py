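"""Camera-vs-ECG agreement on a simulated session.

Synthesizes a session with a simultaneous 100 Hz reference ECG, detects R
peaks (Pan-Tompkins style) and camera pulse peaks independently, pairs the
beats and reports Pearson r, RMSE and Bland-Altman limits of agreement.
"""

import numpy as np

from pulsescreen.agreement import agreement_stats, detect_r_peaks, pair_beats
from pulsescreen.bvp import detect_pulse_peaks, extract_bvp
from pulsescreen.synthetic import generate_cohort, simulate_session

subject = generate_cohort(n_mdd=0, n_healthy=1, seed=0)[0]
session = simulate_session(subject, trace_noise_sd=0.05)

ecg_beats = detect_r_peaks(session.ecg)
cam_beats = detect_pulse_peaks(extract_bvp(session.rgb_trace))
cam, ref, match_rate = pair_beats(cam_beats, ecg_beats)
s = agreement_stats(cam, ref)

print(f"ECG beats: {len(ecg_beats)}, camera beats: {len(cam_beats)}, "
      f"match rate {match_rate:.1%}")
print(f"IBI agreement: r = {s.r:.3f} (p = {s.p_value:.2g}), "
      f"RMSE = {s.rmse:.1f} ms")
print(f"Bland-Altman: bias = {s.bias:.2f} ms, "
      f"limits [{s.loa_low:.1f}, {s.loa_high:.1f}] ms (sigma = {s.sd_diff:.1f})")
print("\nThe ~120 ms pulse transit time cancels in interval differencing, so")
print("the bias stays near zero even though the camera pulse lags the R wave.")
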