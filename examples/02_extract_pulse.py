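"""Extract the blood-volume pulse and interbeat intervals from a trace.

Builds a clean synthetic session at 60 bpm, runs the wavelet + band-pass
BVP extraction and the adaptive peak detector, and compares the recovered
interbeat intervals with the generator's ground truth.
"""

import numpy as np

from pulsescreen import AutonomicProfile, generate_beats
from pulsescreen.agreement import agreement_stats, pair_beats
from pulsescreen.bvp import clean_ibi, compute_ibi, detect_pulse_peaks, extract_bvp
from pulsescreen.hrv import ProtocolConfig
from pulsescreen.synthetic import synthesize_rgb_trace

protocol = ProtocolConfig()
profile = AutonomicProfile(mean_hr=60.0)
beats = generate_beats(profile, protocol, seed=0)
trace = synthesize_rgb_trace(beats, duration_s=protocol.total_s,
                             noise_sd=0.05, seed=1)

bvp = extract_bvp(trace)
detected = detect_pulse_peaks(bvp)
ibi = clean_ibi(compute_ibi(detected))
print(f"true beats: {len(beats)}, detected: {len(detected)}")
print(f"mean HR: {60.0 / (np.mean(ibi.ibi_ms) / 1000.0):.1f} bpm "
      f"(rejected intervals: {ibi.rejection_fraction:.1%})")

cam, ref, match_rate = pair_beats(detected, beats)
stats = agreement_stats(cam, ref)
print(f"camera vs truth IBI: r = {stats.r:.3f}, "
      f"MAE = {np.mean(np.abs(cam - ref)):.1f} ms, "
      f"match rate = {match_rate:.1%}")
print("\nr near 1 and a few-ms error show the 30 fps camera trace preserves")
print("beat-to-beat timing after sub-frame peak refinement.")
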