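"""Recover the green trace from rendered frames with a moving face.

Renders a short pulsatile session as 320x180 frames whose face ellipse
sways sideways, then runs detection, tracking, landmark smoothing and ROI
averaging to recover the per-frame green mean.
"""

import numpy as np

from pulsescreen.synthetic import FaceGeometry, render_frames, synthesize_rgb_trace
from pulsescreen.video_roi import frames_to_trace

beats = np.arange(0.5, 19.5, 1.0)
generated = synthesize_rgb_trace(beats, duration_s=20.0, pulse_amp=5.0,
                                 noise_sd=0.0, seed=5)
stream = render_frames(generated, FaceGeometry(), motion_amp_px=5.0)
recovered = frames_to_trace(stream)

r = np.corrcoef(recovered.g, generated.g)[0, 1]
print(f"frames: {stream.n_frames} at {stream.fps:.0f} fps, "
      f"{stream.width}x{stream.height}")
print(f"recovered vs generated green trace: r = {r:.4f}, "
      f"max abs error = {np.abs(recovered.g - generated.g).max():.2f} tones")
print("\nTracking keeps the ROI on the face, so the recovered trace matches")
print("the generator up to 256-tone quantization.")
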