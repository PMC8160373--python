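import numpy as np
import pytest

from pulsescreen.bvp import compute_ibi, detect_pulse_peaks, extract_bvp
from pulsescreen.hrv import ProtocolConfig
from pulsescreen.synthetic import (
    AutonomicProfile,
    generate_beats,
    synthesize_rgb_trace,
)


@pytest.fixture(scope="session")
def protocol():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def quiet_profile_60():
    """60 bpm, no modulation, no noise: metronome heart."""
    return AutonomicProfile(
        mean_hr=60.0,
        lf_amp_per_period=(0.0, 0.0, 0.0),
        hf_amp_per_period=(0.0, 0.0, 0.0),
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def healthy_profile_60():
    """60 bpm with the default healthy task-suppressed HF response."""
    return AutonomicProfile(mean_hr=60.0)


@pytest.fixture(scope="session")
def clean_session_60(healthy_profile_60, protocol):
    """One clean modulated session at 60 bpm, seed 0: ground-truth beats,
    the camera trace, and the pipeline-detected beat times.  'Clean' means
    no motion artifacts and low sensor noise (good lighting)."""
    beats = generate_beats(healthy_profile_60, protocol, seed=0)
    trace = synthesize_rgb_trace(
        beats, duration_s=protocol.total_s, noise_sd=0.05, seed=1
    )
    detected = detect_pulse_peaks(extract_bvp(trace))
    return {"beats": beats, "trace": trace, "detected": detected}


@pytest.fixture(scope="session")
def metronome_ibi(quiet_profile_60, protocol):
    return compute_ibi(generate_beats(quiet_profile_60, protocol, seed=0))
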