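"""Synthetic screening sessions with controllable autonomic structure.

No public recordings exist for this kind of protocol, so every downstream
stage is exercised on simulated sessions built from an integral pulse
frequency modulation (IPFM) beat generator: the instantaneous cardiac rate

    r(t) = (mean_hr / 60) * (1 + m(t)),
    m(t) = a_LF(period(t)) sin(2 pi f_LF t)
         + a_HF(period(t)) sin(2 pi f_HF t) + noise(t),

is integrated, and a beat fires each time the integral crosses an integer.
Period-specific modulation amplitudes encode the task-evoked autonomic
response: healthy profiles suppress the HF (parasympathetic) amplitude
during the mental task, depressive profiles respond flatly.

On top of the beat train the module synthesizes a reference single-lead ECG
(Gaussian QRS template at each beat, 100 Hz), a facial mean-RGB trace whose
green channel dips ~120 ms after each R wave (the pulse transit time to the
face), and, optionally, rendered frames carrying a moving face ellipse for
the ROI stage.  Cohorts pair each subject's autonomic profile with a Zung
SDS score drawn from group-specific truncated normals around the reported
clinical means (healthy ~33, depressive ~53, cutoff 48).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import truncnorm

from .hrv import ProtocolConfig
from .video_roi import FrameStream, RgbTrace

__all__ = [
    "AutonomicProfile",
    "SyntheticSubject",
    "SyntheticSession",
    "EcgSignal",
    "FaceGeometry",
    "HEALTHY_PROFILE",
    "MDD_PROFILE",
    "SDS_CUTOFF",
    "generate_beats",
    "synthesize_ecg",
    "synthesize_rgb_trace",
    "render_frames",
    "generate_cohort",
    "simulate_session",
]

SDS_CUTOFF = 48  # Zung SDS score at or above which MDD is suspected


@dataclass(frozen=True)
class AutonomicProfile:
    """IPFM rate-modulation parameters per protocol period (Pre-R, MT, Post-R)."""

    mean_hr: float = 70.0  # beats/min
    lf_freq: float = 0.10  # Hz
    hf_freq: float = 0.25  # Hz
    lf_amp_per_period: tuple[float, float, float] = (0.05, 0.07, 0.05)
    hf_amp_per_period: tuple[float, float, float] = (0.08, 0.02, 0.08)
    noise_sd: float = 0.02  # dimensionless rate-modulation noise

    def __post_init__(self) -> None:
        if not 40 <= self.mean_hr <= 180:
            raise ValueError("mean_hr must be in [40, 180] bpm")
        if not 0.04 <= self.lf_freq < 0.15:
            raise ValueError("lf_freq must be in [0.04, 0.15) Hz")
        if not 0.15 <= self.hf_freq < 0.4:
            raise ValueError("hf_freq must be in [0.15, 0.4) Hz")
        amps = (*self.lf_amp_per_period, *self.hf_amp_per_period, self.noise_sd)
        if any(a < 0 for a in amps):
            raise ValueError("modulation amplitudes must be non-negative")


#: Default group profiles: healthy suppresses HF during the mental task,
#: the depressive profile shows a flat HF response.
HEALTHY_PROFILE = AutonomicProfile(hf_amp_per_period=(0.08, 0.02, 0.08))
MDD_PROFILE = AutonomicProfile(hf_amp_per_period=(0.05, 0.05, 0.05))


@dataclass(frozen=True)
class SyntheticSubject:
    group: Literal["healthy", "mdd"]
    sds_score: int
    profile: AutonomicProfile
    seed: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not 20 <= self.sds_score <= 80:
            raise ValueError("SDS score must be in [20, 80]")
        if self.group == "healthy" and self.sds_score >= SDS_CUTOFF:
            raise ValueError("healthy subjects must have SDS below the cutoff")
        if self.group == "mdd" and self.sds_score < SDS_CUTOFF:
            raise ValueError("mdd subjects must have SDS at or above the cutoff")


@dataclass
class EcgSignal:
    samples: np.ndarray  # dimensionless amplitude
    fs: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, float)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class SyntheticSession:
    beat_times: np.ndarray  # seconds from session start (ground truth)
    ecg: EcgSignal | None
    rgb_trace: RgbTrace
    subject: SyntheticSubject
    ptt_ms: float = 120.0


def generate_beats(
    profile: AutonomicProfile,
    protocol: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    grid_fs: float = 64.0,
) -> np.ndarray:
    """IPFM beat times over the protocol; deterministic for a fixed seed.

    The modulation noise is white Gaussian on the integration grid, smoothed
    with a 0.25 s moving average and rescaled back to ``noise_sd`` so the
    rate stays continuous.  Raises if the total modulation would drive the
    instantaneous rate non-positive.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / grid_fs
    t = np.arange(0.0, protocol.total_s + dt, dt)
    b = protocol.boundaries
    period = np.clip(np.searchsorted(b[1:3], t, side="right"), 0, 2)

    lf_amp = np.asarray(profile.lf_amp_per_period)[period]
    hf_amp = np.asarray(profile.hf_amp_per_period)[period]
    m = lf_amp * np.sin(2 * np.pi * profile.lf_freq * t) + hf_amp * np.sin(
        2 * np.pi * profile.hf_freq * t
    )
    if profile.noise_sd > 0:
        w = max(1, int(round(0.25 * grid_fs)))
        noise = uniform_filter1d(rng.standard_normal(len(t)), size=w)
        sd = noise.std()
        if sd > 0:
            noise *= profile.noise_sd / sd
        m = m + noise
    if np.max(np.abs(m)) >= 1.0:
        raise ValueError("total modulation |m| >= 1; instantaneous rate non-positive")

    rate = (profile.mean_hr / 60.0) * (1.0 + m)
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2) * dt])
    n_beats = int(np.floor(integral[-1] + 1e-9))
    if n_beats < 1:
        return np.empty(0)
    return np.interp(np.arange(1, n_beats + 1, dtype=float), integral, t)


def synthesize_ecg(
    beat_times: np.ndarray,
    fs: float = 100.0,
    duration_s: float | None = None,
    qrs_sd_ms: float = 8.0,
) -> EcgSignal:
    """Reference ECG: one Gaussian QRS template per beat on a flat baseline.

    Morphology is irrelevant downstream (only R-peak times are consumed), so
    a narrow positive Gaussian (~20 ms wide) stands in for the QRS complex.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    beat_times = np.asarray(beat_times, float)
    if duration_s is None:
        duration_s = (
            ProtocolConfig().total_s if len(beat_times) == 0 else beat_times[-1] + 1.0
        )
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    sd = qrs_sd_ms / 1000.0
    half = int(np.ceil(4 * sd * fs))
    for tb in beat_times:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs
        x[lo:hi] += np.exp(-0.5 * ((tt - tb) / sd) ** 2)
    return EcgSignal(samples=x, fs=fs)


def synthesize_rgb_trace(
    beat_times: np.ndarray,
    duration_s: float,
    fs: float = 30.0,
    ptt_ms: float = 120.0,
    pulse_amp: float = 1.5,
    noise_sd: float = 0.2,
    drift_amp: float = 2.0,
    baseline: tuple[float, float, float] = (150.0, 110.0, 95.0),
    pulse_sd_s: float = 0.11,
    seed: int = 0,
) -> RgbTrace:
    """Facial mean-RGB trace with a pulsatile green channel.

    The green channel is ``baseline - pulse_amp * w(t)`` where ``w`` is a
    smooth systolic waveform (Gaussian) peaking ``ptt_ms`` after each beat,
    plus slow sinusoidal drift and white sensor noise.  Red and blue carry
    baseline, drift and noise only.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if pulse_amp < 0:
        raise ValueError("pulse_amp must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    w = np.zeros(n)
    half = int(np.ceil(4 * pulse_sd_s * fs))
    for tb in np.asarray(beat_times, float) + ptt_ms / 1000.0:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        w[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tb) / pulse_sd_s) ** 2)

    phases = rng.uniform(0, 2 * np.pi, size=2)
    drift = drift_amp * (
        np.sin(2 * np.pi * 0.03 * t + phases[0])
        + 0.5 * np.sin(2 * np.pi * 0.07 * t + phases[1])
    )
    noise = rng.normal(0, noise_sd, size=(3, n)) if noise_sd > 0 else np.zeros((3, n))
    r = baseline[0] + drift + noise[0]
    g = baseline[1] + drift + noise[1] - pulse_amp * w
    b = baseline[2] + drift + noise[2]
    return RgbTrace(t=t, r=r, g=g, b=b, fps=fs)


@dataclass(frozen=True)
class FaceGeometry:
    """Face ellipse and frame geometry for synthetic rendering."""

    width: int = 320
    height: int = 180
    cx: float = 160.0
    cy: float = 90.0
    semi_x: float = 55.0
    semi_y: float = 75.0
    background: tuple[int, int, int] = (40, 40, 40)

    def __post_init__(self) -> None:
        if not (
            0 < self.cx - self.semi_x
            and self.cx + self.semi_x < self.width
            and 0 < self.cy - self.semi_y
            and self.cy + self.semi_y < self.height
        ):
            raise ValueError("face ellipse must lie inside the frame")

    def center_at(self, t: float, motion_amp_px: float, motion_freq: float) -> tuple[float, float]:
        return (self.cx + motion_amp_px * np.sin(2 * np.pi * motion_freq * t), self.cy)


def render_frames(
    rgb_trace: RgbTrace,
    geometry: FaceGeometry = FaceGeometry(),
    motion_amp_px: float = 0.0,
    motion_freq: float = 0.1,
    center_fn=None,
) -> FrameStream:
    """Render the trace as frames: a face ellipse whose pixels carry the
    per-frame trace values (quantized to 256 tones) on a uniform background,
    the ellipse center following a slow sinusoidal horizontal motion (or an
    arbitrary ``center_fn(t) -> (cx, cy)`` override)."""
    g = geometry
    if center_fn is None and motion_amp_px + g.semi_x >= min(g.cx, g.width - g.cx):
        raise ValueError("motion would carry the face outside the frame")
    n = len(rgb_trace)
    frames = np.empty((n, g.height, g.width, 3), dtype=np.uint8)
    yy, xx = np.mgrid[0 : g.height, 0 : g.width]
    vals = np.clip(
        np.rint(np.stack([rgb_trace.r, rgb_trace.g, rgb_trace.b], axis=1)), 0, 255
    ).astype(np.uint8)
    bg = np.array(g.background, dtype=np.uint8)
    for i in range(n):
        if center_fn is not None:
            cx, cy = center_fn(rgb_trace.t[i])
        else:
            cx, cy = g.center_at(rgb_trace.t[i], motion_amp_px, motion_freq)
        mask = ((xx - cx) / g.semi_x) ** 2 + ((yy - cy) / g.semi_y) ** 2 <= 1.0
        frame = np.broadcast_to(bg, (g.height, g.width, 3)).copy()
        frame[mask] = vals[i]
        frames[i] = frame
    return FrameStream(
        frames=frames,
        fps=rgb_trace.fps,
        metadata={"geometry": g, "motion_amp_px": motion_amp_px, "motion_freq": motion_freq},
    )


def _truncated_sds(rng: np.random.Generator, group: str) -> int:
    """Group SDS score from a truncated normal around the clinical means."""
    if group == "healthy":
        mean, sd, lo, hi = 33.0, 5.0, 20.0, SDS_CUTOFF - 1e-9
    else:
        mean, sd, lo, hi = 53.0, 5.0, SDS_CUTOFF, 80.0
    a, bnd = (lo - mean) / sd, (hi - mean) / sd
    val = truncnorm.rvs(a, bnd, loc=mean, scale=sd, random_state=rng)
    score = int(np.clip(np.rint(val), 20, 80))
    if group == "healthy":
        score = min(score, SDS_CUTOFF - 1)
    else:
        score = max(score, SDS_CUTOFF)
    return score


def generate_cohort(
    n_mdd: int,
    n_healthy: int,
    seed: int = 0,
    amp_jitter_sigma: float = 0.3,
    atypical_healthy_frac: float = 0.15,
    atypical_mdd_frac: float = 0.20,
) -> list[SyntheticSubject]:
    """Cohort of subjects with group-linked SDS scores and autonomic profiles.

    Per-subject heterogeneity (lognormal amplitude jitter plus a minority of
    atypical responders: healthy subjects with blunted task suppression,
    depressive subjects with partial suppression) keeps the groups
    overlapping, mirroring the imperfect real-world separability of the
    task-evoked HF response.  Deterministic per seed.
    """
    if n_mdd < 0 or n_healthy < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    subjects: list[SyntheticSubject] = []
    groups = ["mdd"] * n_mdd + ["healthy"] * n_healthy
    for i, group in enumerate(groups):
        base = HEALTHY_PROFILE if group == "healthy" else MDD_PROFILE
        jit = rng.lognormal(0.0, amp_jitter_sigma, size=6)
        lf = tuple(a * j for a, j in zip(base.lf_amp_per_period, jit[:3]))
        hf = list(a * j for a, j in zip(base.hf_amp_per_period, jit[3:]))
        if group == "healthy" and rng.random() < atypical_healthy_frac:
            hf[1] = hf[0] * rng.uniform(0.6, 1.0)  # blunted suppression
        elif group == "mdd" and rng.random() < atypical_mdd_frac:
            hf[1] = hf[0] * rng.uniform(0.25, 0.6)  # partial suppression
        mean_hr = float(np.clip(rng.normal(70.0, 8.0), 55.0, 95.0))
        profile = replace(
            base,
            mean_hr=mean_hr,
            lf_amp_per_period=lf,
            hf_amp_per_period=tuple(hf),
        )
        subjects.append(
            SyntheticSubject(
                group=group,
                sds_score=_truncated_sds(rng, group),
                profile=profile,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"{group[0]}{i:03d}",
            )
        )
    return subjects


def simulate_session(
    subject: SyntheticSubject,
    protocol: ProtocolConfig = ProtocolConfig(),
    with_ecg: bool = True,
    ptt_ms: float = 120.0,
    pulse_amp: float = 1.5,
    trace_noise_sd: float = 0.2,
) -> SyntheticSession:
    """Full session for one subject: beats, optional ECG, RGB trace."""
    beats = generate_beats(subject.profile, protocol, seed=subject.seed)
    ecg = (
        synthesize_ecg(beats, fs=100.0, duration_s=protocol.total_s)
        if with_ecg
        else None
    )
    trace = synthesize_rgb_trace(
        beats,
        duration_s=protocol.total_s,
        ptt_ms=ptt_ms,
        pulse_amp=pulse_amp,
        noise_sd=trace_noise_sd,
        seed=subject.seed + 1,
    )
    return SyntheticSession(
        beat_times=beats, ecg=ecg, rgb_trace=trace, subject=subject, ptt_ms=ptt_ms
    )
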