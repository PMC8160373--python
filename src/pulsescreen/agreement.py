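"""Validation of camera-derived IBI against the reference ECG channel.

R peaks are detected with a Pan-Tompkins-style chain (5-15 Hz band-pass,
squared derivative, 150 ms moving-window integration, adaptive threshold
with a 250 ms refractory period, parabolic sub-sample refinement).  Camera
and ECG beats are paired by nearest-neighbor matching within 500 ms — wide
enough to absorb the ~120 ms pulse transit time to the face plus jitter —
and consecutive paired intervals feed Pearson correlation, RMSE and
Bland-Altman limits of agreement (bias +/- 1.96 sigma of the differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import FlatSignalError
from .synthetic import EcgSignal

__all__ = [
    "AgreementStats",
    "detect_r_peaks",
    "pair_beats",
    "agreement_stats",
    "correlate_scores",
]


@dataclass
class AgreementStats:
    r: float
    p_value: float
    rmse: float  # ms
    bias: float  # ms, camera - reference
    loa_low: float  # ms
    loa_high: float  # ms
    sd_diff: float  # ms, n-1 sample SD
    n_pairs: int
    r_defined: bool = True


def detect_r_peaks(ecg: EcgSignal, refractory_s: float = 0.25) -> np.ndarray:
    """R-peak times (seconds) from a single-lead ECG; needs fs >= 100 Hz."""
    x = np.asarray(ecg.samples, float)
    fs = ecg.fs
    if fs < 100:
        raise ValueError("ECG sampling rate must be at least 100 Hz")
    if len(x) < fs or np.ptp(x) == 0:
        raise FlatSignalError("ECG signal is flat or too short")

    sos = butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sosfiltfilt(sos, x)
    integ = uniform_filter1d(np.gradient(bp) ** 2, size=max(1, int(round(0.15 * fs))))

    dist = max(1, int(round(refractory_s * fs)))
    cand, _ = find_peaks(integ, distance=dist)
    if len(cand) == 0:
        raise FlatSignalError("no QRS-like activity found")
    heights = integ[cand]
    thr = 0.3 * np.percentile(heights, 90)
    cand = cand[heights >= thr]
    if len(cand) == 0:
        raise FlatSignalError("no QRS-like activity above the adaptive threshold")

    # refine to the R apex on the raw signal, then sub-sample parabolic fit
    half = int(round(0.1 * fs))
    times = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        i = lo + int(np.argmax(x[lo:hi]))
        delta = 0.0
        if 0 < i < len(x) - 1:
            denom = x[i - 1] - 2 * x[i] + x[i + 1]
            if denom != 0:
                delta = float(np.clip(0.5 * (x[i - 1] - x[i + 1]) / denom, -0.5, 0.5))
        times.append((i + delta) / fs)
    times = np.array(sorted(set(times)))
    return times[np.concatenate([[True], np.diff(times) > refractory_s / 2])]


def pair_beats(
    camera_beats: np.ndarray,
    ecg_beats: np.ndarray,
    max_lag_ms: float = 500.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pair camera and ECG beats; return matched consecutive IBIs.

    Each ECG beat is matched to its nearest camera beat within ``max_lag_ms``
    (one-to-one; the closer ECG beat wins a contested camera beat).  An IBI
    pair is kept only where both member beats matched consecutive camera
    beats, so a constant camera-side delay (pulse transit time) cancels.
    Returns ``(camera_ibi_ms, ecg_ibi_ms, match_rate)``.
    """
    cam = np.asarray(camera_beats, float)
    ecg = np.asarray(ecg_beats, float)
    if np.any(np.diff(cam) <= 0) or np.any(np.diff(ecg) <= 0):
        raise ValueError("beat sequences must be strictly increasing")
    max_lag = max_lag_ms / 1000.0

    match = np.full(len(ecg), -1)
    if len(cam) > 0:
        pos = np.searchsorted(cam, ecg)
        for i, (t, p) in enumerate(zip(ecg, pos)):
            cands = [j for j in (p - 1, p) if 0 <= j < len(cam)]
            if not cands:
                continue
            j = min(cands, key=lambda j: abs(cam[j] - t))
            if abs(cam[j] - t) <= max_lag:
                match[i] = j
        # resolve contested camera beats: nearest ECG beat keeps the match
        for j in np.unique(match[match >= 0]):
            claim = np.nonzero(match == j)[0]
            if len(claim) > 1:
                keep = claim[np.argmin(np.abs(ecg[claim] - cam[j]))]
                match[np.setdiff1d(claim, [keep])] = -1

    match_rate = float((match >= 0).mean()) if len(ecg) else 0.0
    if len(ecg) and match_rate < 0.8:
        warnings.warn(
            f"only {match_rate:.0%} of ECG beats matched; alignment is suspect",
            stacklevel=2,
        )
    cam_ibi, ecg_ibi = [], []
    for i in range(len(ecg) - 1):
        ji, jk = match[i], match[i + 1]
        if ji >= 0 and jk == ji + 1:
            cam_ibi.append((cam[jk] - cam[ji]) * 1000.0)
            ecg_ibi.append((ecg[i + 1] - ecg[i]) * 1000.0)
    return np.array(cam_ibi), np.array(ecg_ibi), match_rate


def agreement_stats(cam_ibi_ms: np.ndarray, ref_ibi_ms: np.ndarray) -> AgreementStats:
    """Pearson r, RMSE and Bland-Altman limits for paired IBIs."""
    cam = np.asarray(cam_ibi_ms, float)
    ref = np.asarray(ref_ibi_ms, float)
    if len(cam) != len(ref) or len(cam) < 3:
        raise ValueError("need at least 3 paired intervals of equal length")
    diff = cam - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rmse = float(np.sqrt(np.mean(diff**2)))
    r_defined = cam.std() > 0 and ref.std() > 0
    if r_defined:
        r, p = stats.pearsonr(cam, ref)
    else:
        r, p = np.nan, np.nan
    return AgreementStats(
        r=float(r),
        p_value=float(p),
        rmse=rmse,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n_pairs=len(cam),
        r_defined=bool(r_defined),
    )


def correlate_scores(
    logits: np.ndarray, sds_scores: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between per-subject logit and SDS scores."""
    logits = np.asarray(logits, float)
    sds = np.asarray(sds_scores, float)
    if len(logits) != len(sds) or len(logits) < 3:
        raise ValueError("need at least 3 paired scores")
    if logits.std() == 0 or sds.std() == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(logits, sds)
    return float(r), float(p)
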