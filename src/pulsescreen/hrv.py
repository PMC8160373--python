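"""Task-evoked HRV spectral features over the three-period protocol.

The screening protocol is pre-rest (140 s), a random-number-generation
mental task (100 s) and post-rest (120 s), 360 s in total.  For each period
the accepted interbeat intervals are cubic-spline resampled to a uniform
4 Hz grid, mean-removed, and Welch-estimated (Hann window, segments of at
most 240 samples = 60 s, 50% overlap).  Band powers are trapezoidal
integrals of the density over LF = [0.04, 0.15) Hz (mixed sympathetic and
parasympathetic drive) and HF = [0.15, 0.4) Hz (parasympathetic,
respiration-coupled), in ms^2.

The candidate feature vector has 15 entries: LF, HF and LF/HF for each of
the three periods, plus percent changes %d X_(A=>B) = 100 (X_B - X_A) / X_A
for the Pre-R => MT and MT => Post-R transitions of each of the three
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .bvp import IbiSeries
from .errors import InsufficientDataError, UndefinedDeltaError

__all__ = [
    "ProtocolConfig",
    "BandConfig",
    "PeriodHrv",
    "FeatureVector15",
    "PERIOD_NAMES",
    "FEATURE_NAMES",
    "segment_periods",
    "compute_psd",
    "band_power",
    "period_hrv",
    "compute_features",
]

PERIOD_NAMES = ("PreR", "MT", "PostR")

FEATURE_NAMES = (
    "LF_PreR", "LF_MT", "LF_PostR",
    "HF_PreR", "HF_MT", "HF_PostR",
    "LFHF_PreR", "LFHF_MT", "LFHF_PostR",
    "pctLF_PreR_MT", "pctHF_PreR_MT", "pctLFHF_PreR_MT",
    "pctLF_MT_PostR", "pctHF_MT_PostR", "pctLFHF_MT_PostR",
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Durations of the three protocol periods, seconds."""

    pre_r_s: float = 140.0
    mt_s: float = 100.0
    post_r_s: float = 120.0

    def __post_init__(self) -> None:
        if min(self.pre_r_s, self.mt_s, self.post_r_s) <= 0:
            raise ValueError("all period durations must be positive")

    @property
    def total_s(self) -> float:
        return self.pre_r_s + self.mt_s + self.post_r_s

    @property
    def boundaries(self) -> tuple[float, float, float, float]:
        return (
            0.0,
            self.pre_r_s,
            self.pre_r_s + self.mt_s,
            self.total_s,
        )

    def period_of(self, t: float) -> int:
        """Index of the half-open period [start, end) containing t; the last
        period also claims its closing boundary."""
        b = self.boundaries
        if t < b[0] or t > b[3]:
            raise ValueError(f"time {t} outside the protocol")
        if t < b[1]:
            return 0
        if t < b[2]:
            return 1
        return 2


@dataclass(frozen=True)
class BandConfig:
    """LF/HF band edges, half-open [lo, hi) in Hz."""

    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        if not (0 < self.lf[0] < self.lf[1] <= self.hf[0] < self.hf[1]):
            raise ValueError("bands must be positive, ordered and disjoint")


@dataclass(frozen=True)
class PeriodHrv:
    lf_power: float  # ms^2
    hf_power: float  # ms^2

    @property
    def lf_hf_ratio(self) -> float:
        return self.lf_power / self.hf_power if self.hf_power > 0 else np.nan


class FeatureVector15:
    """The 15 named candidate explanatory variables, in fixed order."""

    names = FEATURE_NAMES

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, float)
        if values.shape != (15,):
            raise ValueError("feature vector must have exactly 15 entries")
        self.values = values

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def segment_periods(
    ibi: IbiSeries,
    protocol: ProtocolConfig = ProtocolConfig(),
    min_intervals: int = 20,
) -> list[IbiSeries]:
    """Split an IBI series into the three protocol periods.

    An interval belongs to the period containing its *ending* beat time
    (half-open boundaries, so an interval ending exactly at the Pre-R/MT
    boundary belongs to MT).
    """
    b = protocol.boundaries
    t_end = ibi.interval_times
    out = []
    for p in range(3):
        sel = (t_end >= b[p]) & (t_end < b[p + 1])
        if p == 2:  # closing boundary belongs to the last period
            sel |= t_end == b[3]
        sel &= ibi.accepted
        n = int(sel.sum())
        if n < min_intervals:
            raise InsufficientDataError(
                f"period {PERIOD_NAMES[p]} has {n} accepted intervals "
                f"(< {min_intervals})"
            )
        seg = IbiSeries(
            beat_times=np.concatenate(
                [[t_end[sel][0] - ibi.ibi_ms[sel][0] / 1000.0], t_end[sel]]
            ),
            ibi_ms=ibi.ibi_ms[sel],
        )
        out.append(seg)
    return out


def compute_psd(
    segment: IbiSeries,
    fs_interp: float = 4.0,
    max_window: int = 240,
    min_intervals: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of an IBI segment.

    Accepted (time, ibi) samples are cubic-spline interpolated onto a
    uniform ``fs_interp`` grid, mean-removed, and Welch-estimated with a
    Hann window of at most ``max_window`` samples at 50% overlap.  Returns
    (frequencies Hz, density ms^2/Hz).
    """
    t = segment.interval_times[segment.accepted]
    y = segment.ibi_ms[segment.accepted]
    if len(y) < min_intervals:
        raise InsufficientDataError(
            f"{len(y)} accepted intervals (< {min_intervals})"
        )
    grid = np.arange(t[0], t[-1], 1.0 / fs_interp)
    resampled = CubicSpline(t, y)(grid)
    resampled = resampled - resampled.mean()
    nperseg = min(len(resampled), max_window)
    freqs, density = welch(
        resampled,
        fs=fs_interp,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )
    return freqs, density


def band_power(
    freqs: np.ndarray, density: np.ndarray, band: tuple[float, float]
) -> float:
    """Trapezoidal integral of the density over [lo, hi), ms^2."""
    lo, hi = band
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(
            f"band [{lo}, {hi}) outside the resolvable range "
            f"[{freqs[0]:.4g}, {freqs[-1]:.4g}]"
        )
    inner = (freqs > lo) & (freqs < hi)
    xs = np.concatenate([[lo], freqs[inner], [hi]])
    ys = np.interp(xs, freqs, density)
    return float(np.trapezoid(ys, xs))


def period_hrv(
    segment: IbiSeries, bands: BandConfig = BandConfig(), **psd_kwargs
) -> PeriodHrv:
    freqs, density = compute_psd(segment, **psd_kwargs)
    return PeriodHrv(
        lf_power=band_power(freqs, density, bands.lf),
        hf_power=band_power(freqs, density, bands.hf),
    )


def _pct_change(a: float, b: float, name: str) -> float:
    if a == 0:
        raise UndefinedDeltaError(f"{name}: baseline value is zero")
    return 100.0 * (b - a) / a


def compute_features(periods: list[PeriodHrv]) -> FeatureVector15:
    """Assemble the 15 candidate features from the three period triples."""
    if len(periods) != 3:
        raise ValueError("need exactly three PeriodHrv (Pre-R, MT, Post-R)")
    lf = [p.lf_power for p in periods]
    hf = [p.hf_power for p in periods]
    ratio = [p.lf_hf_ratio for p in periods]
    values = lf + hf + ratio
    for a, b, tag in [(0, 1, "PreR_MT"), (1, 2, "MT_PostR")]:
        values.append(_pct_change(lf[a], lf[b], f"pctLF_{tag}"))
        values.append(_pct_change(hf[a], hf[b], f"pctHF_{tag}"))
        values.append(_pct_change(ratio[a], ratio[b], f"pctLFHF_{tag}"))
    return FeatureVector15(np.asarray(values))
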