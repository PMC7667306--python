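"""Cardiac chain: R-peak detection, inter-beat intervals, RMSSD.

RMSSD — the root mean square of successive differences between adjacent
inter-beat intervals (IBIs) — is the time-domain heart-rate-variability
index used throughout; higher values indicate stronger parasympathetic
(vagal) influence on the heart.

R peaks are found with a Pan–Tompkins-style transform: band-pass the ECG
to the QRS band (5–15 Hz), differentiate, square, integrate over a 150 ms
moving window, then pick maxima above an adaptive threshold (a configurable
fraction of a running peak-amplitude estimate) with a 250 ms refractory
period.  Peak locations are refined on the zero-phase band-passed trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "RPeakList",
    "IBISeries",
    "HRVResult",
    "NoPeaksError",
    "detect_r_peaks",
    "ibis_from_peaks",
    "apply_corrections",
    "rmssd",
]

logger = logging.getLogger(__name__)

#: minimum interval between detected heartbeats (s)
REFRACTORY_S = 0.25


class NoPeaksError(ValueError):
    """Raised when a trace contains no detectable heartbeat."""


@dataclass(frozen=True)
class RPeakList:
    """Strictly increasing R-peak times in seconds."""

    times_s: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("peak times must be strictly increasing")
        object.__setattr__(self, "times_s", t)

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass(frozen=True)
class IBISeries:
    """Positive inter-beat intervals in milliseconds."""

    ibis_ms: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.ibis_ms, dtype=float)
        if np.any(x <= 0):
            raise ValueError("all IBIs must be positive")
        object.__setattr__(self, "ibis_ms", x)

    def __len__(self) -> int:
        return int(self.ibis_ms.size)

    @property
    def mean_ms(self) -> float:
        return float(np.mean(self.ibis_ms))


@dataclass(frozen=True)
class HRVResult:
    rmssd_ms: float
    n_ibis: int
    condition: str | None = None


def detect_r_peaks(
    ecg: np.ndarray,
    fs_hz: float,
    threshold_frac: float = 0.3,
    refractory_s: float = REFRACTORY_S,
    min_duration_s: float = 10.0,
) -> RPeakList:
    """Locate R peaks in a single-channel ECG-like trace.

    ``threshold_frac`` is the fraction of the running peak estimate (a
    2 s rolling maximum of the integrated transform) a candidate must
    exceed.  Raises :class:`NoPeaksError` when nothing crosses threshold.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size / fs_hz < min_duration_s:
        raise ValueError(f"trace shorter than {min_duration_s} s")
    sos = butter(2, [5.0, 15.0], btype="bandpass", fs=fs_hz, output="sos")
    bp = sosfiltfilt(sos, x)
    transformed = np.square(np.gradient(bp))
    win = max(1, int(round(0.150 * fs_hz)))
    integ = uniform_filter1d(transformed, size=win)
    # running peak estimate over a 2 s neighbourhood; adaptive to amplitude drift
    run_peak = maximum_filter1d(integ, size=int(round(2.0 * fs_hz)))
    if np.max(run_peak) <= 0:
        raise NoPeaksError("flat trace: no QRS energy found")
    thresh = threshold_frac * run_peak
    cand, _ = find_peaks(integ, distance=max(1, int(round(refractory_s * fs_hz))))
    cand = cand[integ[cand] >= thresh[cand]]
    if cand.size == 0:
        raise NoPeaksError("no candidate exceeded the adaptive threshold")
    # refine: integrated maximum lags/leads the R wave; snap to the local
    # extremum of the band-passed trace
    half = int(round(0.10 * fs_hz))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # re-impose the refractory after refinement
    keep = [refined[0]]
    min_gap = refractory_s * fs_hz
    for idx in refined[1:]:
        if idx - keep[-1] >= min_gap:
            keep.append(idx)
        elif np.abs(bp[idx]) > np.abs(bp[keep[-1]]):
            keep[-1] = idx
    return RPeakList(times_s=np.asarray(keep) / fs_hz)


def apply_corrections(
    peaks: RPeakList, corrections: list[tuple[str, float]], tol_s: float = 0.05
) -> RPeakList:
    """Apply manual-edit corrections: ('add', t) inserts a peak at t,
    ('remove', t) deletes the detected peak nearest t within ``tol_s``."""
    times = list(peaks.times_s)
    for action, t in corrections:
        if action == "add":
            times.append(float(t))
        elif action == "remove":
            if not times:
                continue
            arr = np.asarray(times)
            i = int(np.argmin(np.abs(arr - t)))
            if abs(arr[i] - t) <= tol_s:
                times.pop(i)
        else:
            raise ValueError(f"unknown correction action {action!r}")
    return RPeakList(times_s=np.sort(np.asarray(times)))


def ibis_from_peaks(
    peaks: RPeakList,
    physiological_filter: bool = False,
    bounds_ms: tuple[float, float] = (300.0, 2000.0),
) -> IBISeries:
    """Successive peak differences in ms; n_peaks − 1 intervals.

    With ``physiological_filter`` on, IBIs outside ``bounds_ms`` are removed
    and the count logged (off by default).
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to form an IBI")
    ibis = np.diff(peaks.times_s) * 1000.0
    if physiological_filter:
        lo, hi = bounds_ms
        mask = (ibis >= lo) & (ibis <= hi)
        n_removed = int(np.sum(~mask))
        if n_removed:
            logger.info("ibis_from_peaks: removed %d IBIs outside [%g, %g] ms",
                        n_removed, lo, hi)
        ibis = ibis[mask]
        if ibis.size == 0:
            raise ValueError("physiological filter removed every IBI")
    return IBISeries(ibis_ms=ibis)


def rmssd(ibis: IBISeries, condition: str | None = None) -> HRVResult:
    """Root mean square of successive IBI differences, in ms."""
    if len(ibis) < 2:
        raise ValueError("RMSSD undefined for fewer than 2 IBIs")
    d = np.diff(ibis.ibis_ms)
    return HRVResult(
        rmssd_ms=float(np.sqrt(np.mean(np.square(d)))),
        n_ibis=len(ibis),
        condition=condition,
    )
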