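"""R-peak detection by differential thresholding, RR derivation, windowing.

Candidate peaks are local maxima of the denoised trace (sign change of
the first difference with negative curvature) whose amplitude clears an
adaptive threshold computed per detection window:

    threshold = (max(x) - min(x)) * 0.7 + min(x)

i.e. 70% of the local dynamic range above the local minimum.  A 200 ms
refractory rule keeps only the largest candidate of any run of
near-coincident candidates, reflecting the physiological floor on
inter-beat spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signals import ECGRecord, RPeakSeries, RRSeries

__all__ = ["DetectorParams", "detect_r_peaks", "to_rr_intervals",
           "segment_windows", "amplitude_threshold", "EFFECTIVE_MIN_BEATS"]

ARTIFACT_BOUNDS_MS = (300.0, 2000.0)
EFFECTIVE_MIN_BEATS = 40
EFFECTIVE_MAX_ARTIFACT_FRAC = 0.20


@dataclass(frozen=True)
class DetectorParams:
    threshold_fraction: float = 0.7
    detection_window: float = 10.0   # s over which max/min are taken
    refractory: float = 200.0        # ms

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.refractory <= 0:
            raise ValueError("refractory must be positive")
        if self.detection_window <= 0:
            raise ValueError("detection_window must be positive")


def amplitude_threshold(x: np.ndarray, fraction: float = 0.7) -> float:
    """Adaptive amplitude threshold over one detection window."""
    mx, mn = float(np.max(x)), float(np.min(x))
    return (mx - mn) * fraction + mn


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima: first difference changes sign + to -, i.e.
    negative second difference at the turning point."""
    d = np.diff(x)
    return np.flatnonzero((d[:-1] > 0) & (d[1:] < 0)) + 1


def detect_r_peaks(ecg: ECGRecord, params: DetectorParams | None = None) -> RPeakSeries:
    """Detect R peaks on a (denoised) ECG record.

    Returns an empty series with a warning when the signal is flat.
    """
    params = params or DetectorParams()
    if ecg.n < 3:
        raise ValueError("need at least 3 samples to detect peaks")
    x = ecg.samples
    if np.max(x) == np.min(x):
        warnings.warn("flat signal: no R peaks detected", stacklevel=2)
        return RPeakSeries(peak_times=np.array([]), peak_amplitudes=np.array([]),
                           fs=ecg.fs)
    maxima = _local_maxima(x)
    win = max(int(round(params.detection_window * ecg.fs)), 2)
    keep = []
    for start in range(0, ecg.n, win):
        stop = min(start + win, ecg.n)
        seg = x[start:stop]
        if seg.size < 2 or np.max(seg) == np.min(seg):
            continue
        thr = amplitude_threshold(seg, params.threshold_fraction)
        m = maxima[(maxima >= start) & (maxima < stop)]
        keep.extend(m[x[m] >= thr].tolist())
    keep = np.asarray(sorted(keep), dtype=int)
    # Refractory rule: within any run of candidates closer than the
    # refractory spacing keep only the largest.
    ref_samples = params.refractory / 1000.0 * ecg.fs
    sel: list[int] = []
    for i in keep:
        if sel and i - sel[-1] < ref_samples:
            if x[i] > x[sel[-1]]:
                sel[-1] = i
        else:
            sel.append(int(i))
    sel_arr = np.asarray(sel, dtype=int)
    return RPeakSeries(peak_times=ecg.start_time + sel_arr / ecg.fs,
                       peak_amplitudes=x[sel_arr], fs=ecg.fs)


def to_rr_intervals(peaks: RPeakSeries) -> RRSeries:
    """Successive peak spacings in ms; intervals outside [300, 2000] ms
    are flagged as artifacts (not removed)."""
    if peaks.n < 2:
        warnings.warn("fewer than 2 peaks: empty RR series", stacklevel=2)
        return RRSeries(intervals=np.array([]), end_times=np.array([]))
    intervals = np.diff(peaks.peak_times) * 1000.0
    lo, hi = ARTIFACT_BOUNDS_MS
    artifact = (intervals < lo) | (intervals > hi)
    return RRSeries(intervals=intervals, end_times=peaks.peak_times[1:],
                    artifact=artifact)


def segment_windows(rr: RRSeries, window_length: float = 100.0,
                    total_duration: float | None = None):
    """Cut consecutive non-overlapping windows of RR intervals.

    An interval belongs to the half-open window [k*L, (k+1)*L) containing
    its end time.  The trailing partial window is discarded.  A window is
    "effective" when it holds at least 40 intervals of which at most 20%
    are artifact-flagged.

    Returns a list of ``(window_index, RRSeries, effective)`` tuples.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if rr.n == 0:
        return []
    span = total_duration if total_duration is not None else float(rr.end_times[-1])
    n_windows = int(span // window_length)
    out = []
    idx = np.floor(rr.end_times / window_length).astype(int)
    for k in range(n_windows):
        mask = idx == k
        sub = RRSeries(intervals=rr.intervals[mask], end_times=rr.end_times[mask],
                       artifact=rr.artifact[mask])
        effective = (sub.n >= EFFECTIVE_MIN_BEATS
                     and (sub.n == 0 or sub.artifact.mean() <= EFFECTIVE_MAX_ARTIFACT_FRAC))
        out.append((k, sub, effective))
    return out
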