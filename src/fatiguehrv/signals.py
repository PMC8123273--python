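"""Core signal containers shared across the pipeline.

The pipeline works on three representations of cardiac activity:
a uniformly sampled single-lead voltage trace (:class:`ECGRecord`),
the detected R-peak event series (:class:`RPeakSeries`), and the
derived inter-beat interval series (:class:`RRSeries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ECGRecord", "RPeakSeries", "RRSeries"]


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage in millivolts.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.fs

    def copy_with(self, samples: np.ndarray) -> "ECGRecord":
        return ECGRecord(samples=np.asarray(samples, dtype=float),
                         fs=self.fs, start_time=self.start_time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "ecg_mV": self.samples})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ECGRecord":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("ECG CSV must contain at least two samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(samples=df["ecg_mV"].to_numpy(), fs=fs, start_time=float(t[0]))


@dataclass
class RPeakSeries:
    """Detected R-peak times (s) and amplitudes (mV)."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_times.size != self.peak_amplitudes.size:
            raise ValueError("peak times and amplitudes must align")
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.peak_times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"peak_time_s": self.peak_times,
                             "amplitude_mV": self.peak_amplitudes})


@dataclass
class RRSeries:
    """Ordered inter-beat (RR) intervals in milliseconds.

    ``end_times`` holds the absolute time (s) of the R peak that closes
    each interval; ``artifact`` flags intervals outside the physiological
    band used by the windowing effectiveness rule.
    """

    intervals: np.ndarray
    end_times: np.ndarray
    artifact: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.end_times = np.asarray(self.end_times, dtype=float)
        if self.intervals.size != self.end_times.size:
            raise ValueError("intervals and end_times must align")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must be positive")
        if self.artifact is None:
            self.artifact = np.zeros(self.intervals.size, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)

    @property
    def n(self) -> int:
        return self.intervals.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"end_time_s": self.end_times,
                             "rr_ms": self.intervals,
                             "artifact_flag": self.artifact.astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RRSeries":
        df = pd.read_csv(path)
        art = df["artifact_flag"].to_numpy(dtype=bool) if "artifact_flag" in df else None
        return cls(intervals=df["rr_ms"].to_numpy(),
                   end_times=df["end_time_s"].to_numpy(), artifact=art)
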