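"""The 21 HRV indexes computed per 100-s RR window.

Time domain (T1-T8): AVNN, AVHR, SDNN, CV, RMSSD, SDSD, pNN50, pNN20.
Frequency domain (F1-F8): LF, LF%, LFnorm, HF, HF%, HFnorm, TP, LF/HF,
with LF = 0.04-0.15 Hz and HF = 0.15-0.4 Hz band power of the RR series
resampled to a uniform grid.
Non-linear (N1-N5): Poincare SD1/SD2 and ellipse area S = pi*SD1*SD2,
plus the ternary-difference scatter quadrant shares A++ (two consecutive
interval increases) and B-- (two consecutive decreases).

Naming note: SD1 here is the dispersion perpendicular to the identity
line of the lag-1 Poincare plot (the short axis) and SD2 the dispersion
along it, the universal convention; some sources label the axes the
other way around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signals import RRSeries

__all__ = [
    "SpectralParams", "time_domain_features", "frequency_domain_features",
    "poincare_features", "ternary_scatter_features", "derive_band_indexes",
    "compute_feature_vector", "FEATURE_NAMES",
]

FEATURE_NAMES = [
    "T1_AVNN", "T2_AVHR", "T3_SDNN", "T4_CV", "T5_RMSSD", "T6_SDSD",
    "T7_PNN50", "T8_PNN20",
    "F1_LF", "F2_LFpercent", "F3_LFnorm", "F4_HF", "F5_HFpercent",
    "F6_HFnorm", "F7_TP", "F8_LF_HF",
    "N1_SD1", "N2_SD2", "N3_S", "N4_Aplus", "N5_Bminus",
]


class UndefinedFeatureError(ValueError):
    """Raised when a window is too short for a feature family."""


@dataclass(frozen=True)
class SpectralParams:
    """Welch spectrum settings for the frequency-domain indexes."""

    resample_rate: float = 4.0
    spectral_method: str = "welch"   # or "lomb"
    segment_length: float = 50.0     # s, 50% overlap
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.40)
    tp_band: tuple = (0.003, 0.40)

    def __post_init__(self) -> None:
        if self.lf_band[1] > self.hf_band[0] + 1e-12:
            raise ValueError("LF and HF bands must not overlap")
        if self.resample_rate <= 2 * self.hf_band[1]:
            raise ValueError("resample_rate must exceed twice the HF upper edge")
        if self.spectral_method not in ("welch", "lomb"):
            raise ValueError("spectral_method must be 'welch' or 'lomb'")


def _sd(x: np.ndarray, ddof: int = 1) -> float:
    return float(np.std(x, ddof=ddof)) if x.size > ddof else 0.0


def time_domain_features(rr: RRSeries, ddof: int = 1) -> dict:
    """AVNN, AVHR (unrounded and integer-rounded), SDNN, CV, RMSSD, SDSD,
    pNN50, pNN20."""
    x = rr.intervals
    if x.size < 2:
        raise UndefinedFeatureError("time-domain features need >= 2 intervals")
    avnn = float(np.mean(x))
    avhr = 60000.0 / avnn
    sdnn = _sd(x, ddof)
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    sdsd = _sd(d, ddof)
    pnn50 = 100.0 * float(np.mean(np.abs(d) > 50.0))
    pnn20 = 100.0 * float(np.mean(np.abs(d) > 20.0))
    return {
        "T1_AVNN": avnn,
        "T2_AVHR": avhr,
        "T2_AVHR_rounded": int(round(avhr)),
        "T3_SDNN": sdnn,
        "T4_CV": 100.0 * sdnn / avnn,
        "T5_RMSSD": rmssd,
        "T6_SDSD": sdsd,
        "T7_PNN50": pnn50,
        "T8_PNN20": pnn20,
    }


def derive_band_indexes(lf: float, hf: float, tp: float) -> dict:
    """Ratios derived from integrated band powers (ms^2).

    Returns LF%, HF% (of total power), LFnorm = LF/(LF+HF), HFnorm,
    and LF/HF.  When LF+HF or TP is zero the ratios are NaN and the
    ``undefined`` flag is set.
    """
    out = {"F1_LF": lf, "F4_HF": hf, "F7_TP": tp, "undefined": False}
    if tp > 0 and (lf + hf) > 0:
        out["F2_LFpercent"] = 100.0 * lf / tp
        out["F5_HFpercent"] = 100.0 * hf / tp
        out["F3_LFnorm"] = lf / (lf + hf)
        out["F6_HFnorm"] = hf / (lf + hf)
        out["F8_LF_HF"] = lf / hf if hf > 0 else np.inf
    else:
        out.update({"F2_LFpercent": np.nan, "F5_HFpercent": np.nan,
                    "F3_LFnorm": np.nan, "F6_HFnorm": np.nan,
                    "F8_LF_HF": np.nan, "undefined": True})
    return out


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple) -> float:
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def rr_power_spectrum(rr: RRSeries, params: SpectralParams):
    """One-sided PSD (ms^2/Hz) of the detrended interval series.

    Welch mode cubic-resamples the irregular beat series onto a uniform
    grid; Lomb mode evaluates the Lomb-Scargle periodogram directly on
    the irregular samples.
    """
    t = rr.end_times
    x = rr.intervals
    if params.spectral_method == "welch":
        grid = np.arange(t[0], t[-1], 1.0 / params.resample_rate)
        xi = CubicSpline(t, x)(grid)
        xi = sps.detrend(xi, type="linear")
        nperseg = min(int(params.segment_length * params.resample_rate), xi.size)
        freqs, psd = sps.welch(xi, fs=params.resample_rate, nperseg=nperseg,
                               noverlap=nperseg // 2, detrend=False)
    else:
        xd = x - np.polyval(np.polyfit(t, x, 1), t)
        freqs = np.linspace(params.tp_band[0], params.tp_band[1], 512)
        pgram = sps.lombscargle(t, xd, 2 * np.pi * freqs)
        # Convert the raw Lomb periodogram to density-like units; the
        # band *ratios* (norms, percents, LF/HF) are insensitive to the
        # overall scale.
        psd = pgram * 4.0 / x.size
    return freqs, psd


def frequency_domain_features(rr: RRSeries, params: SpectralParams | None = None) -> dict:
    """Band powers and derived ratios from the RR spectrum."""
    params = params or SpectralParams()
    if rr.n < 40:
        raise UndefinedFeatureError("frequency-domain features need >= 40 intervals")
    if float(np.ptp(rr.intervals)) == 0.0:
        # constant series: zero power everywhere
        return derive_band_indexes(0.0, 0.0, 0.0)
    freqs, psd = rr_power_spectrum(rr, params)
    lf = _band_power(freqs, psd, params.lf_band)
    hf = _band_power(freqs, psd, params.hf_band)
    tp = _band_power(freqs, psd, params.tp_band)
    return derive_band_indexes(lf, hf, tp)


def poincare_features(rr: RRSeries, ddof: int = 1) -> dict:
    """SD1 (perpendicular to identity line), SD2 (along it), S = pi*SD1*SD2."""
    x = rr.intervals
    if x.size < 3:
        raise UndefinedFeatureError("Poincare features need >= 3 intervals")
    a, b = x[:-1], x[1:]
    sd1 = _sd((b - a) / np.sqrt(2.0), ddof)
    sd2 = _sd((b + a) / np.sqrt(2.0), ddof)
    return {"N1_SD1": sd1, "N2_SD2": sd2, "N3_S": float(np.pi * sd1 * sd2)}


def ellipse_area(sd1: float, sd2: float) -> float:
    """Fitted-ellipse area of the Poincare plot, S = pi*SD1*SD2 (ms^2)."""
    return float(np.pi * sd1 * sd2)


def ternary_scatter_features(rr: RRSeries) -> dict:
    """Quadrant shares of the ternary-difference scatter plot.

    Each consecutive interval triple maps to the point
    (d1, d2) = (rr[k+1]-rr[k], rr[k+2]-rr[k+1]).  A++ is the share of
    points in the open first quadrant (two consecutive increases), B--
    the share in the open third quadrant (two consecutive decreases).
    """
    x = rr.intervals
    if x.size < 3:
        raise UndefinedFeatureError("ternary scatter features need >= 3 intervals")
    d = np.diff(x)
    d1, d2 = d[:-1], d[1:]
    n_pts = d1.size
    a_count = int(np.sum((d1 > 0) & (d2 > 0)))
    b_count = int(np.sum((d1 < 0) & (d2 < 0)))
    return {
        "N4_Aplus": 100.0 * a_count / n_pts,
        "N5_Bminus": 100.0 * b_count / n_pts,
        "N4_Aplus_count": a_count,
        "N5_Bminus_count": b_count,
    }


def compute_feature_vector(rr: RRSeries, spectral: SpectralParams | None = None) -> dict:
    """All 21 indexes for one window, keyed by canonical names."""
    feats = {}
    feats.update(time_domain_features(rr))
    feats.update(frequency_domain_features(rr, spectral))
    feats.update(poincare_features(rr))
    feats.update(ternary_scatter_features(rr))
    return feats
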