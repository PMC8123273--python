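import numpy as np
import pytest

from fatiguehrv import synth
from fatiguehrv.signals import RRSeries


def match_f1(detected, truth, tol=0.05):
    """Detection F1 with greedy nearest-time matching at tolerance tol (s)."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0 or truth.size == 0:
        return 0.0
    used = set()
    tp = 0
    for d in detected:
        j = int(np.argmin(np.abs(truth - d)))
        if abs(truth[j] - d) <= tol and j not in used:
            tp += 1
            used.add(j)
    precision = tp / detected.size
    recall = tp / truth.size
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@pytest.fixture(scope="session")
def clean_rr_60bpm():
    """Noise-free-ish RR series at ~60 bpm for detector round trips."""
    params = synth.StateParams(0, avnn_mean=1000.0, lf_amp=40.0,
                               hf_amp=25.0, jitter_sd=15.0)
    return synth.generate_rr_series(params, 300.0, seed=7)


@pytest.fixture()
def constant_rr():
    intervals = np.full(60, 800.0)
    return RRSeries(intervals=intervals, end_times=np.cumsum(intervals) / 1000.0)


@pytest.fixture(scope="session")
def blobs_3class():
    """Three well-separated Gaussian blobs (sigma 0.1, centers 3 sigma apart)."""
    rng = np.random.default_rng(11)
    centers = np.array([[0.0, 0.0], [0.6, 0.0], [0.0, 0.6]])
    x = np.vstack([rng.normal(c, 0.1, size=(100, 2)) for c in centers])
    y = np.repeat([0, 1, 2], 100)
    return x, y
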