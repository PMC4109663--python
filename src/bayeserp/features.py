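"""78-element feature vector per estimated single-trial ERP.

The inventory (fixed order, 78 names) is:

* five non-overlapping 200-ms windows over 0–1000 ms, each contributing
  max amplitude, max latency (ms), min amplitude, min latency (ms) and mean
  power — 25 features;
* global max amplitude, max latency (ms) and min amplitude over the whole
  window — 3 features;
* the 50 level-2 Haar approximation coefficients of the 200-sample
  waveform — 50 features.

Latency ties break toward the earliest sample; latencies are in ms after
stimulus onset.  The inventory is a documented stand-in at the published
count of 78 — the historical feature list was never enumerated — and is
exposed via ``FEATURE_NAMES`` so alternatives can be slotted in.
"""

from __future__ import annotations

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import FS_HZ, N_POST

__all__ = ["FEATURE_NAMES", "N_FEATURES", "extract_features", "standardize", "ERPFeatureExtractor"]

_N_WINDOWS = 5
_WAVELET = "haar"
_LEVEL = 2
_N_WAVELET = 50


def _build_names() -> list:
    names = []
    for w in range(_N_WINDOWS):
        names += [
            f"win{w}_max_amp",
            f"win{w}_max_lat_ms",
            f"win{w}_min_amp",
            f"win{w}_min_lat_ms",
            f"win{w}_power",
        ]
    names += ["global_max_amp", "global_max_lat_ms", "global_min_amp"]
    names += [f"haar_a{_LEVEL}_{i:02d}" for i in range(_N_WAVELET)]
    return names


FEATURE_NAMES: tuple = tuple(_build_names())
N_FEATURES: int = len(FEATURE_NAMES)  # 78


def extract_features(u: np.ndarray, fs_hz: float = FS_HZ) -> np.ndarray:
    """Compute the 78 features of one 200-sample waveform."""
    u = np.asarray(u, dtype=float)
    if u.shape != (N_POST,):
        raise ValueError(f"expected a length-{N_POST} waveform, got shape {u.shape}")
    ms_per_sample = 1000.0 / fs_hz
    out = np.empty(N_FEATURES)
    k = 0
    win = N_POST // _N_WINDOWS
    for w in range(_N_WINDOWS):
        seg = u[w * win : (w + 1) * win]
        imax = int(np.argmax(seg))
        imin = int(np.argmin(seg))
        out[k : k + 5] = (
            seg[imax],
            (w * win + imax) * ms_per_sample,
            seg[imin],
            (w * win + imin) * ms_per_sample,
            float(np.mean(seg**2)),
        )
        k += 5
    imax = int(np.argmax(u))
    out[k : k + 3] = (u[imax], imax * ms_per_sample, u[int(np.argmin(u))])
    k += 3
    approx = pywt.wavedec(u, _WAVELET, level=_LEVEL)[0]
    out[k:] = approx
    return out


def standardize(features: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """z-score with training statistics; zero-SD columns map to 0."""
    features = np.asarray(features, dtype=float)
    sds = np.asarray(sds, dtype=float)
    scale = np.where(sds > 0, sds, 1.0)
    z = (features - np.asarray(means, dtype=float)) / scale
    return np.where(sds > 0, z, 0.0)


class ERPFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: (n_epochs, 200) waveforms → (n_epochs, 78) features."""

    def __init__(self, fs_hz: float = FS_HZ):
        self.fs_hz = fs_hz

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_POST:
            raise ValueError(f"X must be (n_epochs, {N_POST}), got {X.shape}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_POST:
            raise ValueError(f"X must be (n_epochs, {N_POST}), got {X.shape}")
        return np.stack([extract_features(row, self.fs_hz) for row in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
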