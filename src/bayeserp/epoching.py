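"""Epoch extraction and baseline correction.

Epochs span 500 ms before to 1000 ms after each stimulus onset (100 + 200
samples at 200 Hz); the onset sample is the first poststimulus sample.
Baseline correction subtracts the prestimulus mean from the whole sweep so
the prestimulus segment is exactly zero-mean for AR identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .simulate import FS_HZ, N_PRE, N_POST, RawEpoch

__all__ = ["ContinuousRecording", "extract_epochs", "baseline_correct", "baseline_correct_array"]


@dataclass(frozen=True)
class ContinuousRecording:
    """Single-channel recording with stimulus onsets (sample indices) and labels."""

    samples: np.ndarray
    fs_hz: float
    stimulus_onsets: list
    stimulus_labels: list

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        onsets = [int(o) for o in self.stimulus_onsets]
        if len(onsets) != len(self.stimulus_labels):
            raise ValueError("one label per onset required")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "stimulus_onsets", onsets)


def extract_epochs(
    rec: ContinuousRecording,
    n_pre: int = N_PRE,
    n_post: int = N_POST,
    subject_id: str = "",
    day: str = "",
    session: int = 0,
) -> list:
    """Cut fixed [onset - n_pre, onset + n_post) windows around each onset.

    Onsets too close to the recording edges are rejected with a warning; all
    returned epochs have exactly ``n_pre`` + ``n_post`` samples.
    """
    epochs = []
    n = rec.samples.size
    for onset, label in zip(rec.stimulus_onsets, rec.stimulus_labels):
        if onset - n_pre < 0 or onset + n_post > n:
            warnings.warn(
                f"onset {onset} too close to recording edge; epoch rejected",
                stacklevel=2,
            )
            continue
        epochs.append(
            RawEpoch(
                pre=rec.samples[onset - n_pre : onset].copy(),
                post=rec.samples[onset : onset + n_post].copy(),
                label=label,
                subject_id=subject_id,
                day=day,
                session=session,
                fs_hz=rec.fs_hz,
            )
        )
    return epochs


def baseline_correct(epoch: RawEpoch) -> RawEpoch:
    """Subtract the prestimulus mean from both segments (idempotent)."""
    baseline = float(np.mean(epoch.pre))
    return replace(epoch, pre=epoch.pre - baseline, post=epoch.post - baseline)


def baseline_correct_array(X: np.ndarray, n_pre: int = N_PRE) -> np.ndarray:
    """Row-wise baseline correction of stacked (n_epochs, n_pre + n_post) sweeps."""
    X = np.asarray(X, dtype=float)
    return X - X[:, :n_pre].mean(axis=1, keepdims=True)
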