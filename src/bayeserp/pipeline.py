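"""The full single-channel pipeline as one sklearn Pipeline.

Smoothing → 78 features → RBF SVM.  ``fit`` reproduces calibration:
per-epoch discrepancy-tuned smoothing (and γ* stored for later), feature
standardization and hyperparameter selection on the calibration epochs.
``predict`` reproduces testing: fixed-γ* smoothing of new epochs, features
standardized with the training statistics, hard SVM labels.
"""

from __future__ import annotations

from sklearn.pipeline import Pipeline

from .classify import P300SVM
from .features import ERPFeatureExtractor
from .smoother import BayesianERPSmoother

__all__ = ["make_single_channel_pipeline"]


def make_single_channel_pipeline(
    random_state=None,
    smoother_kwargs: dict | None = None,
    svm_kwargs: dict | None = None,
) -> Pipeline:
    """Compose the smoother, feature extractor and classifier."""
    return Pipeline(
        [
            ("smoother", BayesianERPSmoother(**(smoother_kwargs or {}))),
            ("features", ERPFeatureExtractor()),
            ("svm", P300SVM(random_state=random_state, **(svm_kwargs or {}))),
        ]
    )
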