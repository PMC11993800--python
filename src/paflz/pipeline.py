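"""Scikit-learn transformer wrappers around coarse graining and complexity.

These make the signal -> binary string -> complexity pipeline composable
with sklearn ``Pipeline`` and model selection: each transformer maps a
matrix of signals (one row per signal) to a binary matrix or a complexity
column.  The module-level functions in :mod:`paflz.signal_prep` and
:mod:`paflz.complexity` remain the primitive interface; these classes are
thin, stateless adapters (``fit`` only validates).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from . import complexity as cx
from . import signal_prep as sp


class _RowwiseBinarizer(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        return np.stack([self._binarize_row(row) for row in X])


class MedianBinarizer(_RowwiseBinarizer):
    """Threshold-crossing coarse graining: per-row median threshold."""

    def _binarize_row(self, row):
        return np.frombuffer(
            sp.threshold_crossing(row).encode(), dtype=np.uint8
        ) - ord("0")


class TwoMeansBinarizer(_RowwiseBinarizer):
    """Two-centroid 1-D k-means coarse graining per row."""

    def __init__(self, init_deflection=None, tolerance=None):
        self.init_deflection = init_deflection
        self.tolerance = tolerance

    def _binarize_row(self, row):
        s = sp.kmeans_binarize(row, self.init_deflection, self.tolerance)
        return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


class FiducialBinarizer(_RowwiseBinarizer):
    """Beat/feature-detection coarse graining (R peaks only, or all waves)."""

    def __init__(self, fs=500, waves="all"):
        self.fs = fs
        self.waves = waves

    def _binarize_row(self, row):
        fid = sp.detect_fiducials(row, self.fs)
        if self.waves == "r":
            s = sp.beat_detection_binarize(fid, row.size)
        else:
            s = sp.feature_detection_binarize(fid, row.size)
        return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


class ComplexityScorer(TransformerMixin, BaseEstimator):
    """Map each binary row to its (normalized) complexity value.

    ``algorithm`` is one of LZ76, LZ78, Ti; output shape is (n_rows, 1).
    """

    def __init__(self, algorithm="LZ76", normalized=True):
        self.algorithm = algorithm
        self.normalized = normalized

    def fit(self, X, y=None):
        X = check_array(X)
        if not np.isin(np.unique(X), (0, 1)).all():
            raise ValueError("ComplexityScorer expects a binary matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        strings = ["".join("1" if v else "0" for v in row) for row in X]
        vals = [cx.score(s, self.algorithm, self.normalized) for s in strings]
        return np.asarray(vals, dtype=float)[:, None]
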