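"""Feature normalization and inter-subject distances.

Counts differ wildly between symptom superclasses (weakness and sensory findings
dominate raw counts), so each column is min–max scaled onto [0, 1] before any
network is built.  Subject dissimilarity is the cosine distance between
normalized feature vectors; Pearson (correlation) and Euclidean distances are
available behind the same interface but are not the default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

_METRICS = ("cosine", "euclidean", "correlation")


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Per-column min–max scaling onto [0, 1].

    value = (count − min_c) / (max_c − min_c).  A constant column carries no
    subtyping signal: it maps to all zeros (with a logged warning) so it drops
    out of cosine numerators entirely.  Idempotent on its own output.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MinMaxNormalizer":
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 subjects to normalize")
        self.min_ = X.min(axis=0).astype(float)
        self.range_ = (X.max(axis=0) - X.min(axis=0)).astype(float)
        constant = self.range_ == 0
        if constant.any():
            logger.warning(
                "constant column(s) mapped to zero: %s", list(X.columns[constant])
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).astype(float)
        rng = self.range_.replace(0, np.inf)  # constant columns -> 0
        return (X - self.min_) / rng


def normalize_minmax(counts: pd.DataFrame) -> pd.DataFrame:
    """Min–max scale a count matrix onto [0, 1] (fit and transform in one call)."""
    return MinMaxNormalizer().fit_transform(counts)


def cosine_distance(u, v) -> float:
    """1 − u·v / (‖u‖‖v‖).  Zero vectors are a hard error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance is undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


class PairwiseDistances(BaseEstimator, TransformerMixin):
    """All-pairs subject distances from a feature matrix.

    Parameters
    ----------
    metric : {"cosine", "euclidean", "correlation"}
        Cosine is the default (the metric retained for the network analysis).
    """

    def __init__(self, metric: str = "cosine"):
        self.metric = metric

    def fit(self, X=None, y=None) -> "PairwiseDistances":
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}, got {self.metric!r}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        X = pd.DataFrame(X).astype(float)
        if len(X) < 2:
            raise ValueError("need at least 2 subjects for a distance matrix")
        if self.metric in ("cosine", "correlation"):
            norms = np.linalg.norm(X.values, axis=1)
            if (norms == 0).any():
                bad = list(X.index[norms == 0])
                raise ValueError(
                    f"zero feature vector(s) for subject(s) {bad}; "
                    "run empty-subject filtering first"
                )
        d = squareform(pdist(X.values, metric=self.metric))
        d = np.clip(d, 0.0, None)  # guard tiny negative rounding
        if self.metric in ("cosine", "correlation"):
            d[d < 1e-12] = 0.0  # parallel vectors are exactly distance 0
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=X.index, columns=X.index)


def distance_matrix(features: pd.DataFrame, metric: str = "cosine") -> pd.DataFrame:
    """Symmetric zero-diagonal distance matrix over subjects (rows of ``features``)."""
    return PairwiseDistances(metric).fit().transform(features)
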