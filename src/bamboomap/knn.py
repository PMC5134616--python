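"""Weighted k-nearest-neighbour classification over segment features.

The baseline classifier: each query segment is assigned by (optionally
distance-weighted) majority voting among its k nearest training
samples in standardized feature space.  The neighbour sets produced
here — feature distances, centroid lags and weights — are exactly what
the geostatistically weighted variant consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .samples import SampleSet

EPS = 1e-6  # inverse-distance regularizer


@dataclass
class NeighborSet:
    """K feature-space neighbours for each query segment.

    Arrays have shape ``(n_query, k)`` and are sorted by feature
    distance within each row.  ``lags`` are Euclidean centroid
    distances in pixels between query and neighbour.
    """

    query_ids: np.ndarray          # (n_query,)
    neighbor_index: np.ndarray     # (n_query, k) row index into training set
    classes: np.ndarray            # (n_query, k) neighbour class labels
    distances: np.ndarray          # (n_query, k) feature-space distance
    lags: np.ndarray               # (n_query, k) centroid lag, pixels
    weights: np.ndarray            # (n_query, k) omega > 0
    train_classes: np.ndarray      # (n_train,) class labels of training set

    @property
    def k(self) -> int:
        return self.neighbor_index.shape[1]


@dataclass
class ClassificationResult:
    """Predicted class and probability vector per segment."""

    segment_ids: np.ndarray
    class_names: list[str]
    proba: np.ndarray              # (n, M), rows sum to 1
    predicted: np.ndarray          # (n,) class labels

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proba, columns=[f"p_{c}" for c in self.class_names])
        df.insert(0, "segment_id", self.segment_ids)
        df.insert(1, "predicted", self.predicted)
        return df


def find_neighbors(train: SampleSet, query_features: pd.DataFrame, k: int,
                   omega_scheme: str = "uniform",
                   feature_names: list[str] | None = None) -> NeighborSet:
    """K nearest training samples per query, in standardized feature space.

    Features are standardized with training-set statistics only.
    ``omega_scheme`` is ``uniform`` (omega = 1) or ``inverse_distance``
    (omega = 1 / (d + 1e-6)).  ``query_features`` must be indexed by
    segment id and carry centroid ``row``/``col`` columns.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if k > len(train):
        raise ValueError(f"k={k} exceeds training size {len(train)}")
    if omega_scheme not in ("uniform", "inverse_distance"):
        raise ValueError(f"unknown omega scheme {omega_scheme!r}")
    names = feature_names or train.feature_names
    Xt = train.features(names)
    mean, sd = Xt.mean(axis=0), Xt.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Zt = (Xt - mean) / sd
    Xq = query_features[names].to_numpy(dtype=np.float64)
    Zq = (Xq - mean) / sd

    nn = NearestNeighbors(n_neighbors=k).fit(Zt)
    dist, idx = nn.kneighbors(Zq)

    train_cent = train.centroids()
    query_cent = query_features[["row", "col"]].to_numpy(dtype=np.float64)
    lags = np.linalg.norm(train_cent[idx] - query_cent[:, None, :], axis=2)

    if omega_scheme == "uniform":
        weights = np.ones_like(dist)
    else:
        weights = 1.0 / (dist + EPS)
    return NeighborSet(
        query_ids=query_features.index.to_numpy(),
        neighbor_index=idx,
        classes=train.labels()[idx],
        distances=dist,
        lags=lags,
        weights=weights,
        train_classes=train.labels(),
    )


def _tie_break(scores: np.ndarray, neighbors: NeighborSet,
               class_names: list[str]) -> np.ndarray:
    """Argmax with ties resolved toward the nearest neighbour's class
    among the tied classes (deterministic, data-driven)."""
    n, _ = scores.shape
    out = np.empty(n, dtype=object)
    for i in range(n):
        row = scores[i]
        top = row.max()
        tied = np.flatnonzero(np.isclose(row, top, rtol=0, atol=1e-12))
        if len(tied) == 1:
            out[i] = class_names[tied[0]]
            continue
        tied_set = {class_names[j] for j in tied}
        choice = None
        for c in neighbors.classes[i]:  # sorted by feature distance
            if c in tied_set:
                choice = c
                break
        out[i] = choice if choice is not None else class_names[min(tied)]
    return out


def knn_classify(neighbors: NeighborSet,
                 class_names: list[str] | None = None) -> ClassificationResult:
    """Weighted majority vote: p(m) ∝ sum_k omega_k * I(c(k) = m)."""
    if class_names is None:
        class_names = sorted(np.unique(neighbors.train_classes))
    n = len(neighbors.query_ids)
    scores = np.zeros((n, len(class_names)))
    for mi, m in enumerate(class_names):
        scores[:, mi] = (neighbors.weights * (neighbors.classes == m)).sum(axis=1)
    proba = scores / scores.sum(axis=1, keepdims=True)
    predicted = _tie_break(scores, neighbors, class_names)
    return ClassificationResult(
        segment_ids=neighbors.query_ids,
        class_names=class_names,
        proba=proba,
        predicted=predicted,
    )
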