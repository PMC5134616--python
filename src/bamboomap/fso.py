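"""Feature-space optimization: class-separability subset search.

The separability of a feature subset is scored as the mean, over all
training samples, of each sample's minimum Euclidean distance to any
sample of a different class, after standardizing every feature to unit
variance over the training samples.  All non-empty subsets of the
candidate features are enumerated (the candidate list is capped to
keep this exact), and the best subset per dimension is reported.
This is a stand-in for the proprietary separation metric of commercial
OBIA software, which is not published; absolute distances are
therefore not comparable across implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .samples import SampleSet

log = logging.getLogger(__name__)

MAX_CANDIDATES = 20


@dataclass
class SeparabilityCurve:
    """Best feature subset and separation distance per dimension."""

    table: pd.DataFrame  # columns: dimension, features (tuple), distance

    def best(self) -> tuple[tuple[str, ...], float]:
        i = self.table["distance"].idxmax()
        return self.table.loc[i, "features"], float(self.table.loc[i, "distance"])


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0)
    return X, sd


def separation_distance(samples: SampleSet, subset: list[str]) -> float:
    """Mean nearest-other-class distance on standardized features.

    Zero-variance features in the subset are skipped with a warning.
    """
    labels = samples.labels()
    if len(np.unique(labels)) < 2:
        raise ValueError("separability needs at least two classes")
    X = samples.features(list(subset))
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.all():
        skipped = [f for f, u in zip(subset, usable) if not u]
        log.warning("skipping zero-variance features: %s", skipped)
        X = X[:, usable]
        sd = sd[usable]
        if X.shape[1] == 0:
            raise ValueError("no usable features in subset")
    Z = X / sd
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    other = labels[:, None] != labels[None, :]
    D = np.where(other, D, np.inf)
    return float(D.min(axis=1).mean())


def optimize_features(samples: SampleSet, candidates: list[str],
                      exclude_classes: list[str] | None = None,
                      ) -> SeparabilityCurve:
    """Exhaustive best-subset search per dimension.

    ``exclude_classes`` removes classes (e.g. barren land and shadow,
    which are trivially separable and would dominate the metric) before
    scoring.  Ties are broken by lexicographic feature order.
    """
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidates)} candidates exceed the exhaustive-search "
            f"bound of {MAX_CANDIDATES}")
    work = samples
    if exclude_classes:
        keep = [c for c in samples.classes if c not in exclude_classes]
        work = samples.subset_classes(keep)
    rows = []
    for d in range(1, len(candidates) + 1):
        best_subset, best_dist = None, -np.inf
        for subset in combinations(sorted(candidates), d):
            dist = separation_distance(work, list(subset))
            if dist > best_dist:
                best_subset, best_dist = subset, dist
        rows.append({"dimension": d, "features": best_subset,
                     "distance": best_dist})
    return SeparabilityCurve(table=pd.DataFrame(rows))
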