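"""Covariance PCA over the per-segment feature table.

Used to rank feature importance before training expansion: the
spectral bands loading most heavily on the first component are the
ones used for the mu +/- t*sigma expansion intervals.  The analysis is
on mean-centred but unstandardized features (covariance, not
correlation, PCA), so DN-scale bands dominate the leading components
by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Component standard deviations, variance fractions and loadings."""

    component_sds: np.ndarray        # descending
    proportions: np.ndarray          # variance fractions, sum 1
    cumulative: np.ndarray
    loadings: pd.DataFrame           # feature x PC, unit-norm columns

    @property
    def feature_names(self) -> list[str]:
        return list(self.loadings.index)


def pca(table: pd.DataFrame, features: list[str] | None = None) -> PcaResult:
    """Eigendecomposition of the feature covariance matrix.

    Zero-variance features are excluded with a warning.  The sign of
    each component is fixed by forcing its largest-magnitude loading to
    be negative (cosmetic; makes runs comparable).
    """
    if features is None:
        features = [c for c in table.columns if c not in ("row", "col", "area")]
    X = table[features].to_numpy(dtype=np.float64)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 segments and 2 features")
    var = X.var(axis=0)
    # relative tolerance: a constant column's variance is only zero up
    # to floating-point accumulation
    keep = var > max(var.max(), 1.0) * 1e-15
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        log.warning("excluding zero-variance features from PCA: %s", dropped)
        features = [f for f, k in zip(features, keep) if k]
        X = X[:, keep]
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign rule: largest-|loading| entry of each PC made negative
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] > 0:
            eigvec[:, j] = -eigvec[:, j]
    sds = np.sqrt(eigval)
    props = eigval / eigval.sum()
    pcs = [f"PC{j + 1}" for j in range(len(eigval))]
    return PcaResult(
        component_sds=sds,
        proportions=props,
        cumulative=np.cumsum(props),
        loadings=pd.DataFrame(eigvec, index=features, columns=pcs),
    )


def expansion_bands(result: PcaResult, spectral_features: list[str],
                    top_pc: int = 1, n_bands: int = 5,
                    override: list[str] | None = None) -> list[str]:
    """Spectral bands with the largest |loading| on a leading component.

    Restricted to ``spectral_features`` (texture/geometry features never
    qualify for reflectance intervals).  ``override`` pins an explicit
    band list, e.g. the green/yellow/red-edge/NIR1/NIR2 choice used in
    the original campaign.
    """
    if override is not None:
        unknown = set(override) - set(result.feature_names)
        if unknown:
            raise KeyError(f"override bands not in PCA result: {sorted(unknown)}")
        return list(override)
    col = f"PC{top_pc}"
    load = result.loadings.loc[
        [f for f in spectral_features if f in result.loadings.index], col
    ]
    ranked = load.abs().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_bands])
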