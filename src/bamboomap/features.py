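"""Per-segment features: band means, GLCM texture, geometry, centroids.

Every feature is computed per image object (segment).  The grey-level
co-occurrence matrix is accumulated only over pixel pairs whose both
members lie inside the segment, at unit offset in the four standard
directions (0, 45, 90, 135 degrees), symmetrized and normalized; the
eight derived statistics follow the standard Haralick-style
definitions.  Geometry uses the principal axes of the member-pixel
coordinates: length and width are the oriented bounding extents,
shape index = perimeter / (4 * sqrt(area)) and
border index = perimeter / (2 * (length + width)), with the perimeter
counted as exposed pixel edges (4-connectivity).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .segmentation import SegmentMap

log = logging.getLogger(__name__)

GLCM_FEATURE_NAMES = (
    "glcm_mean",
    "glcm_std",
    "glcm_homogeneity",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_entropy",
    "glcm_correlation",
    "glcm_asm",
)

GEOMETRY_FEATURE_NAMES = ("length_width", "border_index", "shape_index")

#: (drow, dcol) unit offsets for 0, 45, 90 and 135 degrees.
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def segment_means(raster: np.ndarray, seg: SegmentMap,
                  band_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Arithmetic mean of each band over each segment.

    Returns a DataFrame indexed by segment id with one column per band.
    """
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim == 2:
        r = r[None]
    if r.shape[1:] != seg.shape:
        raise ValueError("raster and segment map shapes differ")
    if band_names is None:
        band_names = tuple(f"band_{i + 1}" for i in range(r.shape[0]))
    lab = seg.labels.ravel()
    counts = np.bincount(lab, minlength=seg.n_segments + 1)[1:]
    data = {}
    for bi, name in enumerate(band_names):
        sums = np.bincount(lab, weights=r[bi].ravel(),
                           minlength=seg.n_segments + 1)[1:]
        data[name] = sums / counts
    return pd.DataFrame(data, index=pd.RangeIndex(1, seg.n_segments + 1,
                                                  name="segment_id"))


def centroids(seg: SegmentMap) -> pd.DataFrame:
    """Mean member-pixel (row, col) per segment, plus pixel area.

    The mean may fall outside a concave segment; only inter-centroid
    distances are consumed downstream, so this is accepted.
    """
    lab = seg.labels.ravel()
    rows, cols = np.indices(seg.shape)
    counts = np.bincount(lab, minlength=seg.n_segments + 1)[1:]
    rsum = np.bincount(lab, weights=rows.ravel(),
                       minlength=seg.n_segments + 1)[1:]
    csum = np.bincount(lab, weights=cols.ravel(),
                       minlength=seg.n_segments + 1)[1:]
    return pd.DataFrame(
        {"row": rsum / counts, "col": csum / counts, "area": counts},
        index=pd.RangeIndex(1, seg.n_segments + 1, name="segment_id"),
    )


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Linear rescale of a band to integer grey levels 0..levels-1."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    b = np.asarray(band, dtype=np.float64)
    lo, hi = b.min(), b.max()
    if hi == lo:
        return np.zeros(b.shape, dtype=np.int64)
    q = np.floor((b - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _glcm_stats(P: np.ndarray, levels: int) -> dict[str, float]:
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = P.sum(axis=1)
    mu = float((i * pi).sum())
    var = float(((i - mu) ** 2 * pi).sum())
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-(P[P > 0] * np.log(P[P > 0])).sum())
    if sd > 0:
        corr = float((((ii - mu) * (jj - mu) * P).sum()) / (sd * sd))
    else:
        corr = 0.0  # degenerate: constant segment
    return {
        "glcm_mean": mu,
        "glcm_std": sd,
        "glcm_homogeneity": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * P).sum()),
        "glcm_dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "glcm_entropy": ent,
        "glcm_correlation": corr,
        "glcm_asm": float((P ** 2).sum()),
    }


def glcm_features(band_raster: np.ndarray, seg: SegmentMap, levels: int = 32,
                  offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                  ) -> pd.DataFrame:
    """Eight GLCM texture statistics per segment.

    Co-occurrences are counted for every offset in ``offsets`` over
    pixel pairs fully inside the segment, pooled across offsets,
    symmetrized and normalized to a probability matrix per segment.
    Segments with no valid pair get all-zero texture (logged).
    """
    q = quantize(band_raster, levels)
    if q.shape != seg.shape:
        raise ValueError("raster and segment map shapes differ")
    lab = seg.labels
    n_seg = seg.n_segments
    L2 = levels * levels
    counts = np.zeros(n_seg * L2, dtype=np.float64)
    n_rows, n_cols = q.shape
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), min(n_rows, n_rows - dr))
        c0 = slice(max(0, -dc), min(n_cols, n_cols - dc))
        r1 = slice(max(0, dr), min(n_rows, n_rows + dr))
        c1 = slice(max(0, dc), min(n_cols, n_cols + dc))
        sa, sb = lab[r0, c0].ravel(), lab[r1, c1].ravel()
        same = sa == sb
        la, lb = q[r0, c0].ravel()[same], q[r1, c1].ravel()[same]
        sid = sa[same] - 1
        # symmetric accumulation
        np.add.at(counts, sid * L2 + la * levels + lb, 1.0)
        np.add.at(counts, sid * L2 + lb * levels + la, 1.0)
    counts = counts.reshape(n_seg, levels, levels)
    rows = []
    empty = []
    for s in range(n_seg):
        tot = counts[s].sum()
        if tot == 0:
            empty.append(s + 1)
            rows.append(dict.fromkeys(GLCM_FEATURE_NAMES, 0.0))
        else:
            rows.append(_glcm_stats(counts[s] / tot, levels))
    if empty:
        log.warning("%d segment(s) have no co-occurring pixel pair; "
                    "texture set to zero (first ids: %s)",
                    len(empty), empty[:5])
    return pd.DataFrame(rows, index=pd.RangeIndex(1, n_seg + 1,
                                                  name="segment_id"))


def _perimeters(seg: SegmentMap) -> np.ndarray:
    """Exposed 4-connectivity pixel-edge count per segment."""
    lab = seg.labels
    per = 4.0 * np.bincount(lab.ravel(), minlength=seg.n_segments + 1)[1:]
    for axis in (0, 1):
        a = np.take(lab, range(lab.shape[axis] - 1), axis=axis)
        b = np.take(lab, range(1, lab.shape[axis]), axis=axis)
        shared = a[a == b]
        per -= 2.0 * np.bincount(shared, minlength=seg.n_segments + 1)[1:]
    return per


def geometry_features(seg: SegmentMap) -> pd.DataFrame:
    """Length/width ratio, border index and shape index per segment.

    Length and width are the extents of the member pixels along the
    principal axes of their coordinate covariance (each extent at least
    one pixel).
    """
    lab = seg.labels.ravel()
    rows, cols = np.indices(seg.shape)
    coords = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(np.float64)
    perim = _perimeters(seg)
    order = np.argsort(lab, kind="stable")
    sorted_lab = lab[order]
    bounds = np.searchsorted(sorted_lab, np.arange(1, seg.n_segments + 2))
    out = np.empty((seg.n_segments, 3))
    for s in range(seg.n_segments):
        pts = coords[order[bounds[s]:bounds[s + 1]]]
        c = pts - pts.mean(axis=0)
        cov = c.T @ c / len(pts)
        _, vecs = np.linalg.eigh(cov)
        proj = c @ vecs[:, ::-1]  # major axis first
        ext = proj.max(axis=0) - proj.min(axis=0) + 1.0
        length, width = max(ext[0], ext[1]), min(ext[0], ext[1])
        area = float(len(pts))
        out[s] = (
            length / width,
            perim[s] / (2.0 * (length + width)),
            perim[s] / (4.0 * np.sqrt(area)),
        )
    return pd.DataFrame(out, columns=list(GEOMETRY_FEATURE_NAMES),
                        index=pd.RangeIndex(1, seg.n_segments + 1,
                                            name="segment_id"))


def build_segment_table(raster: np.ndarray, seg: SegmentMap,
                        band_names: tuple[str, ...] | None = None,
                        glcm_band: int = 6, glcm_levels: int = 32,
                        ) -> pd.DataFrame:
    """Full per-segment feature table.

    Columns: centroid ``row``/``col``, ``area``, one mean per band, the
    eight GLCM statistics (computed on band index ``glcm_band``,
    default NIR1) and the three geometry indices.  Indexed by segment
    id.
    """
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim == 2:
        r = r[None]
    parts = [
        centroids(seg),
        segment_means(r, seg, band_names),
        glcm_features(r[glcm_band], seg, levels=glcm_levels),
        geometry_features(seg),
    ]
    table = pd.concat(parts, axis=1)
    if table.columns.duplicated().any():
        raise ValueError("duplicate feature names in segment table")
    return table
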