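"""Image segmentation: a region-merging stand-in and label ingestion.

The segmentation used here is a deliberately simple greedy pairwise
region merging on the 4-neighbour region-adjacency graph: at each step
the merge with the smallest added spectral variance (the Ward cost
``n1*n2/(n1+n2) * ||mean1 - mean2||^2`` summed over bands) is applied,
until the cheapest merge would cost more than ``scale**2``.  It plays
the role of a multi-resolution segmentation in the pipeline but makes
no claim of equivalence to any commercial implementation; externally
produced label rasters can be ingested instead.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np


@dataclass
class SegmentMap:
    """Per-pixel segment ids, contiguous from 1 to ``n_segments``."""

    labels: np.ndarray  # int raster, values in 1..n_segments
    n_segments: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.min() < 1 or lab.max() > self.n_segments:
            raise ValueError("segment ids must lie in 1..n_segments")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def ingest_segments(label_raster: np.ndarray) -> SegmentMap:
    """Relabel an arbitrary integer label raster to contiguous ids 1..n."""
    lab = np.asarray(label_raster)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ValueError("segment label raster must be integer-typed")
    if lab.min() < 0:
        raise ValueError("segment labels must be non-negative")
    uniq, inv = np.unique(lab, return_inverse=True)
    new = (inv + 1).astype(np.int32).reshape(lab.shape)
    return SegmentMap(labels=new, n_segments=len(uniq))


def segment(raster: np.ndarray, scale: float) -> SegmentMap:
    """Greedy variance-minimizing region merging.

    Parameters
    ----------
    raster
        Multiband image, shape ``(n_bands, n_rows, n_cols)`` (a 2-D
        array is treated as a single band).
    scale
        Scale parameter; merging stops once the cheapest remaining merge
        has Ward cost greater than ``scale**2``.  Larger scale gives
        fewer, larger segments.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    r = np.asarray(raster, dtype=np.float64)
    if r.ndim == 2:
        r = r[None]
    if r.ndim != 3:
        raise ValueError("raster must be 2-D or (bands, rows, cols)")
    n_bands, n_rows, n_cols = r.shape
    n_px = n_rows * n_cols
    flat = r.reshape(n_bands, n_px).T  # (n_px, n_bands)

    # union-find over current regions
    parent = np.arange(n_px)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    count = np.ones(n_px)
    total = flat.copy()  # per-region band sums
    neighbors: list[set[int]] = [set() for _ in range(n_px)]
    idx = np.arange(n_px).reshape(n_rows, n_cols)
    for a, b in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
        for i, j in zip(a.ravel(), b.ravel()):
            neighbors[i].add(int(j))
            neighbors[j].add(int(i))

    def cost(i: int, j: int) -> float:
        di = total[i] / count[i] - total[j] / count[j]
        return float(count[i] * count[j] / (count[i] + count[j]) * (di @ di))

    heap: list[tuple[float, int, int]] = []
    for i in range(n_px):
        for j in neighbors[i]:
            if i < j:
                heap.append((cost(i, j), i, j))
    heapq.heapify(heap)

    max_cost = scale * scale
    while heap:
        c, i, j = heapq.heappop(heap)
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if (i, j) != (min(ri, rj), max(ri, rj)):
            # stale entry: re-evaluate for current roots
            a, b = min(ri, rj), max(ri, rj)
            heapq.heappush(heap, (cost(a, b), a, b))
            continue
        if c > max_cost:
            break
        # merge rj into ri (keep the smaller index as root for determinism)
        parent[rj] = ri
        count[ri] += count[rj]
        total[ri] += total[rj]
        merged_nb = {find(x) for x in (neighbors[ri] | neighbors[rj])}
        merged_nb.discard(ri)
        neighbors[ri] = merged_nb
        neighbors[rj] = set()
        for nb in merged_nb:
            neighbors[nb].discard(rj)
            neighbors[nb].add(ri)
            a, b = min(ri, nb), max(ri, nb)
            heapq.heappush(heap, (cost(a, b), a, b))

    roots = np.array([find(i) for i in range(n_px)])
    return ingest_segments(roots.reshape(n_rows, n_cols).astype(np.int64))
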