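"""Shared fixtures: one small synthetic scene, segmented, with features.

Session-scoped so the moderately expensive raster work is done once.
"""

import numpy as np
import pandas as pd
import pytest

from bamboomap.features import build_segment_table
from bamboomap.samples import FIELD, SampleSet
from bamboomap.scene import BAND_NAMES, SceneConfig, generate_scene
from bamboomap.segmentation import segment


@pytest.fixture(scope="session")
def small_scene():
    cfg = SceneConfig(n_rows=96, n_cols=96, correlation_range=20.0, seed=3)
    class_map, raster = generate_scene(cfg)
    return cfg, class_map, raster


@pytest.fixture(scope="session")
def small_segmented(small_scene):
    cfg, class_map, raster = small_scene
    seg = segment(raster, 10.0)
    table = build_segment_table(raster, seg, band_names=BAND_NAMES)
    return cfg, class_map, raster, seg, table


def random_sample_set(n: int, n_classes: int, n_features: int, seed: int,
                      extent: float = 100.0) -> SampleSet:
    """Random labelled points with features; shared test helper."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "segment_id": np.arange(1, n + 1),
        "class_label": [f"class_{i}" for i in rng.integers(0, n_classes, n)],
        "provenance": FIELD,
        "row": rng.uniform(0, extent, n),
        "col": rng.uniform(0, extent, n),
    })
    for j in range(n_features):
        df[f"f{j}"] = rng.normal(size=n)
    return SampleSet(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
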