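"""Simulation experiments over the synthetic study scene.

The study scene emulates the regime of the original campaign at a
tractable scale: class patches much larger than image objects
(correlation range 45 px vs ~24-px segments on a 320 x 320 raster,
about 4 200 objects) so that between-segment spatial correlation is
resolvable over many lag bins, as it is on the full-size scene the
method was developed for.

``gknn_improvement_experiment`` reproduces the classification-stage
comparison: train both classifiers on a few hundred noisily labelled
segments, fit the transition models from those same training points,
and score both on the held-out segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import assessment, geostat, knn
from .features import build_segment_table
from .pipeline import add_label_noise, segment_truth
from .samples import FIELD, from_segment_table
from .scene import BAND_NAMES, SceneConfig, generate_class_map, generate_scene
from .segmentation import segment

#: Scaled-down study scene: patches >> segments >> pixels.
STUDY_SCENE = dict(n_rows=320, n_cols=320, correlation_range=45.0)
STUDY_SCALE = 10.0
STUDY_FEATURES = ["yellow", "red", "red_edge", "nir1", "nir2", "glcm_contrast"]


@dataclass
class ImprovementResult:
    seed: int
    knn_oa: float
    gknn_oa: float
    n_train: int
    n_test: int
    bamboo_range: float


def gknn_improvement_experiment(seed: int, n_train: int = 500,
                                sg: float = 0.5, k: int = 5,
                                label_noise: float = 0.1,
                                omega_scheme: str = "inverse_distance",
                                ) -> ImprovementResult:
    """k-NN vs gk-NN overall accuracy under noisy training labels.

    Training segments are drawn uniformly from the scene's objects
    with their majority true class, then ``label_noise`` of them are
    flipped to a random other class; every remaining object is a test
    point.  Both classifiers share the same neighbour sets, so the
    comparison isolates the geostatistical reweighting.
    """
    cfg = SceneConfig(seed=seed, **STUDY_SCENE)
    class_map, raster = generate_scene(cfg)
    seg = segment(raster, STUDY_SCALE)
    table = build_segment_table(raster, seg, band_names=BAND_NAMES)
    truth = segment_truth(class_map, seg)

    rng = np.random.default_rng((seed, 11))
    ids = rng.permutation(truth.index.to_numpy())
    tr_ids, te_ids = ids[:n_train], ids[n_train:]
    train = from_segment_table(table, {int(i): truth[i] for i in tr_ids}, FIELD)
    train = add_label_noise(train, label_noise, seed)
    test = from_segment_table(table, {int(i): truth[i] for i in te_ids}, FIELD)

    neighbors = knn.find_neighbors(train, table.loc[te_ids], k,
                                   omega_scheme, STUDY_FEATURES)
    res_knn = knn.knn_classify(neighbors)
    models = geostat.fit_all_transitions(
        train, bin_width=5.0,
        max_lag=0.5 * float(np.hypot(cfg.n_rows, cfg.n_cols)))
    res_gknn = geostat.gknn_classify(
        neighbors, models,
        geostat.GkNNConfig(sg=sg, k=k, omega_scheme=omega_scheme))

    assessed = [c for c in sorted(truth.unique()) if c != "shadow"]
    oa = {}
    for name, res in (("knn", res_knn), ("gknn", res_gknn)):
        cm = assessment.confusion(res, test, class_names=assessed)
        oa[name] = assessment.accuracies(cm)["overall"]
    return ImprovementResult(
        seed=seed, knn_oa=oa["knn"], gknn_oa=oa["gknn"],
        n_train=len(train), n_test=len(test),
        bamboo_range=models[("bamboo", "bamboo")].range_)


def bamboo_range_experiment(seed: int, correlation_range: float = 70.0,
                            size: int = 512, grid_spacing: int = 10,
                            family: str = "spherical") -> float:
    """Fitted same-class transition range for bamboo on a generated map.

    Samples the class map on a regular grid (dense short-lag pair
    support) and fits one named model family; mixing families would
    conflate their differing practical-range definitions.
    """
    import pandas as pd

    from .samples import SampleSet

    cfg = SceneConfig(n_rows=size, n_cols=size,
                      correlation_range=correlation_range, seed=seed)
    class_map = generate_class_map(cfg)
    g = np.arange(grid_spacing // 2, size, grid_spacing)
    rows, cols = np.meshgrid(g, g, indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    labels = [cfg.class_names[class_map.labels[a, b]]
              for a, b in zip(rows, cols)]
    df = pd.DataFrame({
        "segment_id": np.arange(len(rows)), "class_label": labels,
        "provenance": FIELD, "row": rows, "col": cols, "dummy": 0.0})
    curves = geostat.empirical_transitions(SampleSet(df), bin_width=5.0)
    model = geostat.fit_transition_model(curves[("bamboo", "bamboo")],
                                         family=family)
    return model.range_
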