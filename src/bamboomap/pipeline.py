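"""End-to-end pipeline: scene -> segments -> features -> PCA ->
expansion -> feature optimization -> k-NN / gk-NN -> assessment.

Each stage's output is serialized under the run directory and recorded
in a manifest with a content hash, so re-runs with the same config and
seed are reproducible artefact-for-artefact.  A single global seed
fans out to per-stage substreams via ``numpy.random.default_rng((seed,
stage_index))``, so unrelated stages draw independent streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, expansion, features, fso, geostat, knn, pca
from .samples import FIELD, SampleSet, from_segment_table
from .scene import BAND_NAMES, ClassMap, SceneConfig, generate_scene, write_scene
from .segmentation import SegmentMap, segment

log = logging.getLogger(__name__)

SPECTRAL_FEATURES = list(BAND_NAMES)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs."""

    out_dir: str = "pipeline_run"
    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        n_rows=320, n_cols=320, correlation_range=45.0))
    scale: float = 10.0
    n_field_per_class: int = 4
    n_field_bamboo: int = 3
    expansion_t: dict[str, float] = field(
        default_factory=lambda: {
            "bamboo": 0.25, "coniferous": 0.65, "broadleaved": 0.40,
            "mixed_woodland": 0.25, "brush": 0.20, "barren_land": 0.85,
            "shadow": 0.25,
        })
    n_expansion_bands: int = 5
    skip_expansion: bool = False
    run_fso: bool = False
    classification_features: list[str] | None = None
    k: int = 5
    sg: float = 0.5
    omega_scheme: str = "inverse_distance"
    lag_bin_width: float = 5.0
    training_label_noise: float = 0.0
    n_test_per_class: int = 30
    seed: int = 0


def segment_truth(class_map: ClassMap, seg: SegmentMap) -> pd.Series:
    """Majority (modal) true class per segment."""
    lab = seg.labels.ravel()
    cls = class_map.labels.ravel()
    class_ids = sorted(class_map.legend)
    counts = np.zeros((seg.n_segments + 1, len(class_ids)))
    for j, cid in enumerate(class_ids):
        counts[:, j] = np.bincount(lab[cls == cid], minlength=seg.n_segments + 1)
    best = np.argmax(counts, axis=1)[1:]
    names = [class_map.legend[class_ids[j]] for j in best]
    return pd.Series(names, index=pd.RangeIndex(1, seg.n_segments + 1,
                                                name="segment_id"))


def segment_purity(class_map: ClassMap, seg: SegmentMap) -> pd.Series:
    """Fraction of segment pixels belonging to its modal class."""
    lab = seg.labels.ravel()
    cls = class_map.labels.ravel()
    class_ids = sorted(class_map.legend)
    counts = np.zeros((seg.n_segments + 1, len(class_ids)))
    for j, cid in enumerate(class_ids):
        counts[:, j] = np.bincount(lab[cls == cid], minlength=seg.n_segments + 1)
    tot = counts.sum(axis=1)
    return pd.Series((counts.max(axis=1) / np.where(tot > 0, tot, 1))[1:],
                     index=pd.RangeIndex(1, seg.n_segments + 1,
                                         name="segment_id"))


def sample_field_segments(truth: pd.Series, purity: pd.Series,
                          n_per_class: int, seed: int,
                          n_bamboo: int | None = None,
                          min_purity: float = 0.6) -> dict[int, str]:
    """Draw sparse 'field plot' labels: a few fairly pure segments per
    class, mimicking GPS ground samples along an accessible route."""
    rng = np.random.default_rng((seed, 3))
    labels: dict[int, str] = {}
    for cname in sorted(truth.unique()):
        pool = truth.index[(truth == cname) & (purity >= min_purity)]
        if len(pool) == 0:
            pool = truth.index[truth == cname]
        n = n_bamboo if (cname == "bamboo" and n_bamboo is not None) \
            else n_per_class
        n = min(n, len(pool))
        for sid in rng.choice(pool, size=n, replace=False):
            labels[int(sid)] = cname
    return labels


def add_label_noise(samples: SampleSet, fraction: float, seed: int,
                    classes: list[str] | None = None) -> SampleSet:
    """Flip a fraction of sample labels to a uniformly drawn other class."""
    if fraction == 0.0:
        return samples
    rng = np.random.default_rng((seed, 4))
    df = samples.df.copy()
    classes = classes or samples.classes
    n_flip = int(round(fraction * len(df)))
    idx = rng.choice(len(df), size=n_flip, replace=False)
    for i in idx:
        cur = df.iloc[i, df.columns.get_loc("class_label")]
        others = [c for c in classes if c != cur]
        df.iloc[i, df.columns.get_loc("class_label")] = \
            others[int(rng.integers(len(others)))]
    return SampleSet(df)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    def record(stage: str, t0: float, paths: dict[str, Path], **extra) -> None:
        manifest["stages"][stage] = {
            "duration_s": round(time.time() - t0, 3),
            "outputs": {k: str(p) for k, p in paths.items()},
            "hashes": {k: _sha256(Path(p)) for k, p in paths.items()},
            **extra,
        }
        log.info("stage %-12s done in %.2fs %s", stage,
                 time.time() - t0, extra or "")

    try:
        # 1. scene
        t0 = time.time()
        scfg = config.scene
        if scfg.seed != config.seed:
            scfg = SceneConfig(**{**asdict(scfg), "seed": config.seed})
        class_map, raster = generate_scene(scfg)
        paths = write_scene(out, scfg, class_map, raster)
        record("scene", t0, paths, n_classes=len(scfg.class_names))

        # 2. segmentation
        t0 = time.time()
        seg = segment(raster, config.scale)
        seg_path = out / "segments.csv"
        np.savetxt(seg_path, seg.labels, fmt="%d", delimiter=",")
        record("segmentation", t0, {"segments": seg_path},
               n_segments=seg.n_segments)

        # 3. features
        t0 = time.time()
        table = features.build_segment_table(raster, seg, band_names=BAND_NAMES)
        table_path = out / "segment_table.csv"
        table.to_csv(table_path)
        record("features", t0, {"table": table_path}, n_features=table.shape[1])

        # 4. field sampling + PCA band selection
        t0 = time.time()
        truth = segment_truth(class_map, seg)
        purity = segment_purity(class_map, seg)
        field_labels = sample_field_segments(
            truth, purity, config.n_field_per_class, config.seed,
            n_bamboo=config.n_field_bamboo)
        field_samples = from_segment_table(table, field_labels, FIELD)
        pca_result = pca.pca(table)
        bands = pca.expansion_bands(pca_result, SPECTRAL_FEATURES,
                                    n_bands=config.n_expansion_bands)
        pca_path = out / "pca_loadings.csv"
        pca_result.loadings.round(6).to_csv(pca_path)
        record("pca", t0, {"loadings": pca_path}, expansion_bands=bands,
               pc1_proportion=float(pca_result.proportions[0]))

        # 5. training expansion
        t0 = time.time()
        if config.skip_expansion:
            train = field_samples
            model = None
        else:
            model = expansion.fit_spectral_model(field_samples, bands,
                                                 config.expansion_t)
            train = expansion.expand_training(table, model, field_samples)
        if config.training_label_noise > 0:
            train = add_label_noise(train, config.training_label_noise,
                                    config.seed)
        train_path = out / "training_samples.csv"
        train.to_csv(train_path)
        record("expansion", t0, {"training": train_path},
               n_field=len(field_samples), n_training=len(train))

        # 6. feature optimization
        t0 = time.time()
        if config.classification_features is not None:
            feat = list(config.classification_features)
            curve = None
        elif config.run_fso:
            candidates = SPECTRAL_FEATURES + ["glcm_contrast"]
            curve = fso.optimize_features(
                train, candidates,
                exclude_classes=["barren_land", "shadow"])
            feat = list(curve.best()[0])
        else:
            feat = ["yellow", "red", "red_edge", "nir1", "nir2",
                    "glcm_contrast"]
            curve = None
        fso_path = out / "classification_features.json"
        fso_path.write_text(json.dumps(feat, indent=2))
        record("fso", t0, {"features": fso_path}, features=feat)

        # 7. k-NN classification of every segment
        t0 = time.time()
        neighbors = knn.find_neighbors(train, table, config.k,
                                       config.omega_scheme, feat)
        knn_result = knn.knn_classify(neighbors)
        knn_path = out / "classification_knn.csv"
        knn_result.to_frame().to_csv(knn_path, index=False)
        record("knn", t0, {"classification": knn_path})

        # 8. geostatistical modelling + gk-NN
        t0 = time.time()
        diag = 0.5 * float(np.hypot(*seg.shape))
        models = geostat.fit_all_transitions(
            train, bin_width=config.lag_bin_width, max_lag=diag)
        geostat.save_models(models, out / "transition_models")
        gcfg = geostat.GkNNConfig(sg=config.sg, k=config.k,
                                  omega_scheme=config.omega_scheme)
        gknn_result = geostat.gknn_classify(neighbors, models, gcfg)
        gknn_path = out / "classification_gknn.csv"
        gknn_result.to_frame().to_csv(gknn_path, index=False)
        record("gknn", t0, {"classification": gknn_path}, sg=config.sg)

        # 9. assessment on held-out test segments
        t0 = time.time()
        rng = np.random.default_rng((config.seed, 5))
        train_ids = set(train.df["segment_id"])
        assessed = [c for c in sorted(truth.unique()) if c != "shadow"]
        test_labels: dict[int, str] = {}
        for cname in assessed:
            pool = [int(i) for i in truth.index[(truth == cname)]
                    if int(i) not in train_ids]
            n = min(config.n_test_per_class, len(pool))
            if n == 0:
                continue
            for sid in rng.choice(pool, size=n, replace=False):
                test_labels[int(sid)] = cname
        test_set = from_segment_table(table, test_labels, FIELD)
        metrics = {}
        for name, result in (("knn", knn_result), ("gknn", gknn_result)):
            cm = assessment.confusion(result, test_set, class_names=assessed)
            acc = assessment.accuracies(cm)
            metrics[name] = {
                "overall_accuracy_pct": acc["overall"],
                "kappa": assessment.kappa(cm),
                "producers_pct": acc["producers"],
                "users_pct": acc["users"],
            }
            cm.to_frame().to_csv(out / f"confusion_{name}.csv")
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        record("assessment", t0, {"metrics": metrics_path},
               n_test=len(test_set),
               knn_oa=metrics["knn"]["overall_accuracy_pct"],
               gknn_oa=metrics["gknn"]["overall_accuracy_pct"])
    except Exception as exc:
        stage = f"stage_{len(manifest['stages']) + 1}"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    manifest["metrics"] = metrics
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
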