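"""Classify every object with weighted k-NN and the gk-NN blend.

Fits class-conditional transition-probability models from the
training-sample centroids (5-px lag bins, first bin excluded as the
within-object peak), classifies all objects with k = 5 under both the
plain and the geostatistically weighted vote (Sg = 0.5), and assesses
both maps against held-out objects' majority true class.

Reads:  results/segment_table.csv, results/segment_truth.csv,
        results/training_samples.csv, results/classification_features.json
Writes: results/classification_knn.csv, results/classification_gknn.csv,
        results/transition_models/, results/confusion_*.csv,
        results/assessment_metrics.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bamboomap import assessment, geostat, knn
from bamboomap.samples import FIELD, SampleSet, from_segment_table

RESULTS = Path(__file__).resolve().parents[1] / "results"
K, SG = 5, 0.5


def main() -> None:
    table = pd.read_csv(RESULTS / "segment_table.csv", index_col=0)
    truth = pd.read_csv(RESULTS / "segment_truth.csv",
                        index_col=0)["class_label"]
    train = SampleSet.from_csv(RESULTS / "training_samples.csv")
    feat = json.loads((RESULTS / "classification_features.json").read_text())

    neighbors = knn.find_neighbors(train, table, K, "inverse_distance", feat)
    res_knn = knn.knn_classify(neighbors)
    res_knn.to_frame().to_csv(RESULTS / "classification_knn.csv", index=False)

    models = geostat.fit_all_transitions(
        train, bin_width=5.0,
        max_lag=0.5 * float(np.hypot(table["row"].max(), table["col"].max())))
    geostat.save_models(models, RESULTS / "transition_models")
    bb = models[("bamboo", "bamboo")]
    print(f"bamboo same-class model: {bb.family}, p0 {bb.p0:.2f}, "
          f"sill {bb.sill:.2f}, range {bb.range_:.0f} px")

    res_gknn = geostat.gknn_classify(
        neighbors, models,
        geostat.GkNNConfig(sg=SG, k=K, omega_scheme="inverse_distance"))
    res_gknn.to_frame().to_csv(RESULTS / "classification_gknn.csv",
                               index=False)

    train_ids = set(train.df["segment_id"])
    held_out = {int(i): truth[i] for i in truth.index
                if int(i) not in train_ids and truth[i] != "shadow"}
    test = from_segment_table(table, held_out, FIELD)
    assessed = sorted({c for c in truth.unique() if c != "shadow"})

    metrics = {}
    for name, res in (("knn", res_knn), ("gknn", res_gknn)):
        cm = assessment.confusion(res, test, class_names=assessed)
        cm.to_frame().round(2).to_csv(RESULTS / f"confusion_{name}.csv")
        acc = assessment.accuracies(cm)
        metrics[name] = {
            "overall_accuracy_pct": acc["overall"],
            "kappa": assessment.kappa(cm),
        }
        print(f"{name:5s} OA {acc['overall']:.2f}%  "
              f"kappa {metrics[name]['kappa']:.3f}")
    (RESULTS / "assessment_metrics.json").write_text(
        json.dumps(metrics, indent=2))


if __name__ == "__main__":
    main()
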