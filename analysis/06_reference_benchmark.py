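"""Metrics from the published benchmark error matrices.

Feeds the published six-class k-NN and gk-NN error matrices (430 field
test points) through the package's accuracy code and tabulates overall
/ producer's / user's accuracy and kappa for both classifiers,
including the per-class gains from the spatial weighting.

Writes: results/reference_metrics.csv
"""

from pathlib import Path

import pandas as pd

from bamboomap.assessment import accuracies, kappa, round_display
from bamboomap.reference import GKNN_ERROR_MATRIX, KNN_ERROR_MATRIX

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    acc = {name: accuracies(cm) for name, cm in
           (("knn", KNN_ERROR_MATRIX), ("gknn", GKNN_ERROR_MATRIX))}
    for cls in KNN_ERROR_MATRIX.class_names:
        rows.append({
            "class": cls,
            "knn_producers_pct": round_display(acc["knn"]["producers"][cls]),
            "knn_users_pct": round_display(acc["knn"]["users"][cls]),
            "gknn_producers_pct": round_display(acc["gknn"]["producers"][cls]),
            "gknn_users_pct": round_display(acc["gknn"]["users"][cls]),
            "producers_gain_pct": round_display(
                acc["gknn"]["producers"][cls] - acc["knn"]["producers"][cls]),
            "users_gain_pct": round_display(
                acc["gknn"]["users"][cls] - acc["knn"]["users"][cls]),
        })
    df = pd.DataFrame(rows).set_index("class")
    df.to_csv(RESULTS / "reference_metrics.csv")
    print(df.to_string())
    print(f"\noverall: k-NN {round_display(acc['knn']['overall'])}% "
          f"(kappa {kappa(KNN_ERROR_MATRIX):.3f}), "
          f"gk-NN {round_display(acc['gknn']['overall'])}% "
          f"(kappa {kappa(GKNN_ERROR_MATRIX):.3f})")


if __name__ == "__main__":
    main()
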