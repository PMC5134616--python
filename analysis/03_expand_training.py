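"""Expand the sparse field samples with the mu +/- t*sigma rule.

Draws a handful of 'field plot' objects per class (3 bamboo, 4 each
otherwise, mimicking GPS ground truthing under canopy), runs the
covariance PCA to pick the five expansion bands, and labels every
object whose band means fall inside exactly one class's intervals.
Also prints the interval-overlap diagnostic behind the
"little or no overlap" rule.

Reads:  results/segment_table.csv, results/segment_truth.csv
Writes: results/training_samples.csv, results/pca_loadings.csv,
        results/interval_overlaps.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from bamboomap import pca
from bamboomap.expansion import expand_training, fit_spectral_model, overlap_report
from bamboomap.pipeline import PipelineConfig, sample_field_segments
from bamboomap.samples import FIELD, from_segment_table
from bamboomap.scene import BAND_NAMES

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "segment_table.csv", index_col=0)
    truth_df = pd.read_csv(RESULTS / "segment_truth.csv", index_col=0)
    truth, purity = truth_df["class_label"], truth_df["purity"]

    field_labels = sample_field_segments(truth, purity, n_per_class=4,
                                         seed=SEED, n_bamboo=3)
    field = from_segment_table(table, field_labels, FIELD)
    print(f"field samples: {len(field)} "
          f"({field.df['class_label'].value_counts().to_dict()})")

    result = pca.pca(table)
    result.loadings.round(6).to_csv(RESULTS / "pca_loadings.csv")
    bands = pca.expansion_bands(result, list(BAND_NAMES), n_bands=5)
    print(f"PC1 variance fraction {result.proportions[0]:.2f}; "
          f"expansion bands: {bands}")

    cfg = PipelineConfig()
    model = fit_spectral_model(field, bands, cfg.expansion_t)
    overlap_report(model).round(2).to_csv(RESULTS / "interval_overlaps.csv")

    train = expand_training(table, model, field)
    train.to_csv(RESULTS / "training_samples.csv")
    n_exp = (train.df["provenance"] == "expanded").sum()
    print(f"expanded training set: {len(train)} objects "
          f"({n_exp} added, {n_exp / len(table) * 100:.1f}% of all objects)")


if __name__ == "__main__":
    main()
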