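"""Choose classification features by class-separability search.

Enumerates every subset of the eight band means plus GLCM contrast and
reports, per dimension, the subset with the largest mean
nearest-other-class distance on standardized features.  Barren land
and shadow are excluded from the metric (trivially separable classes
would dominate it).

Reads:  results/training_samples.csv
Writes: results/separability_curve.csv, results/classification_features.json
"""

import json
from pathlib import Path

from bamboomap.fso import optimize_features
from bamboomap.samples import SampleSet
from bamboomap.scene import BAND_NAMES

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    train = SampleSet.from_csv(RESULTS / "training_samples.csv")
    candidates = list(BAND_NAMES) + ["glcm_contrast"]
    curve = optimize_features(train, candidates,
                              exclude_classes=["barren_land", "shadow"])
    out = curve.table.copy()
    out["features"] = out["features"].map(lambda t: "+".join(t))
    out.to_csv(RESULTS / "separability_curve.csv", index=False)
    best, dist = curve.best()
    (RESULTS / "classification_features.json").write_text(
        json.dumps(list(best), indent=2))
    print(out.to_string(index=False))
    print(f"\nbest subset: {best} (distance {dist:.3f})")


if __name__ == "__main__":
    main()
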