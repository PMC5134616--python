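"""Labelled segment samples.

A :class:`SampleSet` is a thin wrapper around a DataFrame whose rows
are labelled segments: reserved columns ``segment_id``,
``class_label``, ``provenance`` (``field`` or ``expanded``), centroid
``row``/``col``, and one column per feature.  It feeds every
classifier and the geostatistical estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("segment_id", "class_label", "provenance", "row", "col")

FIELD = "field"
EXPANDED = "expanded"


@dataclass
class SampleSet:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESERVED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.df["segment_id"].duplicated().any():
            raise ValueError("a segment may carry only one label")
        if self.df["provenance"].isna().any():
            raise ValueError("provenance must be set for every sample")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in RESERVED_COLUMNS]

    @property
    def classes(self) -> list[str]:
        return sorted(self.df["class_label"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def features(self, names: list[str] | None = None) -> np.ndarray:
        return self.df[names or self.feature_names].to_numpy(dtype=np.float64)

    def labels(self) -> np.ndarray:
        return self.df["class_label"].to_numpy()

    def centroids(self) -> np.ndarray:
        return self.df[["row", "col"]].to_numpy(dtype=np.float64)

    def field_only(self) -> "SampleSet":
        return SampleSet(self.df[self.df["provenance"] == FIELD].reset_index(drop=True))

    def subset_classes(self, keep: list[str]) -> "SampleSet":
        return SampleSet(
            self.df[self.df["class_label"].isin(keep)].reset_index(drop=True)
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSet":
        return cls(pd.read_csv(path))


def from_segment_table(table: pd.DataFrame, labels: dict[int, str],
                       provenance: str = FIELD) -> SampleSet:
    """Build a SampleSet from a segment feature table and id->label map."""
    ids = [i for i in labels if i in table.index]
    missing = set(labels) - set(ids)
    if missing:
        raise KeyError(f"segment ids not in table: {sorted(missing)[:5]}")
    sub = table.loc[ids]
    df = sub.reset_index().rename(columns={"segment_id": "segment_id"})
    df.insert(1, "class_label", [labels[i] for i in ids])
    df.insert(2, "provenance", provenance)
    df = df.drop(columns=["area"], errors="ignore")
    return SampleSet(df)
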