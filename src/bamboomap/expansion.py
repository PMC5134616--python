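"""Training-sample expansion from sparse field plots.

With only a handful of field samples per class, a classifier over
tens of thousands of image objects is starved.  Expansion labels every
unlabelled segment whose band means fall inside the class's
mu +/- t*sigma interval on ALL selected bands, where mu and sigma are
the field-sample mean and (population) standard deviation of the band
reflectance and t is a small per-class multiplier chosen so that class
intervals barely overlap.  Segments matching more than one class are
ambiguous and, by default, dropped rather than force-assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .samples import EXPANDED, SampleSet

log = logging.getLogger(__name__)


@dataclass
class ClassSpectralModel:
    """Per class x band mean/std plus the per-class interval multiplier t."""

    mu: pd.DataFrame       # class x band
    sigma: pd.DataFrame    # class x band, >= 0
    t: pd.Series           # per class, >= 0

    def __post_init__(self) -> None:
        if (self.sigma.to_numpy() < 0).any():
            raise ValueError("sigma must be >= 0")
        if (self.t < 0).any():
            raise ValueError("t must be >= 0")
        if list(self.mu.index) != list(self.sigma.index) or \
                list(self.mu.columns) != list(self.sigma.columns):
            raise ValueError("mu and sigma must share classes and bands")

    @property
    def classes(self) -> list[str]:
        return list(self.mu.index)

    @property
    def bands(self) -> list[str]:
        return list(self.mu.columns)


def fit_spectral_model(field_samples: SampleSet, bands: list[str],
                       t_values: dict[str, float],
                       ddof: int = 0) -> ClassSpectralModel:
    """Moment fit of the per-class band-reflectance model.

    ``ddof=0`` (population standard deviation) by default: with 3-4
    field samples per class the divisor matters and the tighter
    population choice keeps intervals narrow.
    """
    classes = field_samples.classes
    for c in classes:
        if c not in t_values:
            raise KeyError(f"no t value for class {c!r}")
    mu = pd.DataFrame(index=classes, columns=bands, dtype=float)
    sigma = pd.DataFrame(index=classes, columns=bands, dtype=float)
    for c in classes:
        sub = field_samples.df[field_samples.df["class_label"] == c]
        if len(sub) == 0:
            raise ValueError(f"class {c!r} has no field samples")
        X = sub[bands].to_numpy(dtype=np.float64)
        mu.loc[c] = X.mean(axis=0)
        sigma.loc[c] = X.std(axis=0, ddof=ddof) if len(sub) > ddof else 0.0
    t = pd.Series({c: float(t_values[c]) for c in classes})
    return ClassSpectralModel(mu=mu, sigma=sigma, t=t)


def spectral_ranges(model: ClassSpectralModel) -> pd.DataFrame:
    """Closed intervals [mu - t*sigma, mu + t*sigma] per class x band.

    Returned as a DataFrame indexed by class with MultiIndex columns
    (band, 'lo'|'hi').
    """
    cols = pd.MultiIndex.from_product([model.bands, ["lo", "hi"]])
    out = pd.DataFrame(index=model.classes, columns=cols, dtype=float)
    for c in model.classes:
        half = model.t[c] * model.sigma.loc[c]
        for b in model.bands:
            out.loc[c, (b, "lo")] = model.mu.loc[c, b] - half[b]
            out.loc[c, (b, "hi")] = model.mu.loc[c, b] + half[b]
    return out


def overlap_report(model: ClassSpectralModel) -> pd.DataFrame:
    """Pairwise interval overlap width per band (diagnostic for rule (i)).

    Rows: unordered class pairs; columns: bands; values: width of the
    interval intersection (0 when disjoint).
    """
    ranges = spectral_ranges(model)
    classes = model.classes
    rows = {}
    for i, a in enumerate(classes):
        for b_cls in classes[i + 1:]:
            widths = []
            for band in model.bands:
                lo = max(ranges.loc[a, (band, "lo")], ranges.loc[b_cls, (band, "lo")])
                hi = min(ranges.loc[a, (band, "hi")], ranges.loc[b_cls, (band, "hi")])
                widths.append(max(0.0, hi - lo))
            rows[(a, b_cls)] = widths
    out = pd.DataFrame.from_dict(rows, orient="index", columns=model.bands)
    out.index = pd.MultiIndex.from_tuples(out.index,
                                          names=["class_a", "class_b"])
    return out


def candidate_matches(table: pd.DataFrame, model: ClassSpectralModel) -> pd.DataFrame:
    """Boolean segment x class matrix: inside ALL band intervals of the class."""
    ranges = spectral_ranges(model)
    out = pd.DataFrame(index=table.index, columns=model.classes, dtype=bool)
    for c in model.classes:
        ok = np.ones(len(table), dtype=bool)
        for band in model.bands:
            v = table[band].to_numpy(dtype=np.float64)
            ok &= (v >= ranges.loc[c, (band, "lo")]) & \
                  (v <= ranges.loc[c, (band, "hi")])
        out[c] = ok
    return out


def expand_training(table: pd.DataFrame, model: ClassSpectralModel,
                    field_samples: SampleSet,
                    ambiguous: str = "drop") -> SampleSet:
    """Expand field samples with interval-matched segments.

    A segment is a candidate for class m iff its band means lie inside
    all of m's intervals.  Segments matching exactly one class are
    added with provenance ``expanded``; segments matching several are
    dropped (``ambiguous='drop'``) or assigned to the class with the
    nearest standardized spectral centroid (``ambiguous='nearest'``).
    Field samples are always retained unchanged with their own labels.
    """
    missing = set(model.bands) - set(table.columns)
    if missing:
        raise KeyError(f"segment table lacks model bands: {sorted(missing)}")
    if ambiguous not in ("drop", "nearest"):
        raise ValueError("ambiguous must be 'drop' or 'nearest'")

    matches = candidate_matches(table, model)
    field_ids = set(field_samples.df["segment_id"])
    n_match = matches.to_numpy().sum(axis=1)
    rows = []
    classes = np.array(model.classes)
    sig_floor = model.sigma.replace(0.0, 1.0)
    for pos, seg_id in enumerate(table.index):
        if seg_id in field_ids:
            continue
        k = n_match[pos]
        if k == 0:
            continue
        if k == 1:
            label = classes[matches.to_numpy()[pos]][0]
        elif ambiguous == "drop":
            continue
        else:
            cand = classes[matches.to_numpy()[pos]]
            v = table.loc[seg_id, model.bands].to_numpy(dtype=np.float64)
            z = [np.linalg.norm((v - model.mu.loc[c].to_numpy()) /
                                sig_floor.loc[c].to_numpy()) for c in cand]
            label = cand[int(np.argmin(z))]
        rec = {"segment_id": seg_id, "class_label": label,
               "provenance": EXPANDED,
               "row": table.loc[seg_id, "row"], "col": table.loc[seg_id, "col"]}
        for f in field_samples.feature_names:
            rec[f] = table.loc[seg_id, f]
        rows.append(rec)
    if not rows:
        log.info("expansion selected no additional segments")
        return SampleSet(field_samples.df.copy())
    exp_df = pd.DataFrame(rows)
    out = pd.concat([field_samples.df, exp_df[field_samples.df.columns]],
                    ignore_index=True)
    return SampleSet(out)
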