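"""Class-conditional spatial probability models and the gk-NN classifier.

The core of the package.  From labelled segment centroids, the
empirical transition probability

    p_hat_{m,m'}(h) = #{pairs (u,v): c(u)=m, c(v)=m', |u-v| in bin h}
                      / #{pairs (u,v): c(u)=m, |u-v| in bin h}

is estimated isotropically over ordered sample pairs and binned by
centroid lag.  A covariance-style model

    p(h) = sill + (p0 - sill) * g(h; a)

with g spherical, exponential (exp(-3h/a)) or Gaussian (exp(-3h^2/a^2))
is then fitted per ordered class pair by weighted least squares (bin
pair counts as weights), skipping the first lag bin, which reflects
within-segment correlation (the "peak") rather than between-segment
structure.

The geostatistically weighted k-NN blends this spatial structure into
the neighbour vote with a mixing weight Sg in [0, 1]:

    score(m) = sum_k omega_uk * [ Sg * p_{m,c(k)}(h_uk)
                                  + (1 - Sg) * I(c(k) = m) ]

normalized over classes.  Sg = 0 recovers the plain weighted k-NN
vote; Sg = 1 classifies purely from spatial plausibility of each class
given the observed neighbour classes and lags.  (A literal reading of
the published estimator makes the aspatial term class-independent, so
the neighbour's class would never enter; the form above is the reading
that restores the documented Sg = 0 limit — see docs/methods.md.)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .knn import ClassificationResult, NeighborSet, _tie_break
from .samples import SampleSet

log = logging.getLogger(__name__)

FAMILIES = ("spherical", "exponential", "gaussian")

DEFAULT_BIN_WIDTH = 5.0


@dataclass
class EmpiricalTransitionCurve:
    """Binned transition-probability estimates for one ordered class pair."""

    class_from: str
    class_to: str
    bin_centers: np.ndarray
    bin_width: float
    probabilities: np.ndarray   # NaN where the bin had no (from-class) pair
    pair_counts: np.ndarray     # denominator count per bin

    def usable(self, skip_first: bool = True) -> np.ndarray:
        """Mask of bins with data, optionally excluding the first
        (within-segment) bin."""
        ok = (self.pair_counts > 0) & np.isfinite(self.probabilities)
        if skip_first:
            ok[0] = False
        return ok


def lag_bins(max_lag: float, width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Equal-width lag bin edges [0, width, 2*width, ..., >= max_lag]."""
    n = int(np.ceil(max_lag / width)) + 1
    return np.arange(n + 1, dtype=np.float64) * width


def empirical_transitions(samples: SampleSet,
                          bin_edges: np.ndarray | None = None,
                          bin_width: float = DEFAULT_BIN_WIDTH,
                          classes: list[str] | None = None,
                          ) -> dict[tuple[str, str], EmpiricalTransitionCurve]:
    """Estimate p_hat_{m,m'}(h) for every ordered class pair.

    All ordered sample pairs (u, v), u != v, contribute: the pair falls
    in the lag bin of the centroid distance |u - v| and increments the
    (c(u), c(v)) counter there.  Probabilities are row-normalized per
    (from-class, bin): they sum to 1 over the to-class within each bin
    that has data.  Direction is ignored (isotropic).
    """
    if classes is None:
        classes = samples.classes
    labels = samples.labels()
    cent = samples.centroids()
    D = cdist(cent, cent)
    if bin_edges is None:
        bin_edges = lag_bins(D.max() if D.size else bin_width, bin_width)
    n_bins = len(bin_edges) - 1
    width = float(bin_edges[1] - bin_edges[0])
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    iu, iv = np.where(~np.eye(len(labels), dtype=bool))
    lag = D[iu, iv]
    binned = np.clip(np.searchsorted(bin_edges, lag, side="right") - 1,
                     0, n_bins - 1)
    cindex = {c: i for i, c in enumerate(classes)}
    cu = np.array([cindex[c] for c in labels[iu]])
    cv = np.array([cindex[c] for c in labels[iv]])
    counts = np.zeros((len(classes), len(classes), n_bins))
    np.add.at(counts, (cu, cv, binned), 1.0)

    row_tot = counts.sum(axis=1)  # (from, bin)
    curves = {}
    for mi, m in enumerate(classes):
        for ni, mp in enumerate(classes):
            with np.errstate(invalid="ignore", divide="ignore"):
                p = counts[mi, ni] / row_tot[mi]
            curves[(m, mp)] = EmpiricalTransitionCurve(
                class_from=m, class_to=mp,
                bin_centers=centers, bin_width=width,
                probabilities=p, pair_counts=row_tot[mi],
            )
    return curves


def _g(h: np.ndarray, a: float, family: str) -> np.ndarray:
    h = np.asarray(h, dtype=np.float64)
    if family == "spherical":
        x = np.clip(h / a, 0.0, None)
        g = 1.0 - (1.5 * x - 0.5 * x ** 3)
        return np.where(x <= 1.0, g, 0.0)
    if family == "exponential":
        return np.exp(-3.0 * h / a)
    if family == "gaussian":
        return np.exp(-3.0 * h ** 2 / a ** 2)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class ConditionalProbabilityModel:
    """Fitted transition-probability model for one ordered class pair."""

    class_from: str
    class_to: str
    family: str
    p0: float        # value as h -> 0+
    sill: float      # asymptote at large h
    range_: float    # pixels; a > 0
    rss: float = np.nan
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.sill <= 1.0):
            raise ValueError("p0 and sill must lie in [0, 1]")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def __call__(self, h: np.ndarray | float) -> np.ndarray:
        """Evaluate p(h), h clipped to >= 0, result clipped to [0, 1]."""
        h = np.clip(np.asarray(h, dtype=np.float64), 0.0, None)
        p = self.sill + (self.p0 - self.sill) * _g(h, self.range_, self.family)
        return np.clip(p, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "class_from": self.class_from, "class_to": self.class_to,
            "family": self.family, "p0": self.p0, "sill": self.sill,
            "range": self.range_, "rss": None if np.isnan(self.rss) else self.rss,
            "flags": self.flags,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionalProbabilityModel":
        return cls(class_from=d["class_from"], class_to=d["class_to"],
                   family=d["family"], p0=d["p0"], sill=d["sill"],
                   range_=d["range"],
                   rss=np.nan if d.get("rss") is None else d["rss"],
                   flags=list(d.get("flags", [])))


def _fit_family(h: np.ndarray, p: np.ndarray, w: np.ndarray,
                family: str) -> tuple[np.ndarray, float]:
    """Weighted least squares for one family; returns (p0, sill, a), rss."""
    hmax = float(h.max())
    # data-driven starts
    p0_0 = float(np.clip(p[0], 0.0, 1.0))
    sill_0 = float(np.clip(p[-max(1, len(p) // 4):].mean(), 0.0, 1.0))
    a_starts = [hmax / 4, hmax / 2, hmax]

    sw = np.sqrt(w / w.max())

    def resid(theta):
        p0, sill, a = theta
        return sw * (sill + (p0 - sill) * _g(h, a, family) - p)

    best, best_cost = None, np.inf
    for a0 in a_starts:
        try:
            res = least_squares(
                resid, x0=[p0_0, sill_0, a0],
                bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, 10 * hmax]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # pragma: no cover - defensive
            continue
        if res.cost < best_cost:
            best, best_cost = res.x, res.cost
    if best is None:
        raise RuntimeError("least-squares fit failed")
    rss = float(np.sum((resid(best) / sw) ** 2))
    return best, rss


def fit_transition_model(curve: EmpiricalTransitionCurve,
                         family: str = "auto",
                         skip_first_bin: bool = True,
                         ) -> ConditionalProbabilityModel:
    """Fit a covariance-style model to an empirical transition curve.

    Bins are weighted by pair count; the first bin is excluded by
    default (within-segment peak).  ``family='auto'`` tries all three
    families and keeps the lowest residual sum of squares.  A flat
    curve fits with an unidentifiable range (flagged).  If fitting
    fails, an exponential model from method-of-moments starting values
    is returned, flagged ``fallback``.
    """
    ok = curve.usable(skip_first=skip_first_bin)
    h = curve.bin_centers[ok]
    p = curve.probabilities[ok]
    w = curve.pair_counts[ok]
    if len(h) < 3:
        raise ValueError("need at least 3 usable lag bins to fit")

    flags: list[str] = []
    families = FAMILIES if family == "auto" else (family,)
    best = None
    try:
        for fam in families:
            params, rss = _fit_family(h, p, w, fam)
            if best is None or rss < best[2]:
                best = (fam, params, rss)
        fam, (p0, sill, a), rss = best
    except RuntimeError:
        log.warning("fit failed for (%s, %s); method-of-moments exponential "
                    "fallback", curve.class_from, curve.class_to)
        p0, sill = float(p[0]), float(p[-1])
        a = float(h[len(h) // 2])
        fam, rss = "exponential", np.nan
        flags.append("fallback")

    if abs(p0 - sill) < 1e-3:
        flags.append("range_unidentifiable")
    return ConditionalProbabilityModel(
        class_from=curve.class_from, class_to=curve.class_to, family=fam,
        p0=float(np.clip(p0, 0, 1)), sill=float(np.clip(sill, 0, 1)),
        range_=float(a), rss=rss, flags=flags)


def fit_all_transitions(samples: SampleSet,
                        bin_width: float = DEFAULT_BIN_WIDTH,
                        family: str = "auto",
                        classes: list[str] | None = None,
                        max_lag: float | None = None,
                        ) -> dict[tuple[str, str], ConditionalProbabilityModel]:
    """Estimate and fit transition models for every ordered class pair.

    Pairs whose curve has too few usable bins fall back to a constant
    model at the overall to-class frequency (flagged ``sparse``).
    """
    if classes is None:
        classes = samples.classes
    bins = None
    if max_lag is not None:
        bins = lag_bins(max_lag, bin_width)
    curves = empirical_transitions(samples, bin_edges=bins,
                                   bin_width=bin_width, classes=classes)
    labels = samples.labels()
    freq = {c: float((labels == c).mean()) for c in classes}
    models = {}
    for pair, curve in curves.items():
        try:
            models[pair] = fit_transition_model(curve, family=family)
        except ValueError:
            models[pair] = ConditionalProbabilityModel(
                class_from=pair[0], class_to=pair[1], family="exponential",
                p0=freq[pair[1]], sill=freq[pair[1]], range_=1.0,
                flags=["sparse"])
    return models


@dataclass
class GkNNConfig:
    """Mixing weight, neighbourhood size and weighting scheme."""

    sg: float = 0.5
    k: int = 5
    omega_scheme: str = "inverse_distance"

    def __post_init__(self) -> None:
        if not 0.0 <= self.sg <= 1.0:
            raise ValueError("Sg must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("K must be >= 1")


def gknn_classify(neighbors: NeighborSet,
                  models: dict[tuple[str, str], ConditionalProbabilityModel],
                  config: GkNNConfig,
                  class_names: list[str] | None = None) -> ClassificationResult:
    """Geostatistically weighted k-NN vote.

    score(m) = sum_k omega_uk * [Sg * p_{m,c(k)}(h_uk) + (1-Sg) * I(c(k)=m)],
    normalized over classes.  Queries whose scores all vanish fall back
    to the plain k-NN vote (flag logged).
    """
    if class_names is None:
        class_names = sorted(np.unique(neighbors.train_classes))
    sg = config.sg
    n, k = neighbors.classes.shape
    scores = np.zeros((n, len(class_names)))
    for mi, m in enumerate(class_names):
        spatial = np.zeros((n, k))
        if sg > 0:
            for mp in set(np.unique(neighbors.classes)):
                if (m, mp) not in models:
                    raise KeyError(f"no transition model for pair ({m}, {mp})")
                mask = neighbors.classes == mp
                if mask.any():
                    spatial[mask] = models[(m, mp)](neighbors.lags[mask])
        indicator = (neighbors.classes == m).astype(np.float64)
        scores[:, mi] = (neighbors.weights *
                         (sg * spatial + (1.0 - sg) * indicator)).sum(axis=1)

    tot = scores.sum(axis=1)
    dead = tot <= 0
    if dead.any():
        log.warning("%d queries had all-zero gk-NN scores; falling back to "
                    "plain k-NN vote", int(dead.sum()))
        for mi, m in enumerate(class_names):
            vote = (neighbors.weights[dead] *
                    (neighbors.classes[dead] == m)).sum(axis=1)
            scores[dead, mi] = vote
        tot = scores.sum(axis=1)
    proba = scores / tot[:, None]
    predicted = _tie_break(scores, neighbors, class_names)
    return ClassificationResult(
        segment_ids=neighbors.query_ids, class_names=class_names,
        proba=proba, predicted=predicted)


def save_models(models: dict[tuple[str, str], ConditionalProbabilityModel],
                out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (m, mp), model in models.items():
        (out / f"{m}__{mp}.json").write_text(json.dumps(model.to_dict(), indent=2))


def load_models(in_dir: str | Path,
                ) -> dict[tuple[str, str], ConditionalProbabilityModel]:
    models = {}
    for path in sorted(Path(in_dir).glob("*__*.json")):
        model = ConditionalProbabilityModel.from_dict(json.loads(path.read_text()))
        models[(model.class_from, model.class_to)] = model
    return models
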