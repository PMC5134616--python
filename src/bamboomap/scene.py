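"""Synthetic multispectral scene generation.

Generates spatially autocorrelated class maps and 8-band reflectance
rasters that emulate a shaded montane landscape with seven cover types
(bamboo, coniferous, broadleaved, mixed woodland, brush, barren land,
shadow), so the whole object-based classification pipeline can be
exercised without the original satellite imagery.

Class maps are built by the smoothed-field argmax construction: one
independent white-noise field per class is smoothed with an isotropic
Gaussian kernel whose width is derived from ``correlation_range``,
offset by the log of the class proportion, and each pixel takes the
class with the largest field value.  The kernel-width constant was
calibrated once against the transition-probability range fitted by
:mod:`bamboomap.geostat` and then frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

#: WorldView-2-style multispectral band names, in wavelength order.
BAND_NAMES = (
    "coastal_blue",
    "blue",
    "green",
    "yellow",
    "red",
    "red_edge",
    "nir1",
    "nir2",
)

#: Default seven-class legend; shadow is an ordinary (dark) class.
CLASS_NAMES = (
    "bamboo",
    "coniferous",
    "broadleaved",
    "mixed_woodland",
    "brush",
    "barren_land",
    "shadow",
)

DEFAULT_PROPORTIONS = {
    "bamboo": 0.08,
    "coniferous": 0.22,
    "broadleaved": 0.18,
    "mixed_woodland": 0.20,
    "brush": 0.12,
    "barren_land": 0.05,
    "shadow": 0.15,
}

# Per class: {band: (mean DN, std DN)}.  The green, yellow, red edge,
# NIR1 and NIR2 entries are back-derived from published mu +/- t*sigma
# expansion intervals (mu = midpoint, sigma = halfwidth / t); the
# coastal blue, blue and red entries and the whole shadow row are
# plausible placeholders for a winter montane scene, not published
# values (see docs/methods.md).
DEFAULT_BAND_MODELS: dict[str, dict[str, tuple[float, float]]] = {
    "bamboo": {
        "coastal_blue": (182.0, 8.0),
        "blue": (165.0, 8.0),
        "green": (152.3, 6.8),
        "yellow": (97.8, 8.6),
        "red": (88.0, 9.0),
        "red_edge": (125.3, 18.4),
        "nir1": (121.8, 20.4),
        "nir2": (138.2, 22.2),
    },
    "coniferous": {
        "coastal_blue": (188.0, 9.0),
        "blue": (172.0, 9.0),
        "green": (186.6, 5.5),
        "yellow": (119.4, 4.2),
        "red": (96.0, 8.0),
        "red_edge": (348.4, 31.3),
        "nir1": (391.9, 35.7),
        "nir2": (418.7, 42.8),
    },
    "broadleaved": {
        "coastal_blue": (191.0, 9.0),
        "blue": (176.0, 9.0),
        "green": (193.3, 7.8),
        "yellow": (127.9, 8.5),
        "red": (104.0, 9.0),
        "red_edge": (307.3, 45.5),
        "nir1": (332.9, 49.4),
        "nir2": (359.3, 54.9),
    },
    "mixed_woodland": {
        "coastal_blue": (186.0, 9.0),
        "blue": (170.0, 9.0),
        "green": (179.3, 15.6),
        "yellow": (116.2, 13.6),
        "red": (99.0, 10.0),
        "red_edge": (224.8, 93.4),
        "nir1": (241.1, 109.6),
        "nir2": (257.0, 118.2),
    },
    "brush": {
        "coastal_blue": (180.0, 9.0),
        "blue": (163.0, 9.0),
        "green": (163.2, 16.0),
        "yellow": (106.0, 17.8),
        "red": (93.0, 10.0),
        "red_edge": (166.1, 33.0),
        "nir1": (174.5, 40.8),
        "nir2": (196.5, 52.3),
    },
    "barren_land": {
        "coastal_blue": (205.0, 14.0),
        "blue": (195.0, 14.0),
        "green": (190.9, 29.2),
        "yellow": (113.6, 19.0),
        "red": (132.0, 18.0),
        "red_edge": (94.0, 18.5),
        "nir1": (69.0, 15.5),
        "nir2": (66.0, 16.1),
    },
    "shadow": {
        "coastal_blue": (60.0, 8.0),
        "blue": (48.0, 7.0),
        "green": (40.0, 6.0),
        "yellow": (30.0, 5.0),
        "red": (26.0, 5.0),
        "red_edge": (32.0, 6.0),
        "nir1": (35.0, 7.0),
        "nir2": (34.0, 7.0),
    },
}

# Smoothing kernel width as a fraction of the requested correlation
# range.  Calibrated once so that the range parameter fitted to
# same-class transition probabilities on generated maps tracks
# `correlation_range`, then frozen.
KERNEL_RANGE_FRACTION = 1.0 / 2.8


def _as_band_model_arrays(
    band_models: dict[str, dict[str, tuple[float, float]]],
    class_names: tuple[str, ...],
    band_names: tuple[str, ...],
) -> tuple[np.ndarray, np.ndarray]:
    means = np.empty((len(class_names), len(band_names)))
    stds = np.empty_like(means)
    for ci, cname in enumerate(class_names):
        if cname not in band_models:
            raise ValueError(f"no band model for class {cname!r}")
        for bi, bname in enumerate(band_names):
            if bname not in band_models[cname]:
                raise ValueError(f"no model for class {cname!r} band {bname!r}")
            means[ci, bi], stds[ci, bi] = band_models[cname][bname]
    if (stds < 0).any():
        raise ValueError("band standard deviations must be >= 0")
    return means, stds


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    Parameters
    ----------
    n_rows, n_cols
        Raster dimensions in pixels.
    class_names
        Ordered cover-type legend; class id ``i`` is ``class_names[i]``.
    class_proportions
        Target areal fraction per class, summing to 1.
    correlation_range
        Target spatial range of class patches, in pixels: the lag beyond
        which same-class transition probability has decayed to its sill.
    band_models
        Per class, per band ``(mean DN, std DN)`` of reflectance.
    noise_sd
        Additional white sensor noise (DN) applied to every band.
    seed
        Seed for the scene's random generator.
    """

    n_rows: int = 256
    n_cols: int = 256
    class_names: tuple[str, ...] = CLASS_NAMES
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    band_names: tuple[str, ...] = BAND_NAMES
    band_models: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {c: dict(b) for c, b in DEFAULT_BAND_MODELS.items()}
    )
    correlation_range: float = 20.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("raster dimensions must be positive")
        if self.correlation_range <= 0:
            raise ValueError("correlation_range must be > 0")
        missing = set(self.class_names) - set(self.class_proportions)
        if missing:
            raise ValueError(f"proportions missing for classes: {sorted(missing)}")
        total = sum(self.class_proportions[c] for c in self.class_names)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(self.class_proportions[c] < 0 for c in self.class_names):
            raise ValueError("class proportions must be >= 0")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.class_proportions[c] for c in self.class_names])

    def to_json(self) -> str:
        d = {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "class_names": list(self.class_names),
            "class_proportions": self.class_proportions,
            "band_names": list(self.band_names),
            "band_models": {
                c: {b: list(v) for b, v in m.items()}
                for c, m in self.band_models.items()
            },
            "correlation_range": self.correlation_range,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        d = json.loads(text)
        d["class_names"] = tuple(d["class_names"])
        d["band_names"] = tuple(d["band_names"])
        d["band_models"] = {
            c: {b: tuple(v) for b, v in m.items()}
            for c, m in d["band_models"].items()
        }
        return cls(**d)


@dataclass
class ClassMap:
    """Integer class-label raster with its legend (id -> name)."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        valid = np.isin(self.labels, list(self.legend))
        if not valid.all():
            raise ValueError("class map contains labels not in the legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_fractions(self) -> dict[str, float]:
        n = self.labels.size
        return {
            name: float((self.labels == cid).sum()) / n
            for cid, name in self.legend.items()
        }


def _calibrate_offsets(props: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Offsets making the marginal argmax probabilities match ``props``.

    Each class field is marginally N(offset, 1); starting from the log
    proportions, the offsets are refined by deterministic fixed-point
    iteration on the numerically integrated win probabilities
    ``P(c) = int phi(x - o_c) prod_{c' != c} Phi(x - o_c') dx``.
    """
    from scipy.stats import norm

    active = props > 0
    o = np.where(active, np.log(np.clip(props, 1e-300, None)), -np.inf)
    x = np.linspace(-9.0, 9.0, 1201)
    for _ in range(n_iter):
        cdfs = norm.cdf(x[None, :] - o[:, None])  # (C, X)
        cdfs[~active] = 1.0
        log_all = np.sum(np.log(np.clip(cdfs, 1e-300, None)), axis=0)
        win = np.zeros_like(props)
        for ci in np.flatnonzero(active):
            dens = norm.pdf(x - o[ci])
            others = np.exp(log_all - np.log(np.clip(cdfs[ci], 1e-300, None)))
            win[ci] = np.trapezoid(dens * others, x)
        win = np.clip(win, 1e-12, None)
        o = np.where(active, o + 0.8 * (np.log(props, where=active,
                                                out=np.full_like(props, -np.inf))
                                        - np.log(win)), -np.inf)
        o = o - o[active].max()
    return o


def generate_class_map(config: SceneConfig) -> ClassMap:
    """Generate a spatially autocorrelated class map.

    One unit-variance smoothed Gaussian field per class, offset so the
    marginal argmax probability of each class equals its requested
    proportion (a calibrated refinement of the raw log-proportion
    offset); each pixel is labelled with the argmax field.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sigma_k = config.correlation_range * KERNEL_RANGE_FRACTION
    n_class = len(config.class_names)
    props = config.proportions
    offsets = _calibrate_offsets(props)

    scores = np.empty((n_class, config.n_rows, config.n_cols))
    for ci in range(n_class):
        noise = rng.standard_normal((config.n_rows, config.n_cols))
        if props[ci] == 0.0:
            scores[ci] = -np.inf
            continue
        f = gaussian_filter(noise, sigma_k, mode="wrap")
        sd = f.std()
        if sd > 0:
            f /= sd
        scores[ci] = f + offsets[ci]
    labels = np.argmax(scores, axis=0).astype(np.int32)
    legend = {i: name for i, name in enumerate(config.class_names)}
    return ClassMap(labels=labels, legend=legend)


def generate_reflectance(class_map: ClassMap, config: SceneConfig) -> np.ndarray:
    """Draw an 8-band reflectance raster over a class map.

    The class standard deviation models the spread of object-level
    (segment-mean) reflectance within a class, not independent pixel
    noise: each class carries one smooth unit-variance brightness
    factor field ``f_c`` (same smoothing scale as the class patches,
    demeaned over the class footprint), shared across bands, so

        value(pixel, b) = mean[c, b] + std[c, b] * f_c(pixel)
                          + N(0, noise_sd).

    The shared factor reproduces the strong cross-band correlation of
    real scenes (illumination / vegetation-vigour variation) that makes
    interval-based training expansion meaningful; ``noise_sd`` is the
    only white pixel noise.  Returns ``(n_bands, n_rows, n_cols)``
    float64 DN.  Deterministic for a fixed ``config.seed`` (an
    independent substream from the class-map one).
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    class_ids = sorted(class_map.legend)
    names = [class_map.legend[i] for i in class_ids]
    means, stds = _as_band_model_arrays(
        config.band_models, tuple(names), config.band_names
    )
    rng = np.random.default_rng((config.seed, 1))
    labels = class_map.labels
    n_bands = len(config.band_names)
    sigma_k = config.correlation_range * KERNEL_RANGE_FRACTION
    # one smooth brightness factor per class, demeaned over its footprint
    factor = np.zeros(labels.shape)
    index = np.searchsorted(class_ids, labels)
    for ci in range(len(class_ids)):
        f = gaussian_filter(rng.standard_normal(labels.shape), sigma_k,
                            mode="wrap")
        sd = f.std()
        if sd > 0:
            f /= sd
        mask = index == ci
        if mask.any():
            factor[mask] = f[mask] - f[mask].mean()
    raster = np.empty((n_bands, *labels.shape))
    for bi in range(n_bands):
        raster[bi] = means[index, bi] + stds[index, bi] * factor
    if config.noise_sd > 0:
        raster += rng.standard_normal(raster.shape) * config.noise_sd
    return raster


def generate_scene(config: SceneConfig) -> tuple[ClassMap, np.ndarray]:
    """Class map and matching reflectance raster in one call."""
    cmap = generate_class_map(config)
    return cmap, generate_reflectance(cmap, config)


def write_scene(out_dir: str | Path, config: SceneConfig,
                class_map: ClassMap, raster: np.ndarray) -> dict[str, Path]:
    """Serialize a scene: label TIFF, 8-band float TIFF, config/legend JSON."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels": out / "class_map.tif",
        "reflectance": out / "reflectance.tif",
        "config": out / "scene.json",
        "legend": out / "legend.json",
    }
    tifffile.imwrite(paths["labels"], class_map.labels.astype(np.int32))
    tifffile.imwrite(paths["reflectance"], raster.astype(np.float32))
    paths["config"].write_text(config.to_json())
    paths["legend"].write_text(json.dumps(
        {str(k): v for k, v in class_map.legend.items()}, indent=2))
    return paths
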