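"""Published reference inputs used by the worked example and checks.

Two benchmark error matrices from a WorldView-2 understory-bamboo
mapping assessment over 430 field test points in a shaded montane
panda reserve (six mapped cover classes; the shadow class is excluded
from assessment), one for the plain weighted k-NN classifier and one
for its geostatistically weighted variant, plus the published
per-class interval multipliers used for mu +/- t*sigma training
expansion.  These are inputs to the package's metric functions, not
outputs of this package.
"""

from __future__ import annotations

import numpy as np

from .assessment import ConfusionMatrix

ASSESSED_CLASSES = [
    "bamboo",
    "coniferous",
    "broadleaved",
    "mixed_woodland",
    "brush",
    "barren_land",
]

# rows = predicted, columns = actual
KNN_ERROR_MATRIX = ConfusionMatrix(
    class_names=list(ASSESSED_CLASSES),
    counts=np.array([
        [81, 0, 0, 0, 7, 0],
        [0, 96, 29, 1, 0, 0],
        [1, 2, 39, 11, 6, 0],
        [0, 5, 4, 59, 8, 1],
        [13, 2, 1, 7, 35, 0],
        [3, 0, 0, 1, 0, 18],
    ]),
)

GKNN_ERROR_MATRIX = ConfusionMatrix(
    class_names=list(ASSESSED_CLASSES),
    counts=np.array([
        [81, 0, 0, 0, 6, 0],
        [0, 95, 10, 1, 0, 0],
        [0, 3, 56, 7, 5, 0],
        [0, 5, 3, 62, 8, 0],
        [14, 2, 4, 8, 37, 1],
        [3, 0, 0, 1, 0, 18],
    ]),
)

#: Published per-class interval multipliers for mu +/- t*sigma expansion.
EXPANSION_T = {
    "bamboo": 0.25,
    "coniferous": 0.65,
    "broadleaved": 0.40,
    "mixed_woodland": 0.25,
    "brush": 0.20,
    "barren_land": 0.85,
    "shadow": 0.25,  # shadow multiplier not published; same as bamboo
}

#: Published expansion intervals (lo, hi) per class for the five
#: expansion bands, usable as a cross-check of `spectral_ranges`.
PUBLISHED_EXPANSION_INTERVALS = {
    "bamboo": {
        "green": (150.6, 154.0), "yellow": (95.6, 99.9),
        "red_edge": (120.7, 129.9), "nir1": (116.7, 126.9),
        "nir2": (132.6, 143.7),
    },
    "coniferous": {
        "green": (183.0, 190.2), "yellow": (116.6, 122.1),
        "red_edge": (328.0, 368.7), "nir1": (368.7, 415.1),
        "nir2": (390.8, 446.5),
    },
    "broadleaved": {
        "green": (190.2, 196.4), "yellow": (124.5, 131.3),
        "red_edge": (289.1, 325.5), "nir1": (313.1, 352.6),
        "nir2": (337.3, 381.2),
    },
    "mixed_woodland": {
        "green": (175.4, 183.2), "yellow": (112.8, 119.6),
        "red_edge": (201.4, 248.1), "nir1": (213.7, 268.5),
        "nir2": (227.4, 286.5),
    },
    "brush": {
        "green": (160.0, 166.4), "yellow": (102.4, 109.5),
        "red_edge": (159.5, 172.7), "nir1": (166.3, 182.6),
        "nir2": (186.0, 206.9),
    },
    "barren_land": {
        "green": (166.0, 215.7), "yellow": (97.4, 129.7),
        "red_edge": (78.3, 109.7), "nir1": (55.8, 82.1),
        "nir2": (52.3, 79.6),
    },
}

#: Expansion bands used in the original campaign.
EXPANSION_BANDS = ["green", "yellow", "red_edge", "nir1", "nir2"]

#: Classification features chosen by feature-space optimization there.
CLASSIFICATION_FEATURES = ["yellow", "red", "red_edge", "nir1", "nir2",
                           "glcm_contrast"]
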