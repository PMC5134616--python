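# bamboomap

Object-based mapping of **understory bamboo** from very-high-resolution
8-band multispectral imagery, for ecologists and remote-sensing
practitioners who must classify a fragmented, partly shaded landscape
from only a handful of field plots.  Bamboo is the staple food of the
giant panda; knowing where it grows under the forest canopy is a direct
input to habitat assessment, but the signal is subtle and ground truth
is scarce and expensive to collect on steep terrain.

The package implements the full workflow as a tested library:

1. **Segmentation** of the reflectance raster into image objects
   (greedy variance-minimizing region merging; external label rasters
   can be ingested instead), with per-object band means, GLCM texture
   and geometry features.
2. **Covariance PCA** to rank features and pick the spectral bands that
   drive the first component.
3. **µ±tσ training expansion**: every object whose band means fall
   inside one class's mean ± t·std intervals on the selected bands
   joins the training set, turning ~25 field plots into hundreds of
   training objects.
4. **Feature-space optimization**: exhaustive subset search maximizing
   the mean nearest-other-class distance on standardized features.
5. **Weighted k-NN** classification, and its geostatistical extension —
   the core of the package.
6. **Accuracy assessment**: error matrices, producer's/user's/overall
   accuracy, Cohen's κ; plus fisheye canopy-density estimation.

## The gk-NN classifier

The geostatistically weighted k-NN scores class *m* for a query object
*u* with K feature-space neighbours k = 1..K as

    score(m) = Σ_k ω_uk [ S_g · p_{m,c(k)}(h_uk) + (1 − S_g) · I(c(k) = m) ]
    p(m)     = score(m) / Σ_{m′} score(m′)

where ω_uk is the neighbour weight, h_uk the centroid lag in pixels,
c(k) the neighbour's class, and p_{m,m′}(h) a class-conditional
transition-probability model

    p(h) = sill + (p0 − sill) · g(h; a),   g ∈ {spherical, exponential, Gaussian}

fitted by weighted least squares to the empirical curves

    p̂_{m,m′}(h) = #{pairs (u,v): c(u)=m, c(v)=m′, |u−v| ∈ bin h}
                  / #{pairs (u,v): c(u)=m, |u−v| ∈ bin h}.

S_g = 0 reduces exactly to the plain weighted k-NN vote; larger S_g
gives more weight to spatial plausibility.  See `docs/methods.md` for
the full model description and every default.

Because the original satellite scene is not redistributable, the
package ships a synthetic-scene generator
(`bamboomap.scene`) emulating the study regime — seven spatially
autocorrelated cover classes with published-interval-derived band
models — so the whole pipeline is runnable and testable end to end.

## Worked example

```python
import numpy as np
from bamboomap.reference import KNN_ERROR_MATRIX, GKNN_ERROR_MATRIX
from bamboomap.assessment import accuracies, kappa

for name, cm in [("k-NN", KNN_ERROR_MATRIX), ("gk-NN", GKNN_ERROR_MATRIX)]:
    acc = accuracies(cm)
    print(f"{name}: OA {acc['overall']:.2f}%  kappa {kappa(cm):.3f}  "
          f"bamboo PA {acc['producers']['bamboo']:.2f}%  "
          f"UA {acc['users']['bamboo']:.2f}%")
```

prints

```
k-NN: OA 76.28%  kappa 0.706  bamboo PA 82.65%  UA 92.05%
gk-NN: OA 81.16%  kappa 0.767  bamboo PA 82.65%  UA 93.10%
```

i.e. the benchmark matrices shipped with the package show the spatial
weighting lifting overall accuracy by ~5 points while bamboo stays
reliably mapped (the class that gains most is broadleaved forest:
+23.29 producer's / +12.77 user's points).

The synthetic end-to-end comparison (noisy training labels, S_g = 0.5):

```python
from bamboomap.experiments import gknn_improvement_experiment
r = gknn_improvement_experiment(seed=1)
print(f"k-NN OA {r.knn_oa:.2f}%  gk-NN OA {r.gknn_oa:.2f}%")
```

```
k-NN OA 85.97%  gk-NN OA 86.54%
```

## Analysis scripts

Numbered drivers under `analysis/` run the study pipeline step by step
on the synthetic scene and write their tables under `results/`:

```bash
python analysis/01_simulate_scene.py      # scene + class fractions
python analysis/02_segment_features.py    # objects + feature table
python analysis/03_expand_training.py     # PCA bands + µ±tσ expansion
python analysis/04_optimize_features.py   # separability curve
python analysis/05_classify_and_assess.py # k-NN vs gk-NN maps + metrics
python analysis/06_reference_benchmark.py # published-matrix metrics
python analysis/07_noise_robustness.py    # gk-NN gain across seeds
```

A thin CLI covers the common entry points: `bamboomap scene`,
`bamboomap pipeline`, `bamboomap assess`, `bamboomap canopy`.

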