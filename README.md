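# landcover-kmeans

Pixel-based mapping of cultivated land from high-resolution 4-band
(Blue, Green, Red, NIR) multispectral imagery. The toolkit computes
vegetation/water indices per pixel, clusters a stacked
(NDVI, MNDWI, NIR) feature image with a from-scratch K-means into the
three classes **background / bare soil / crops**, and scores the detected
cultivated-area percentage against a binary ground-truth mask. Three
baseline classifiers — NIR thresholding, NDVI thresholding and K-means on
raw (NIR, Red, Blue) bands — are included for comparison, along with a
synthetic scene generator so the whole pipeline is testable without
restricted satellite data.

Intended users: remote-sensing and agronomy researchers comparing simple
unsupervised pixel classifiers for field-scale agricultural monitoring on
sensors that lack a SWIR band.

## Method

Per pixel, with DN the raw digital numbers of each band:

- NDVI = (NIR − Red) / (NIR + Red) — chlorophyll-sensitive greenness;
- MNDWI = (Green − NIR) / (Green + NIR) — a Green/NIR spectral-contrast
  index used as the SWIR-free stand-in for NDWI.

The proposed classifier stacks (NDVI, MNDWI, NIR) into an n_pixels × 3
matrix, min-max normalizes each feature to [0, 1], and runs Lloyd's
K-means with k = 3 and Euclidean distance
d(x, c) = sqrt(Σ_k (x_k − c_k)²): centroids are initialized from randomly
sampled points (seeded; 10 restarts, best inertia kept), then
nearest-centroid assignment and per-cluster mean updates alternate until
centroids stop moving. Cluster semantics are fixed deterministically:
the cluster holding the majority of zero-padding pixels is *background*,
the higher-NDVI cluster of the remaining two is *crops*, the last is
*soil*.

Accuracy is the relative error of the cultivated-area percentage,

    cultivated % = 100 · (crop pixels) / (total pixels)
    error %      = 100 · |detected − actual| / actual

with the actual percentage taken from an expert-digitized mask.

## Worked example

```python
import landcover_kmeans as lk

# a 512x512 benchmark scene: zero-padded border, soil lanes, 25 crop
# parcels covering ~71% of the image, with known ground truth
scene, mask, truth = lk.generate_scene(lk.default_scene_spec(seed=0))

for name, cls in lk.CLASSIFIERS.items():
    est = cls() if "threshold" in name else cls(random_state=0)
    detected = lk.cultivated_percentage(est.fit_predict(scene))
    print(f"{name:16s} detected {detected:6.2f}%  "
          f"error {lk.relative_error(detected, truth):5.2f}%")
```

prints

```
nir-threshold    detected  65.06%  error  7.76%
ndvi-threshold   detected  71.85%  error  1.87%
kmeans-bands     detected  70.47%  error  0.09%
spectral-kmeans  detected  70.52%  error  0.01%
```

The true cultivated share is 70.53%. The fixed NIR threshold (700 DN)
misses dimly lit crop pixels and underestimates by almost 8%; the fixed
NDVI cut-off (0.2) sits too close to the soil NDVI distribution and
overestimates; clustering adapts its decision boundary to the scene and
the index-based feature stack, being nearly invariant to illumination,
recovers the truth to a few hundredths of a percent.

The same workflow is available from the shell:

```
landcover-kmeans simulate --height 512 --width 512 --seed 0 \
    --out-scene scene.tif --out-mask mask.tif
landcover-kmeans compare --scene scene.tif --mask mask.tif --seed 0
landcover-kmeans classify --scene scene.tif --mask mask.tif \
    --method spectral-kmeans --out-labels labels.tif --out-color labels.png
```

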