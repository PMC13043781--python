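# Methods

## Problem and scope

The toolkit estimates the cultivated share of an agricultural scene from a
single 4-band (Blue, Green, Red, NIR) high-resolution image, without
training labels. Each pixel is classified into one of three classes —
background (the zero-padded frame left where the rotated sensor footprint
does not cover the raster grid), bare soil, and crops — and the crops
share of the image is compared with an expert-digitized binary mask via
the relative error |detected − actual| / actual × 100.

All computations operate on raw digital numbers (DN). No radiometric
calibration is applied: the classification thresholds (NIR 700 DN, NDVI
0.2) are defined on the DN scale, and rescaling would silently change
their meaning. The DN bit depth of the source product is not prescribed;
the synthetic generator uses an 11-bit-like [0, 2047] range so the 700
threshold is interior to it.

A pixel is *background* iff all four bands equal the scene's nodata value
(default 0). This purely radiometric definition replaces vaguer criteria
("index close to zero"), which are circular because soil NDVI also
straddles zero.

## Spectral indices

Eight per-pixel indices are provided (NDVI, MNDWI, EVI, SAVI, GCI, CVI,
DVI, NDWI), each a pure map with no smoothing or clipping. Constants:
SAVI soil-adjustment L = 0.5; EVI L = 1, C1 = 6, C2 = 7.5.

Degenerate denominators (exactly 0, typically the zero background) yield
the value 0 and a flag in a `degenerate` mask — never NaN/inf — so
downstream clustering always receives finite features and background
pixels naturally sit at index 0.

Two formula variants deserve note. The EVI implemented by default carries
no leading gain factor (pass `gain=2.5` for the common literature form),
and CVI defaults to NIR/(Red − Green) with the usual NIR·Red/Green² form
behind `literature_form=True`. NDWI in its traditional form requires a
SWIR band this sensor does not record, so `ndwi()` always raises and
MNDWI (Green vs NIR) serves as the SWIR-free contrast index.

## Classifiers

1. **NIR threshold.** NIR = 0 → background; (0, 700] → soil; > 700 →
   crops. Boundary inclusivity follows from "greater than 700" defining
   crops: exactly 700 is soil.
2. **NDVI threshold.** Background by the nodata test; else NDVI ≤ 0.2 →
   soil, > 0.2 → crops.
3. **Band K-means.** Stack (NIR, Red, Blue), min-max normalize each
   feature over all pixels (background included; a constant feature maps
   to all zeros), cluster with k = 3.
4. **Spectral K-means** (the method of interest). Stack
   (NDVI, MNDWI, NIR), normalize and cluster identically. The two index
   features are ratios and hence nearly invariant to multiplicative
   brightness changes, which is the source of this variant's robustness.

K-means clusters carry no semantics, so a deterministic labeling rule
makes the three-class claim executable: the cluster receiving the
majority of the scene's background pixels is *background* (if the scene
has none: the cluster with the smallest centroid norm); of the remaining
two, the cluster with the higher mean pre-normalization NDVI over its
members is *crops* (band stacks carry no NDVI column, so higher mean NIR
is used); ties break toward higher mean NIR, then lower cluster index.
After mapping, any scene-background pixel that strayed into another
cluster is forced to the background label, keeping the class-map contract
(background pixels always map to background) unconditional.

Background pixels are included in the clustering input by default — the
background class is one of the three clusters by design. With
`include_background=False` the background is pre-masked instead; only two
land classes then remain, so the land pixels are split into two clusters
(higher-NDVI cluster = crops) and background is assigned directly. Both
modes agree on well-separated scenes.

## K-means core

Lloyd's algorithm, written out in this package (scikit-learn's KMeans
appears only as an independent cross-check in the test suite):

- *Initialization*: k distinct input points sampled uniformly without
  replacement (Forgy), seeded via `random_state`.
- *Assignment*: nearest centroid by Euclidean distance, compared on
  squares internally; ties go to the lowest centroid index.
- *Update*: per-cluster mean. An empty cluster is repaired by moving its
  centroid to the point currently farthest from its assigned centroid
  (distinct points for multiple repairs) — deterministic.
- *Convergence*: maximum absolute per-coordinate centroid displacement
  ≤ `tol` (default 1e-4; the source procedure says only "until the
  centroids no longer change", so the tolerance is an explicit,
  configurable operationalization). `max_iter` defaults to 300, likewise
  an artifact choice since no value is prescribed.
- *Restarts*: `n_init` runs with seeds `random_state`, `random_state+1`,
  …, keeping the lowest final inertia. The scene classifiers default to
  `n_init=10`. This matters: with ~70% of pixels in one class, a single
  random initialization frequently places two centroids inside the
  dominant cluster and converges to a local optimum that splits it while
  merging soil with background; restarts reliably find the
  lower-inertia three-population partition.

Identical (data, parameters, seed) gives bit-identical results. The
objective value after every assignment step is logged
(`inertia_history_`), and is non-increasing by construction.

## Synthetic scenes

The generator emulates the structure of the target imagery: a zero
border (the rotated-footprint padding), a soil interior, and axis-aligned
rectangular crop parcels that define the ground-truth mask exactly.

Radiometry per pixel and band:

    DN = clip(gain · mean_class,band + ε_band,  0, 2047)

with ε ~ N(0, sd_class,band) additive sensor/texture noise (default sd
40 DN for every class and band) and `gain` a per-pixel illumination
factor shared across the four bands, gain ~ N(1, 0.15) clipped below at
0.1. The gain term models brightness variation from illumination,
topography and within-field heterogeneity; it is the physically motivated
mechanism that separates the methods, because it moves raw DNs
proportionally while leaving band ratios almost unchanged.

Default class spectra (mean DN): soil B/G/R/NIR = 420/520/370/450, crops
= 310/490/270/900. These satisfy the classification conventions with
margin on one side and deliberately not the other: crop NIR (900) exceeds
700, but its illumination spread puts ~7% of crop pixels below the
threshold, so NIR thresholding underestimates; soil NDVI (≈0.10) is
below 0.2, but additive noise pushes a few percent of soil pixels above
it, so NDVI thresholding overestimates; both K-means variants adapt
their boundaries to the scene and recover the truth to ≲0.1%, with the
spectral stack consistently the most accurate. The benchmark scene
(`default_scene_spec`) is a 5×5 grid of square parcels separated by soil
lanes, integer parcel sides chosen so the cultivated share tracks ~70.5%
of the full image at any raster size (70.53% at 512×512).

What the generator does **not** emulate: spatially correlated texture,
mixed boundary pixels, atmospheric effects, sensor PSF, multiple crop
types and phenology. Passing tests therefore demonstrate the algorithmic
correctness and the illumination-robustness ranking of the methods, not
performance on real imagery.

## Evaluation conventions

The denominator of the cultivated percentage defaults to *all* pixels,
zero-padding included (`include_background=True`), matching the
convention "total area from pixel count × pixel area"; the flag switches
to land-only accounting. Percentages are rounded to two decimals only at
presentation. The relative-error form requires a positive reference and
is scale-invariant: error(c·d, c·a) = error(d, a).

The area report converts pixel counts with pixel_area = GSD², 0.25 m² at
the default 0.5 m ground sampling distance.

## I/O and formats

Scenes, masks and label maps are plain multi-page TIFFs (tifffile), one
page per band, row-major with origin top-left; scene metadata (pixel
size, optional 6-tuple affine geotransform, nodata value) rides in the
ImageDescription tag as JSON, giving lossless round-trips. Band order in
a file is always an explicit argument (default blue, green, red, nir) —
never guessed from metadata, since a silent RGB/BGR mix-up corrupts every
index. Label maps use uint8 codes 0/1/2 with an optional RGB composite
(white = background, brown = soil, green = crops; the palette is an
artifact choice, only the three-way distinction is meaningful).

## Problem sizes and runtime

The documented benchmark runs at 512×512 (262,144 pixels, 3 features,
k = 3, 10 restarts), where the full four-method comparison completes in
seconds; unit and property tests use 64–128 px scenes and ≤10-point
instances for the exhaustive K-means optimality oracle. These sizes are
the package's reference configuration for reproducible results.

## Known limitations

- The cluster→class rule assumes exactly three clusters; other k values
  are rejected rather than guessed at.
- Min-max normalization is sensitive to single extreme pixels (a clipped
  band can place an NDVI of ±1 at the range edge); with the default
  spectra this compresses but never breaks the class separations.
- The NIR 700 DN threshold is sensor- and scale-specific; on data with a
  different bit depth it must be re-specified by the user.
- Scenes are processed in memory as float64; very large rasters would
  need tiling, which is out of scope.
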