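"""The four pixel-based classifiers: two fixed-threshold rules and two
K-means variants, all mapping a scene to a three-class map
(background / soil / crops).

* NIR thresholding: DN 0 -> background, (0, 700] -> soil, > 700 -> crops.
* NDVI thresholding: background by the all-bands-nodata test, then
  NDVI <= 0.2 -> soil, NDVI > 0.2 -> crops.
* Band K-means: cluster the (NIR, Red, Blue) stack, min-max normalized to
  [0, 1], with K = 3.
* Spectral K-means (the proposed method): cluster the (NDVI, MNDWI, NIR)
  stack, min-max normalized, K = 3.

K-means clusters carry no semantics, so :func:`label_clusters` fixes the
cluster -> class correspondence: the cluster holding the majority of the
scene's background pixels becomes *background* (fallback: smallest centroid
norm), the higher-mean-NDVI cluster of the remaining two becomes *crops*
(band stacks: higher mean NIR), and the last is *soil*.

All classifiers are sklearn-style estimators (fit / predict /
get_params / set_params); the module-level ``classify_*`` functions are
thin conveniences over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ValidationError
from .indices import mndwi, ndvi
from .kmeans import ClusterModel, KMeans, assign
from .scene import MultispectralScene

BACKGROUND, SOIL, CROPS = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", SOIL: "soil", CROPS: "crops"}

DEFAULT_NIR_SOIL_UPPER = 700.0
DEFAULT_NDVI_CROP_LOWER = 0.2


@dataclass
class FeatureStack:
    """Per-pixel feature matrix with its normalization record.

    ``features`` is (n_pixels, n_features), min-max scaled to [0, 1] per
    feature; ``norm_record`` keeps each feature's pre-scaling (min, max) so
    original values are exactly recoverable (constant features scale to all
    zeros and recover to their constant). Rows enumerate pixels in row-major
    order over the source grid of shape ``scene_shape``.
    """

    features: np.ndarray
    feature_names: tuple
    norm_record: tuple
    scene_shape: tuple

    @property
    def n_pixels(self) -> int:
        return self.features.shape[0]

    def pixel_index(self, row: int) -> tuple[int, int]:
        """Map a feature-matrix row to its (row, col) grid position."""
        _, width = self.scene_shape
        return divmod(row, width)

    def raw_feature(self, i: int) -> np.ndarray:
        """Reconstruct feature column ``i`` on its original scale."""
        lo, hi = self.norm_record[i]
        return self.features[:, i] * (hi - lo) + lo

    def raw_column(self, name: str) -> np.ndarray:
        return self.raw_feature(self.feature_names.index(name))


def _minmax(columns: list[np.ndarray]):
    normed, record = [], []
    for col in columns:
        lo, hi = float(col.min()), float(col.max())
        record.append((lo, hi))
        if hi > lo:
            normed.append((col - lo) / (hi - lo))
        else:
            normed.append(np.zeros_like(col))  # constant feature -> all zeros
    return np.column_stack(normed), tuple(record)


def build_band_stack(scene: MultispectralScene) -> FeatureStack:
    """Stack raw (NIR, Red, Blue) bands, min-max normalized to [0, 1]."""
    cols = [scene.nir.ravel(), scene.red.ravel(), scene.blue.ravel()]
    features, record = _minmax(cols)
    return FeatureStack(features, ("nir", "red", "blue"), record, scene.shape)


def build_spectral_stack(scene: MultispectralScene) -> FeatureStack:
    """Stack (NDVI, MNDWI, NIR), each min-max normalized to [0, 1].

    Degenerate index pixels (zero denominator, i.e. the zero background)
    enter as index value 0 before normalization.
    """
    cols = [ndvi(scene).values.ravel(), mndwi(scene).values.ravel(), scene.nir.ravel()]
    features, record = _minmax(cols)
    return FeatureStack(features, ("ndvi", "mndwi", "nir"), record, scene.shape)


@dataclass
class ClassMap:
    """Per-pixel label grid over {background=0, soil=1, crops=2}."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)
    cluster_to_class: dict | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError("labels must form a 2-D grid")
        if not np.isin(arr, (BACKGROUND, SOIL, CROPS)).all():
            raise ValidationError("labels must be in {0, 1, 2}")
        self.labels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict:
        return {name: int(np.sum(self.labels == code)) for code, name in CLASS_NAMES.items()}


def label_clusters(model: ClusterModel, stack: FeatureStack,
                   scene: MultispectralScene) -> dict:
    """Assign semantics to the three K-means clusters.

    background := the cluster holding the majority of the scene's background
    (all-bands-nodata) pixels; if the scene has none, the cluster whose
    centroid has the smallest Euclidean norm. crops := of the remaining two,
    the cluster with the higher mean pre-normalization NDVI over its member
    pixels (band stacks carry no NDVI column: higher mean NIR instead); ties
    break toward higher mean NIR, then lower cluster index. soil := the rest.
    """
    k = model.centroids.shape[0]
    if k != 3:
        raise ValidationError(f"semantic labeling requires exactly 3 clusters, got {k}")

    assignments = np.asarray(model.assignments)
    bg_flat = scene.background_mask().ravel()
    if bg_flat.any():
        counts = np.bincount(assignments[bg_flat], minlength=3)
        background_cluster = int(np.argmax(counts))
    else:
        background_cluster = int(np.argmin(np.linalg.norm(model.centroids, axis=1)))

    primary = "ndvi" if "ndvi" in stack.feature_names else "nir"
    primary_col = stack.raw_column(primary)
    nir_col = stack.raw_column("nir")

    remaining = [j for j in range(3) if j != background_cluster]

    def cluster_score(j: int):
        member = assignments == j
        if member.any():
            return (float(primary_col[member].mean()), float(nir_col[member].mean()), -j)
        # empty cluster: fall back to its (denormalized) centroid coordinates
        p_i = stack.feature_names.index(primary)
        n_i = stack.feature_names.index("nir")
        lo_p, hi_p = stack.norm_record[p_i]
        lo_n, hi_n = stack.norm_record[n_i]
        return (model.centroids[j, p_i] * (hi_p - lo_p) + lo_p,
                model.centroids[j, n_i] * (hi_n - lo_n) + lo_n, -j)

    crops_cluster = max(remaining, key=cluster_score)
    soil_cluster = next(j for j in remaining if j != crops_cluster)
    return {background_cluster: BACKGROUND, soil_cluster: SOIL, crops_cluster: CROPS}


class NIRThresholdClassifier(BaseEstimator):
    """Fixed-threshold rule on the NIR band.

    NIR = 0 -> background; 0 < NIR <= soil_upper -> soil;
    NIR > soil_upper -> crops.
    """

    def __init__(self, soil_upper: float = DEFAULT_NIR_SOIL_UPPER):
        self.soil_upper = soil_upper

    def fit(self, scene: MultispectralScene, y=None):
        self.scene_shape_ = scene.shape
        return self

    def predict(self, scene: MultispectralScene) -> ClassMap:
        nir = scene.nir
        if np.any(nir < 0):
            raise ValidationError("NIR band contains negative digital numbers")
        labels = np.full(nir.shape, SOIL, dtype=np.uint8)
        labels[nir == 0] = BACKGROUND
        labels[nir > self.soil_upper] = CROPS
        return ClassMap(labels, provenance={
            "classifier": "nir-threshold", "soil_upper": self.soil_upper})

    def fit_predict(self, scene: MultispectralScene) -> ClassMap:
        return self.fit(scene).predict(scene)


class NDVIThresholdClassifier(BaseEstimator):
    """Fixed-threshold rule on NDVI.

    Background by the all-bands-nodata test; otherwise NDVI in (-1,
    crop_lower] -> soil and NDVI > crop_lower -> crops.
    """

    def __init__(self, crop_lower: float = DEFAULT_NDVI_CROP_LOWER):
        self.crop_lower = crop_lower

    def fit(self, scene: MultispectralScene, y=None):
        self.scene_shape_ = scene.shape
        return self

    def predict(self, scene: MultispectralScene) -> ClassMap:
        values = ndvi(scene).values
        labels = np.full(values.shape, SOIL, dtype=np.uint8)
        labels[values > self.crop_lower] = CROPS
        labels[scene.background_mask()] = BACKGROUND
        return ClassMap(labels, provenance={
            "classifier": "ndvi-threshold", "crop_lower": self.crop_lower})

    def fit_predict(self, scene: MultispectralScene) -> ClassMap:
        return self.fit(scene).predict(scene)


class _KMeansSceneClassifier(BaseEstimator):
    """Shared machinery for the two clustering classifiers."""

    stack_name = ""

    def __init__(self, n_clusters: int = 3, random_state: int = 0,
                 max_iter: int = 300, tol: float = 1e-4,
                 include_background: bool = True, n_init: int = 10):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.include_background = include_background
        self.n_init = n_init

    def _build_stack(self, scene: MultispectralScene) -> FeatureStack:
        raise NotImplementedError

    def fit(self, scene: MultispectralScene, y=None):
        if self.n_clusters != 3:
            raise ValidationError(
                "the three-class land-cover semantics require n_clusters=3"
            )
        stack = self._build_stack(scene)
        bg_flat = scene.background_mask().ravel()

        if self.include_background or not bg_flat.any():
            # default mode: background is simply the third cluster
            est = KMeans(n_clusters=self.n_clusters, max_iter=self.max_iter,
                         tol=self.tol, random_state=self.random_state,
                         n_init=self.n_init)
            est.fit(stack.features)
            model = est.to_model()
            self.cluster_to_class_ = label_clusters(model, stack, scene)
        else:
            # background pre-masked: only soil and crops remain, so the
            # land pixels are split into two clusters and background is
            # assigned directly from the nodata test
            est = KMeans(n_clusters=2, max_iter=self.max_iter,
                         tol=self.tol, random_state=self.random_state,
                         n_init=self.n_init)
            est.fit(stack.features[~bg_flat])
            assignments = est.predict(stack.features)
            model = est.to_model()
            model.assignments = assignments
            primary = "ndvi" if "ndvi" in stack.feature_names else "nir"
            land = ~bg_flat
            scores = []
            for j in range(2):
                member = land & (assignments == j)
                scores.append((float(stack.raw_column(primary)[member].mean()),
                               float(stack.raw_column("nir")[member].mean()), -j))
            crops_cluster = max(range(2), key=lambda j: scores[j])
            self.cluster_to_class_ = {crops_cluster: CROPS,
                                      1 - crops_cluster: SOIL}

        self.stack_ = stack
        self.kmeans_ = est
        self.model_ = model
        return self

    def predict(self, scene: MultispectralScene) -> ClassMap:
        if not hasattr(self, "model_"):
            raise ValidationError(f"{type(self).__name__} is not fitted yet")
        stack = self._build_stack(scene)
        assignments = assign(stack.features, self.model_.centroids)
        n_found = self.model_.centroids.shape[0]
        lut = np.array([self.cluster_to_class_[j] for j in range(n_found)],
                       dtype=np.uint8)
        labels = lut[assignments].reshape(scene.shape)
        # the class-map contract: scene background pixels are always labeled
        # background, whatever cluster the zero-feature point landed in
        labels[scene.background_mask()] = BACKGROUND
        return ClassMap(
            labels,
            provenance={
                "classifier": self.stack_name,
                "k": self.n_clusters,
                "seed": self.random_state,
                "n_iter": self.model_.n_iter,
                "inertia": self.model_.inertia,
                "include_background": self.include_background,
            },
            cluster_to_class=dict(self.cluster_to_class_),
        )

    def fit_predict(self, scene: MultispectralScene) -> ClassMap:
        return self.fit(scene).predict(scene)


class BandKMeansClassifier(_KMeansSceneClassifier):
    """K-means (K=3) on the min-max normalized (NIR, Red, Blue) stack."""

    stack_name = "kmeans-bands"

    def _build_stack(self, scene: MultispectralScene) -> FeatureStack:
        return build_band_stack(scene)


class SpectralKMeansClassifier(_KMeansSceneClassifier):
    """K-means (K=3) on the min-max normalized (NDVI, MNDWI, NIR) stack —
    the proposed spectral method."""

    stack_name = "spectral-kmeans"

    def _build_stack(self, scene: MultispectralScene) -> FeatureStack:
        return build_spectral_stack(scene)


def classify_nir_threshold(scene: MultispectralScene,
                           soil_upper: float = DEFAULT_NIR_SOIL_UPPER) -> ClassMap:
    return NIRThresholdClassifier(soil_upper=soil_upper).fit_predict(scene)


def classify_ndvi_threshold(scene: MultispectralScene,
                            crop_lower: float = DEFAULT_NDVI_CROP_LOWER) -> ClassMap:
    return NDVIThresholdClassifier(crop_lower=crop_lower).fit_predict(scene)


def classify_kmeans(stack: FeatureStack, scene: MultispectralScene, k: int = 3,
                    seed: int = 0, max_iter: int = 300, tol: float = 1e-4,
                    n_init: int = 10) -> ClassMap:
    """Cluster a pre-built feature stack and return the semantic class map."""
    if k != 3:
        raise ValidationError("the three-class land-cover semantics require k=3")
    est = KMeans(n_clusters=k, max_iter=max_iter, tol=tol, random_state=seed,
                 n_init=n_init)
    est.fit(stack.features)
    model = est.to_model()
    mapping = label_clusters(model, stack, scene)
    lut = np.array([mapping[j] for j in range(3)], dtype=np.uint8)
    labels = lut[model.assignments].reshape(stack.scene_shape)
    labels[scene.background_mask()] = BACKGROUND
    name = "spectral-kmeans" if "ndvi" in stack.feature_names else "kmeans-bands"
    return ClassMap(
        labels,
        provenance={"classifier": name, "k": k, "seed": seed,
                    "n_iter": model.n_iter, "inertia": model.inertia},
        cluster_to_class=mapping,
    )


CLASSIFIERS = {
    "nir-threshold": NIRThresholdClassifier,
    "ndvi-threshold": NDVIThresholdClassifier,
    "kmeans-bands": BandKMeansClassifier,
    "spectral-kmeans": SpectralKMeansClassifier,
}
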