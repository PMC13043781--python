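"""The four pixel classifiers: threshold rules, feature stacks, cluster
semantics and determinism."""

import numpy as np
import pytest

from landcover_kmeans import (
    BACKGROUND,
    CROPS,
    SOIL,
    BandKMeansClassifier,
    MultispectralScene,
    NDVIThresholdClassifier,
    NIRThresholdClassifier,
    SpectralKMeansClassifier,
    ValidationError,
    build_band_stack,
    build_spectral_stack,
    classify_kmeans,
    classify_ndvi_threshold,
    classify_nir_threshold,
    generate_scene,
    label_clusters,
)
from landcover_kmeans.kmeans import KMeans


class TestThresholdClassifiers:
    def test_nir_rule_boundaries(self, tiny_scene):
        labels = classify_nir_threshold(tiny_scene).labels
        assert labels[0, 0] == BACKGROUND          # NIR = 0
        assert labels[1, 0] == SOIL                # NIR = 700 (inclusive)
        assert labels[1, 1] == CROPS               # NIR = 700.01
        assert labels[0, 2] == CROPS               # NIR = 900

    def test_nir_uniform_crops(self):
        one = np.full((4, 4), 900.0)
        cm = classify_nir_threshold(MultispectralScene(blue=one, green=one,
                                                       red=one, nir=one))
        assert (cm.labels == CROPS).all()

    def test_ndvi_rule(self, tiny_scene):
        labels = classify_ndvi_threshold(tiny_scene).labels
        assert labels[0, 0] == BACKGROUND          # all-zero pixel
        # NIR=900, Red=270 -> NDVI 0.538 > 0.2
        assert labels[0, 2] == CROPS
        # NIR=450, Red=370 -> NDVI 0.098 <= 0.2
        assert labels[0, 1] == SOIL
        # NDVI exactly 0.2 is soil: NIR=600, Red=400
        s = MultispectralScene(blue=np.ones((1, 1)), green=np.ones((1, 1)),
                               red=np.full((1, 1), 400.0), nir=np.full((1, 1), 600.0))
        assert classify_ndvi_threshold(s).labels[0, 0] == SOIL

    def test_pixel_order_invariance(self, tiny_scene):
        """Threshold rules are per-pixel: transposing the scene transposes
        the labels."""
        t = MultispectralScene(blue=tiny_scene.blue.T, green=tiny_scene.green.T,
                               red=tiny_scene.red.T, nir=tiny_scene.nir.T)
        for fn in (classify_nir_threshold, classify_ndvi_threshold):
            np.testing.assert_array_equal(fn(t).labels, fn(tiny_scene).labels.T)


class TestFeatureStacks:
    def test_band_stack_minmax(self):
        nir = np.array([[0.0, 1000.0]])
        red = np.array([[0.0, 500.0]])
        blue = np.array([[0.0, 250.0]])
        s = MultispectralScene(blue=blue, green=blue, red=red, nir=nir)
        st = build_band_stack(s)
        assert st.feature_names == ("nir", "red", "blue")
        np.testing.assert_allclose(st.features, [[0, 0, 0], [1, 1, 1]])

    def test_constant_feature_maps_to_zero(self):
        one = np.full((2, 2), 7.0)
        var = np.array([[1.0, 2.0], [3.0, 4.0]])
        s = MultispectralScene(blue=var, green=var, red=var, nir=one)
        st = build_band_stack(s)
        assert (st.features[:, 0] == 0).all()
        np.testing.assert_allclose(st.raw_feature(0), 7.0)  # reconstructable

    def test_spectral_stack_values_and_bounds(self):
        nir = np.array([[0.0, 900.0, 450.0]])
        red = np.array([[0.0, 100.0, 370.0]])
        green = np.array([[0.0, 200.0, 520.0]])
        s = MultispectralScene(blue=green, green=green, red=red, nir=nir)
        st = build_spectral_stack(s)
        assert st.feature_names == ("ndvi", "mndwi", "nir")
        # background pixel contributes (0, 0, 0) pre-normalization
        np.testing.assert_allclose(st.raw_feature(0)[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(st.raw_feature(0)[1], 0.8, atol=1e-12)  # 800/1000
        np.testing.assert_allclose(st.raw_feature(1)[1], -700.0 / 1100.0, atol=1e-12)
        assert st.features.min() >= 0.0 and st.features.max() <= 1.0

    def test_normalization_reconstruction(self, small_benchmark):
        scene, _, _ = small_benchmark
        st = build_spectral_stack(scene)
        assert (st.features >= 0).all() and (st.features <= 1).all()
        np.testing.assert_allclose(st.raw_column("nir"), scene.nir.ravel(),
                                   rtol=0, atol=1e-9)

    def test_pixel_index_row_major(self, tiny_scene):
        st = build_band_stack(tiny_scene)
        assert st.pixel_index(0) == (0, 0)
        assert st.pixel_index(4) == (1, 1)
        assert st.pixel_index(8) == (2, 2)


class TestLabelClusters:
    def _model(self, stack, assignments, centroids=None):
        k = KMeans(n_clusters=3)
        if centroids is None:
            centroids = np.stack([stack.features[assignments == j].mean(axis=0)
                                  for j in range(3)])
        k.cluster_centers_ = centroids
        k.labels_ = np.asarray(assignments)
        k.inertia_, k.n_iter_, k.converged_, k.inertia_history_ = 0.0, 1, True, []
        return k.to_model()

    def test_majority_background_then_ndvi_ordering(self, small_benchmark):
        scene, mask, _ = small_benchmark
        st = build_spectral_stack(scene)
        bg = scene.background_mask().ravel()
        crop = mask.mask.ravel().astype(bool) & ~bg
        assignments = np.where(bg, 1, np.where(crop, 2, 0))
        mapping = label_clusters(self._model(st, assignments), st, scene)
        assert mapping == {1: BACKGROUND, 0: SOIL, 2: CROPS}

    def test_no_background_falls_back_to_centroid_norm(self, noiseless_half_scene):
        scene, mask, _ = generate_scene(noiseless_half_scene)
        st = build_spectral_stack(scene)
        crop = mask.mask.ravel().astype(bool)
        assignments = np.where(crop, 2, 0).astype(int)
        assignments[0] = 1  # give cluster 1 a token low-norm membership
        st.features[0] = 0.0
        mapping = label_clusters(self._model(st, assignments), st, scene)
        assert mapping[1] == BACKGROUND and mapping[2] == CROPS and mapping[0] == SOIL

    def test_requires_k3(self, small_benchmark):
        scene, _, _ = small_benchmark
        st = build_spectral_stack(scene)
        k = KMeans(n_clusters=2)
        k.cluster_centers_ = np.zeros((2, 3))
        k.labels_ = np.zeros(st.n_pixels, dtype=int)
        k.inertia_, k.n_iter_, k.converged_, k.inertia_history_ = 0.0, 1, True, []
        with pytest.raises(ValidationError):
            label_clusters(k.to_model(), st, scene)


class TestKMeansClassifiers:
    @pytest.mark.parametrize("cls", [BandKMeansClassifier, SpectralKMeansClassifier])
    def test_recovers_generating_labels(self, cls, small_benchmark):
        scene, mask, _ = small_benchmark
        cm = cls(random_state=0).fit_predict(scene)
        truth = np.where(scene.background_mask(), BACKGROUND,
                         np.where(mask.mask == 1, CROPS, SOIL))
        agreement = np.mean(cm.labels == truth)
        assert agreement >= 0.99
        assert set(cm.cluster_to_class.values()) == {BACKGROUND, SOIL, CROPS}

    def test_deterministic_under_seed(self, small_benchmark):
        scene, _, _ = small_benchmark
        a = SpectralKMeansClassifier(random_state=3).fit_predict(scene)
        b = SpectralKMeansClassifier(random_state=3).fit_predict(scene)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_background_pixels_always_background(self, small_benchmark):
        scene, _, _ = small_benchmark
        bg = scene.background_mask()
        for cls in (NIRThresholdClassifier, NDVIThresholdClassifier,
                    BandKMeansClassifier, SpectralKMeansClassifier):
            cm = cls().fit_predict(scene)
            assert (cm.labels[bg] == BACKGROUND).all()

    def test_labels_partition_scene(self, small_benchmark):
        scene, _, _ = small_benchmark
        cm = SpectralKMeansClassifier().fit_predict(scene)
        assert cm.shape == scene.shape
        assert sum(cm.class_counts().values()) == scene.height * scene.width

    def test_exclude_background_mode(self, small_benchmark):
        scene, mask, _ = small_benchmark
        cm = SpectralKMeansClassifier(include_background=False).fit_predict(scene)
        assert (cm.labels[scene.background_mask()] == BACKGROUND).all()
        truth = np.where(scene.background_mask(), BACKGROUND,
                         np.where(mask.mask == 1, CROPS, SOIL))
        assert np.mean(cm.labels == truth) >= 0.99

    def test_k_must_be_three(self, small_benchmark):
        scene, _, _ = small_benchmark
        with pytest.raises(ValidationError):
            SpectralKMeansClassifier(n_clusters=1).fit(scene)
        with pytest.raises(ValidationError):
            classify_kmeans(build_band_stack(scene), scene, k=1)

    def test_classify_kmeans_wrapper_matches_estimator(self, small_benchmark):
        scene, _, _ = small_benchmark
        st = build_spectral_stack(scene)
        a = classify_kmeans(st, scene, k=3, seed=0)
        b = SpectralKMeansClassifier(random_state=0).fit_predict(scene)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.provenance["classifier"] == "spectral-kmeans"
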