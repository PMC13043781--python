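import numpy as np
import pytest

from landcover_kmeans import MultispectralScene, SyntheticSceneSpec, generate_scene


@pytest.fixture
def tiny_scene() -> MultispectralScene:
    """3x3 scene with one background pixel, soil and crop DN values."""
    nir = np.array([[0.0, 450.0, 900.0],
                    [700.0, 700.01, 1200.0],
                    [300.0, 800.0, 500.0]])
    red = np.array([[0.0, 370.0, 270.0],
                    [500.0, 200.0, 300.0],
                    [350.0, 100.0, 450.0]])
    green = np.array([[0.0, 520.0, 490.0],
                      [450.0, 300.0, 350.0],
                      [400.0, 250.0, 480.0]])
    blue = np.array([[0.0, 420.0, 310.0],
                     [380.0, 260.0, 280.0],
                     [330.0, 200.0, 410.0]])
    return MultispectralScene(blue=blue, green=green, red=red, nir=nir)


@pytest.fixture
def small_benchmark():
    """A small separable synthetic scene: zero border, soil interior, one
    crop parcel; mild noise so every classifier should recover the truth."""
    spec = SyntheticSceneSpec(
        height=96, width=96, background_border=8,
        parcels=[(20, 20, 60, 76)],
        gain_sd=0.05, seed=11,
    )
    return generate_scene(spec)


@pytest.fixture
def noiseless_half_scene():
    """Zero-noise scene, no border, crops covering exactly half the image."""
    spec = SyntheticSceneSpec(
        height=40, width=40, background_border=0,
        parcels=[(0, 0, 40, 20)],
        gain_sd=0.0, seed=0,
    )
    return spec.scaled_noise(0.0)
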