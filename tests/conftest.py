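import numpy as np
import pytest

from mtocquant.datatypes import GroundTruth, NoiseParams, SceneParams

NOISELESS = NoiseParams(poisson_gain=0.0, read_sd=0.0)


@pytest.fixture
def still_scene() -> SceneParams:
    return SceneParams(image_shape=(256, 256), frame_interval=None)


@pytest.fixture
def movie_scene() -> SceneParams:
    return SceneParams(image_shape=(192, 192), frame_interval=0.1)


@pytest.fixture
def clean_truth() -> GroundTruth:
    """Noise-free ground truth with zero backgrounds for exactness checks."""
    return GroundTruth(
        enrichment_ratio=3.0, cyto_level=100.0, slide_bg=0.0,
        haze_level=0.0, autofluo_level=0.0, embryo_cv=0.0, noise=NOISELESS,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
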