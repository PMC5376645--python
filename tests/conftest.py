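import numpy as np
import pytest

from ocuquant.registration import SimilarityTransform
from ocuquant.synthetic import SceneConfig, generate_vessel_scene

ON_CENTER = (128, 36)
ON_RADIUS = 18
BAND = (80, 176)


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, identity-registered scene with moderate extravasation."""
    config = SceneConfig(
        leak_intensity=0.5, noise_sigma=0.0, landmark_jitter_sigma=0.0, seed=3
    )
    return generate_vessel_scene(config)


@pytest.fixture(scope="session")
def misregistered_scene():
    """Noiseless scene with a known similarity mis-registration."""
    transform = SimilarityTransform(
        scale=1.02, rotation=np.deg2rad(5.0), translation=(4.0, -6.0)
    )
    config = SceneConfig(
        leak_intensity=0.5,
        noise_sigma=0.0,
        landmark_jitter_sigma=0.0,
        transform_true=transform,
        seed=3,
    )
    return generate_vessel_scene(config)


def random_similarity(rng, max_rotation_deg=10.0, max_shift=10.0, scale_band=0.03):
    """A random similarity transform within the stated mis-registration budget."""
    return SimilarityTransform(
        scale=float(rng.uniform(1 - scale_band, 1 + scale_band)),
        rotation=float(np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))),
        translation=tuple(rng.uniform(-max_shift, max_shift, size=2)),
    )
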