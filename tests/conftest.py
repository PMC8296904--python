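import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from eeglocate import (
    LabeledPoints,
    SimilarityTransform,
    generate_cap,
    training_template,
)


@pytest.fixture(scope="session")
def default_cap() -> LabeledPoints:
    """One synthetic 65-electrode cap (seed 0)."""
    return generate_cap(seed=0)


@pytest.fixture(scope="session")
def cap_template():
    """Average template from 12 simulated training caps (seed 0)."""
    return training_template(seed=0)


def random_similarity(
    rng: np.random.Generator,
    max_rotation_deg: float = 25.0,
    scale_range: tuple[float, float] = (0.95, 1.05),
    max_translation_mm: float = 30.0,
) -> SimilarityTransform:
    """Draw a random similarity transform within the given ranges."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_rotation_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    scale = rng.uniform(*scale_range)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = rng.uniform(0.0, max_translation_mm) * direction
    return SimilarityTransform(scale, R, t)
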