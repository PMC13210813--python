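import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rowkit.geometry import CorrespondenceSet, Homography, estimate_homography
from rowkit.simulate import SceneConfig, generate_scene


@pytest.fixture
def noise_free_scene():
    """Default 5-row x 12-plant scene with no jitter, dropout, or outliers."""
    return generate_scene(SceneConfig(seed=42))


@pytest.fixture
def trapezoid_correspondence():
    """A perspective-like trapezoid-to-rectangle correspondence."""
    return CorrespondenceSet(
        src=np.array([[100, 400], [540, 400], [200, 100], [440, 100]], float),
        dst=np.array([[100, 400], [540, 400], [100, 0], [540, 0]], float),
    )


def random_quad_correspondence(rng, spread=400.0):
    """A random well-conditioned 4-point correspondence, or None if the
    perturbed corners happen to be degenerate."""
    base = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) * spread
    src = base + rng.uniform(-0.15 * spread, 0.15 * spread, (4, 2))
    dst = base + rng.uniform(-0.15 * spread, 0.15 * spread, (4, 2))
    try:
        corr = CorrespondenceSet(src=src, dst=dst)
        estimate_homography(corr)
    except ValueError:
        return None
    return corr
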