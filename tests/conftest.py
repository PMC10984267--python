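import numpy as np
import pytest

from panicount.boxes import DetectionSet, Frame, ScoredBox
from panicount.simulate import SceneParams, generate_field_scene


def random_boxes(rng: np.random.Generator, n: int, extent: float = 100.0,
                 max_size: float = 40.0) -> DetectionSet:
    """n random boxes with distinct-ish scores inside [0, extent)^2."""
    boxes = []
    for _ in range(n):
        x0 = rng.uniform(0, extent - 1)
        y0 = rng.uniform(0, extent - 1)
        w = rng.uniform(1, max_size)
        h = rng.uniform(1, max_size)
        boxes.append(
            ScoredBox(x0, y0, min(x0 + w, extent), min(y0 + h, extent),
                      rng.uniform(0, 1))
        )
    return DetectionSet(boxes=boxes, frame=Frame.PLOT)


@pytest.fixture(scope="session")
def small_scene():
    """One seeded scene shared by tests that only read it."""
    return generate_field_scene(42)


@pytest.fixture(scope="session")
def small_scene_params():
    return SceneParams()
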