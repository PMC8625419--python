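import numpy as np
import pytest

from myotype import texture_classifier as tc
from myotype.synthetic_tissue import generate_wellset


def axial_error(a: float, b: float) -> float:
    """Acute angular distance between two axes in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


@pytest.fixture(scope="session")
def trained_model():
    """Foreground classifier trained on a small mixed synthetic wellset."""
    scenes, _ = generate_wellset(6, 0.5, 5, base_seed=11, other_fraction=0.2)
    stacks = [tc.compute_texture_features(s["alpha_actinin"].pixels) for s in scenes]
    labels = [np.where(s["truth_class"].labels == 0, 0, 3) for s in scenes]
    ts = tc.subsample_balanced(stacks, labels, fraction=0.025, seed=1)
    return tc.train_pixel_classifier(ts, seed=1)
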