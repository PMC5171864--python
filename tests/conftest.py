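import numpy as np
import pytest

from finquant import SyntheticFinSpec, render_fin
from finquant.records import AmputationPlane


@pytest.fixture(scope="session")
def default_fin():
    """One rendered fin pair with ground truth (deterministic)."""
    return render_fin(SyntheticFinSpec(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_plane(rng, shape):
    """A random oblique amputation plane with valid distal side."""
    h, w = shape
    while True:
        p1 = (float(rng.uniform(0, h - 1)), float(rng.uniform(0, w - 1)))
        p2 = (float(rng.uniform(0, h - 1)), float(rng.uniform(0, w - 1)))
        if p1 == p2:
            continue
        d = np.array(p2) - np.array(p1)
        d = d / np.linalg.norm(d)
        for side, vec in (("up", (-1, 0)), ("down", (1, 0)),
                          ("left", (0, -1)), ("right", (0, 1))):
            n = np.array([-d[1], d[0]])
            if abs(np.dot(n, vec)) > 1e-6:
                return AmputationPlane(p1, p2, side)
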