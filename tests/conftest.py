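import numpy as np
import pytest

from sleepswitch.pipeline import score_recording
from sleepswitch.synth import SyntheticConfig, generate_recording


@pytest.fixture(scope="session")
def recording():
    """Default synthetic recording used across scoring tests."""
    return generate_recording(SyntheticConfig(seed=7), n_epochs=3000)


@pytest.fixture(scope="session")
def scored(recording):
    """Recording scored with boundaries fit on its first half."""
    return score_recording(
        recording.band_powers, recording.labels3, control_range=(0, 1500)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_intersections(pts, window=5):
    """All-pairs oracle: crossing non-adjacent segment pairs that fit in one
    epoch window. Independent of the production intersection finder."""
    out = set()
    n = len(pts)

    def x2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    for i in range(n - 1):
        for j in range(i + 2, n - 1):
            if j + 1 - i > window - 1:
                continue
            p, q = pts[i], pts[i + 1]
            r, s = pts[j], pts[j + 1]
            d1 = x2(q - p, r - p)
            d2 = x2(q - p, s - p)
            d3 = x2(s - r, p - r)
            d4 = x2(s - r, q - r)
            if (d1 > 0) != (d2 > 0) and (d3 > 0) != (d4 > 0) \
                    and d1 != d2 and d3 != d4:
                out.add((i, j))
    return out
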