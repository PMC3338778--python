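import numpy as np
import pytest

from motanlage.track_metrics import Track


@pytest.fixture
def straight_track() -> Track:
    """25 collinear points spaced 2.5 um along x, dt = 5 min."""
    xs = np.arange(25) * 2.5
    return Track("straight", np.column_stack([xs, np.zeros(25)]), dt_min=5.0)


@pytest.fixture
def stationary_track() -> Track:
    return Track("still", np.zeros((25, 2)), dt_min=5.0)


def make_track(points, dt_min=5.0, track_id="t") -> Track:
    return Track(track_id, np.asarray(points, dtype=float), dt_min=dt_min)


@pytest.fixture
def l_track() -> Track:
    """Right-angle path: 3 um along x then 4 um along y."""
    return make_track([(0, 0), (3, 0), (3, 4)])
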