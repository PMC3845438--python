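import numpy as np
import pytest

from vesselgrow import phantoms


@pytest.fixture(scope="session")
def tube30():
    """Noise-free tube at 30 degrees, radius 3, contrast 100."""
    return phantoms.make_tube_2d(65, 30, 3, 100, 0, 0)


@pytest.fixture(scope="session")
def tree_phantom():
    """Depth-3 tree, radius 3, mild noise."""
    return phantoms.make_tree_2d(128, 3, 3, 100, 5, 0)


@pytest.fixture(scope="session")
def y_phantom():
    """Noise-free Y: trunk at 90 deg splitting +-30 deg."""
    return phantoms.make_branch_2d(128, 90, 30, 3, 100, 0, 0)


def first_centerline_seed(ph):
    """Integer pixel at the start of the root centerline."""
    p = ph.centerline[0].points[0]
    return tuple(int(round(v)) for v in p)


def min_centerline_distance(ph, point):
    """Distance from a pixel to the nearest ground-truth centerline sample."""
    pt = np.asarray(point, dtype=float)
    return min(
        float(np.hypot(*(pt - p))) if len(pt) == 2
        else float(np.linalg.norm(pt - p))
        for branch in ph.centerline for p in branch.points
    )
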