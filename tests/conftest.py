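import numpy as np
import pytest

from retinamosaic import Window, PointPattern, Morphology


@pytest.fixture(scope="session")
def square_3mm() -> Window:
    return Window.rectangle(3000.0, 3000.0)


@pytest.fixture(scope="session")
def half_disc() -> Window:
    """Dorsal-hemisphere-like region, ~4.5 mm^2."""
    return Window.half_disc(1700.0)


@pytest.fixture
def collinear_pattern(square_3mm) -> PointPattern:
    """Three collinear points spaced 100 um, well inside a large window."""
    pts = np.array([[1000.0, 1500.0], [1100.0, 1500.0], [1200.0, 1500.0]])
    return PointPattern(pts, square_3mm)


def make_y_tree() -> Morphology:
    """Soma at origin, 150 um trunk along +x, two branches to radius 300 um."""
    ang = np.deg2rad(30.0)
    tip = 300.0 * np.array([np.cos(ang), np.sin(ang)])
    nodes = {
        "ids": [1, 2, 3, 4],
        "types": [1, 3, 3, 3],
        "xyz": [[0, 0, 0], [150, 0, 0], [tip[0], tip[1], 0], [tip[0], -tip[1], 0]],
        "radii": [6.0, 0.5, 0.5, 0.5],
        "parents": [-1, 1, 2, 2],
    }
    return Morphology(np.array(nodes["ids"]), np.array(nodes["types"]),
                      np.array(nodes["xyz"]), np.array(nodes["radii"]),
                      np.array(nodes["parents"]))


@pytest.fixture
def y_tree() -> Morphology:
    return make_y_tree()
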