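import numpy as np
import pytest

from gliamorph import synth
from gliamorph.imgprep import CellMask
from gliamorph.morpho import MorphometricExtractor


def draw_disc_mask(radius: int, pad: int = 14) -> np.ndarray:
    from skimage.draw import disk

    n = 2 * (radius + pad)
    m = np.zeros((n, n), dtype=bool)
    rr, cc = disk((n // 2, n // 2), radius)
    m[rr, cc] = True
    return m


def sierpinski_carpet(level: int) -> np.ndarray:
    m = np.ones((1, 1), dtype=bool)
    for _ in range(level):
        z = np.zeros_like(m)
        m = np.block([[m, m, m], [m, z, m], [m, m, m]])
    return m


@pytest.fixture(scope="session")
def cell_batch():
    """50 ramified + 50 amoeboid masks at default shape specs, with features."""
    rng = np.random.default_rng(20240917)
    masks, truth = [], []
    for cls in ("ramified", "amoeboid"):
        for _ in range(50):
            spec = synth.default_spec(cls, seed=int(rng.integers(2**31)))
            masks.append(CellMask(synth.make_cell_mask(spec), spec.pixel_size_um))
            truth.append(cls)
    features = MorphometricExtractor().fit_transform(masks)
    return masks, features, np.array(truth)
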