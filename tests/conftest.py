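import numpy as np
import pytest

from cortexratio import phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Clean 64-cube phantom with the default (small-brain) geometry."""
    return phantom.make_brain_phantom((64, 64, 64), n_rois=8)


@pytest.fixture(scope="session")
def standard_phantom():
    """Clean standard phantom (brain scaled to the FOV), 82 ROIs."""
    return phantom.standard_phantom()


@pytest.fixture(scope="session")
def sphere_shell():
    """Binary spherical-shell masks with known radii (a=15, b=22) on a 48-cube."""
    a, b = 15.0, 22.0
    shape = (48, 48, 48)
    c = tuple((n - 1) / 2.0 for n in shape)
    ax = [np.arange(n) - cc for n, cc in zip(shape, c)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    return {"wm": r < a, "gm": (r >= a) & (r < b), "r": r, "a": a, "b": b}


@pytest.fixture(scope="session")
def slab_masks():
    """Flat ribbon: 6 GM layers over 3 WM layers, open to CSF above."""
    gm = np.zeros((10, 10, 14), dtype=bool)
    wm = np.zeros_like(gm)
    gm[:, :, 4:10] = True
    wm[:, :, :4] = True
    return {"gm": gm, "wm": wm}
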