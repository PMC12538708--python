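import numpy as np
import pytest

import seedspread as sp


@pytest.fixture(scope="session")
def default_weights_48():
    """Queen weights on the standard 6 x 8 uniformity grid."""
    return sp.build_weights(6, 8, "queen")


@pytest.fixture(scope="session")
def rendered_scene():
    """A reduced-resolution rendered scene with its ground truth.

    120 Poisson-placed soybeans plus weeds on the default belt at
    2.5 px/mm (960 x 540 raster), shared by segmentation tests.
    """
    params = sp.ProcessParams(
        process="poisson",
        mix_counts={"soybean": 110, "a_trifida": 6, "a_artemisiifolia": 4},
    )
    layout = sp.sample_layout(params, seed=42, px_per_mm=2.5)
    image, mask, counts = sp.render_scene(layout)
    return image, mask, layout, counts


def brute_force_moran(x, w):
    """Independent O(N^2) double-loop evaluation of Moran's I."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    xbar = sum(x) / n
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += w[i, j]
    denom = sum((xi - xbar) ** 2 for xi in x)
    return n * num / (s0 * denom)
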