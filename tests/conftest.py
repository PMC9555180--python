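import numpy as np
import pytest

from rangefc import BoldSeries, BrainGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid():
    """~200 in-mask voxels on a 12 mm grid with both short and long pairs."""
    shape = (6, 10, 6)
    mask = np.zeros(shape, bool)
    mask[:, :, :] = True
    mask[0, 0, 0] = False  # keep the ordering non-trivial
    affine = np.diag([12.0, 12.0, 12.0, 1.0])
    affine[:3, 3] = -12.0 * (np.array(shape) - 1) / 2.0
    return BrainGrid(mask=mask, affine=affine)


@pytest.fixture
def small_series(rng, small_grid):
    data = rng.standard_normal((60, small_grid.voxel_count))
    return BoldSeries(data=data, tr_seconds=2.0, subject_id="fixture")


def naive_fc_strength(series, grid, threshold_mm=75.0):
    """Brute-force all-pairs oracle for the FC-strength maps (O(V^2 T))."""
    X = series.data
    V = X.shape[1]
    spfc = np.zeros(V)
    lpfc = np.zeros(V)
    snfc = np.zeros(V)
    lnfc = np.zeros(V)
    coords = grid.coords_mm
    for i in range(V):
        for j in range(V):
            if i == j:
                continue
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
            d = np.linalg.norm(coords[i] - coords[j])
            if z > 0:
                if d < threshold_mm:
                    spfc[i] += z
                else:
                    lpfc[i] += z
            elif z < 0:
                if d < threshold_mm:
                    snfc[i] += z
                else:
                    lnfc[i] += z
    return spfc, lpfc, snfc, lnfc
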