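import numpy as np
import pytest

from safconn.streamlines import Bundle, DensityMap, GridSpec


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(voxel_size=1.0, origin=(0.0, 0.0, 0.0), shape=(8, 8, 8))


@pytest.fixture
def map_builder(small_grid):
    """Build a DensityMap on the small grid from {(i,j,k): count} dicts."""

    def build(counts_by_voxel, grid=None):
        grid = grid or small_grid
        counts = np.zeros(grid.shape, dtype=np.int32)
        for (i, j, k), c in counts_by_voxel.items():
            counts[i, j, k] = c
        return DensityMap(grid=grid, counts=counts)

    return build


@pytest.fixture
def u_arc_bundle():
    """A smooth synthetic U-shaped bundle of near-identical arcs."""

    def build(n_streamlines=20, jitter=0.0, shift=(0.0, 0.0, 0.0), seed=7):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, np.pi, 24)
        streamlines = []
        for _ in range(n_streamlines):
            base = np.stack(
                [10 + 20 * t / np.pi, 15 + 10 * np.sin(t), np.full_like(t, 12.0)],
                axis=1,
            )
            if jitter:
                base = base + rng.normal(scale=jitter, size=base.shape)
            streamlines.append(base + np.asarray(shift))
        return Bundle(streamlines=streamlines)

    return build
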