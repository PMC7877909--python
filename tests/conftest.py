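import numpy as np
import pytest

from mbonmap import synthetic as syn


@pytest.fixture(scope="session")
def atlas34():
    """Shared 34-region atlas on a 48^3 grid (seeded, deterministic)."""
    return syn.generate_atlas((48, 48, 48), n_regions=34, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def neighbor_offsets(connectivity: int):
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    return offsets


def chebyshev_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force Chebyshev-ball dilation, independent of scipy."""
    if radius == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    shape = mask.shape
    for v in np.argwhere(mask):
        z0, y0, x0 = v
        out[max(0, z0 - radius):min(shape[0], z0 + radius + 1),
            max(0, y0 - radius):min(shape[1], y0 + radius + 1),
            max(0, x0 - radius):min(shape[2], x0 + radius + 1)] = True
    return out


def flood_fill(mask: np.ndarray, seed_region: np.ndarray,
               connectivity: int = 26) -> np.ndarray:
    """Independent breadth-first flood-fill oracle.

    Starts from every true voxel of ``mask`` inside ``seed_region`` and
    spreads through ``mask`` under the given connectivity; the result is the
    union of mask components that intersect the seed region.
    """
    offsets = neighbor_offsets(connectivity)
    shape = mask.shape
    visited = np.zeros(shape, dtype=bool)
    frontier = [tuple(v) for v in np.argwhere(mask & seed_region)]
    for tv in frontier:
        visited[tv] = True
    while frontier:
        cur = frontier.pop()
        for off in offsets:
            nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
            if (all(0 <= nb[i] < shape[i] for i in range(3))
                    and mask[nb] and not visited[nb]):
                visited[nb] = True
                frontier.append(nb)
    return visited
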