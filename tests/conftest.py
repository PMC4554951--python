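import numpy as np
import pytest

from pomoct import FruitSpec, ParenchymaSpec, make_fruit, make_parenchyma


@pytest.fixture(scope="session")
def small_parenchyma():
    """A small, fast parenchyma phantom shared by read-only tests."""
    spec = ParenchymaSpec(shape=(64, 64, 64), n_cells=120, target_porosity=0.25, seed=5)
    volume, voids, truth = make_parenchyma(spec)
    return spec, volume, voids, truth


@pytest.fixture(scope="session")
def small_fruit():
    """A small whole-fruit phantom (coarser voxels) for vasculature tests."""
    spec = FruitSpec(shape=(96, 96, 96), voxel_size_mm=0.26, fruit_radius_mm=11.0,
                     core_radius_mm=6.0, core_air_radius_mm=2.0,
                     region_dilate_vox=5, region_erode_vox=4, seed=3)
    volume, truth = make_fruit(spec)
    return spec, volume, truth


def flood_fill_count(mask: np.ndarray) -> int:
    """Independent 26-connected component count by explicit flood fill."""
    mask = np.asarray(mask, bool)
    visited = np.zeros_like(mask)
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                q = (z + dz, y + dy, x + dx)
                if (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1]
                        and 0 <= q[2] < mask.shape[2] and mask[q] and not visited[q]):
                    visited[q] = True
                    stack.append(q)
    return count


def brute_force_faces(mask: np.ndarray) -> int:
    """Independent exposed-face count by per-voxel neighbour inspection."""
    mask = np.asarray(mask, bool)
    faces = 0
    for z, y, x in zip(*np.nonzero(mask)):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = (z + dz, y + dy, x + dx)
            if not (0 <= q[0] < mask.shape[0] and 0 <= q[1] < mask.shape[1]
                    and 0 <= q[2] < mask.shape[2]) or not mask[q]:
                faces += 1
    return faces
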