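import numpy as np
import pytest

from heq.core import FULL_GRID, quantify_slice
from heq.phantoms import CohortSpec, PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def simple_phantom():
    """Noise-free phantom: 3 disk lesions + 1 annulus (b0=4, b1=1)."""
    return make_phantom(PhantomSpec(lesion_count=3, ring_count=1, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy cohort for CV tests: 8 patients x 2 slices."""
    return make_cohort(
        CohortSpec(n_patients=8, slices_per_patient=2, seed=3),
        PhantomSpec(image_size=128, lesion_radius_px=3, noise_sd=25.0),
    )


@pytest.fixture(scope="session")
def small_cohort_curves(small_cohort):
    return [
        quantify_slice(s.ct, s.mask, FULL_GRID) for s in small_cohort.slices
    ]


def flood_fill_betti(grid):
    """Independent Betti-number oracle: BFS flood fill over all cells.

    Foreground components use 8-neighbourhoods; background components use
    4-neighbourhoods and count as holes iff they contain no border cell.
    """
    grid = np.asarray(grid, dtype=bool)
    h, w = grid.shape
    seen = np.zeros_like(grid, dtype=bool)

    def bfs(sy, sx, value, neigh):
        stack = [(sy, sx)]
        seen[sy, sx] = True
        cells = []
        while stack:
            y, x = stack.pop()
            cells.append((y, x))
            for dy, dx in neigh:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and not seen[ny, nx] \
                        and grid[ny, nx] == value:
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        return cells

    n8 = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
          if (dy, dx) != (0, 0)]
    n4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    b0 = 0
    for y in range(h):
        for x in range(w):
            if grid[y, x] and not seen[y, x]:
                b0 += 1
                bfs(y, x, True, n8)
    b1 = 0
    for y in range(h):
        for x in range(w):
            if not grid[y, x] and not seen[y, x]:
                cells = bfs(y, x, False, n4)
                if not any(
                    cy in (0, h - 1) or cx in (0, w - 1) for cy, cx in cells
                ):
                    b1 += 1
    return b0, b1
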