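"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the library routines they validate: components
are found by breadth-first flood fill over explicit neighbor offsets,
sums and medians by direct enumeration.
"""

from __future__ import annotations

from collections import deque

import numpy as np

OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
OFFSETS_8 = OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_components(grid: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected true-pixel components of a binary grid by BFS."""
    offsets = OFFSETS_4 if connectivity == 4 else OFFSETS_8
    grid = np.asarray(grid, dtype=bool)
    h, w = grid.shape
    seen = np.zeros_like(grid)
    components = []
    for r0 in range(h):
        for c0 in range(w):
            if not grid[r0, c0] or seen[r0, c0]:
                continue
            comp = []
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.append((r, c))
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and grid[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            components.append(frozenset(comp))
    return components


def component_signature(pixels: frozenset, intensity: np.ndarray | None = None):
    """Hashable exact summary of a component: (size, sum of rows, sum of
    cols[, intensity sum]) — centroid times size, so no float compare."""
    size = len(pixels)
    rsum = sum(p[0] for p in pixels)
    csum = sum(p[1] for p in pixels)
    if intensity is None:
        return (size, rsum, csum)
    isum = int(sum(int(intensity[p]) for p in pixels))
    return (size, rsum, csum, isum)


def neighborhood_median(image: np.ndarray, mask: np.ndarray, r: int, c: int, window: int) -> float:
    """Median of the window around (r, c) over within-mask, in-bounds pixels."""
    half = window // 2
    h, w = image.shape
    vals = [
        float(image[rr, cc])
        for rr in range(r - half, r + half + 1)
        for cc in range(c - half, c + half + 1)
        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]
    ]
    return float(np.median(vals))
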