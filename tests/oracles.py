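"""Independent brute-force oracles used to cross-check the implementation.

Deliberately simple and slow: breadth-first flood fill over an explicit
neighbour-offset list, no shared code with the package's labelling path.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append(d)
    return offsets


def flood_fill_count(
    values: np.ndarray,
    voi_mask: np.ndarray,
    threshold: float,
    connectivity: int = 26,
    min_size: int = 1,
) -> int:
    """Count connected above-threshold VOI regions by BFS flood fill."""
    foreground = voi_mask & (values >= threshold)
    seen = np.zeros_like(foreground, dtype=bool)
    offsets = neighbour_offsets(connectivity)
    shape = foreground.shape
    count = 0
    for index in np.argwhere(foreground):
        start = tuple(index)
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    if foreground[nx, ny, nz] and not seen[nx, ny, nz]:
                        seen[nx, ny, nz] = True
                        queue.append((nx, ny, nz))
        if size >= min_size:
            count += 1
    return count
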