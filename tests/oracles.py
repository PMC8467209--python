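"""Independent brute-force oracles for the landscape-pattern metrics.

Deliberately naive: explicit flood fill and direct double sums, sharing no
code with the package implementation.
"""

from collections import deque

import numpy as np


def flood_patches(values: np.ndarray, mask: np.ndarray, connectivity: int):
    """List of (category, area) patches by breadth-first flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    h, w = values.shape
    seen = np.zeros((h, w), dtype=bool)
    patches = []
    for r0 in range(h):
        for c0 in range(w):
            if seen[r0, c0] or not mask[r0, c0]:
                continue
            cat = values[r0, c0]
            area = 0
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                area += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < h
                        and 0 <= cc < w
                        and not seen[rr, cc]
                        and mask[rr, cc]
                        and values[rr, cc] == cat
                    ):
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            patches.append((int(cat), area))
    return patches


def oracle_pland(values: np.ndarray, mask: np.ndarray) -> dict:
    total = int(mask.sum())
    out = {}
    for v in np.unique(values[mask]):
        out[int(v)] = 100.0 * int(((values == v) & mask).sum()) / total
    return out


def oracle_division(values: np.ndarray, mask: np.ndarray, connectivity: int) -> float:
    patches = flood_patches(values, mask, connectivity)
    total = sum(a for _, a in patches)
    return 1.0 - sum((a / total) ** 2 for _, a in patches)


def oracle_shdi(values: np.ndarray, mask: np.ndarray) -> float:
    total = int(mask.sum())
    acc = 0.0
    for v in np.unique(values[mask]):
        p = int(((values == v) & mask).sum()) / total
        acc -= p * np.log(p)
    return acc
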