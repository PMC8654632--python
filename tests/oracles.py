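"""Independent brute-force oracles used only by the tests.

These are deliberately naive re-derivations — breadth-first search for
connected components, explicit loops for moments — kept separate from the
library so they can disagree with it.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_components(data: np.ndarray, max_hops: int = 3) -> list[frozenset[tuple[int, int, int]]]:
    """Connected components of a binary volume by breadth-first search.

    Two foreground voxels are neighbours iff each index differs by at most
    one and at most ``max_hops`` indices differ.  Returns the partition as
    a list of frozensets of index triples (order irrelevant).
    """
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
        and abs(di) + abs(dj) + abs(dk) <= max_hops
    ]
    foreground = {tuple(v) for v in np.argwhere(data > 0)}
    seen: set[tuple[int, int, int]] = set()
    components = []
    for start in sorted(foreground):
        if start in seen:
            continue
        queue = deque([start])
        seen.add(start)
        comp = {start}
        while queue:
            i, j, k = queue.popleft()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in foreground and nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        components.append(frozenset(comp))
    return components


def fractional_anisotropy(u1: float, u2: float, u3: float) -> float:
    """FA of three eigenvalues, written out term by term."""
    mean = (u1 + u2 + u3) / 3.0
    num = (u1 - mean) ** 2 + (u2 - mean) ** 2 + (u3 - mean) ** 2
    den = u1 * u1 + u2 * u2 + u3 * u3
    if den == 0.0:
        return math.nan
    return math.sqrt(1.5 * num / den)


def brute_force_covariance(points: np.ndarray) -> np.ndarray:
    """Population covariance as an explicit double loop over coordinates."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    mean = [sum(p[d] for p in points) / n for d in range(3)]
    cov = np.zeros((3, 3))
    for p in points:
        for a in range(3):
            for b in range(3):
                cov[a, b] += (p[a] - mean[a]) * (p[b] - mean[b])
    return cov / n
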