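"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package: Moran's I is
evaluated with an explicit double loop over cube pairs, and density
clustering with a literal mark-then-flood-fill over the 3D array.
"""

from collections import deque

import numpy as np

FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def moran_brute_force(counts, mask=None, cube_size=1.0):
    """Moran's I by an O(n²) double loop over in-mask cube centroids.

    Weights are 1 when centroid distance ≤ cube_size (excluding i == j),
    0 otherwise.
    """
    counts = np.asarray(counts, dtype=float)
    if mask is None:
        mask = np.ones(counts.shape, dtype=bool)
    coords = np.argwhere(mask) * cube_size
    a = counts[mask]
    n = len(a)
    abar = a.mean()
    num = 0.0
    w = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = np.linalg.norm(coords[i] - coords[j])
            if d <= cube_size + 1e-9:
                num += (a[i] - abar) * (a[j] - abar)
                w += 1
    denom = ((a - abar) ** 2).sum() * w
    return n * num / denom


def mark_and_flood_fill(counts, quantile=0.75, mask=None):
    """Independent density clustering: neighborhood-mean marking + BFS flood fill.

    Returns (threshold, marked bool array, list of frozensets of cube index
    tuples — one set per contiguous cluster).
    """
    counts = np.asarray(counts, dtype=float)
    dims = counts.shape
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    threshold = float(np.quantile(counts[mask], quantile))

    def neighbors(ixyz):
        for off in FACE_OFFSETS:
            j = tuple(np.add(ixyz, off))
            if all(0 <= j[k] < dims[k] for k in range(3)) and mask[j]:
                yield j

    marked = np.zeros(dims, dtype=bool)
    for idx in map(tuple, np.argwhere(mask)):
        hood = [idx] + list(neighbors(idx))
        if np.mean([counts[h] for h in hood]) > threshold:
            for h in hood:
                marked[h] = True

    seen = np.zeros(dims, dtype=bool)
    clusters = []
    for idx in map(tuple, np.argwhere(marked)):
        if seen[idx]:
            continue
        comp = set()
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for nb in neighbors(cur):
                if marked[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        clusters.append(frozenset(comp))
    return threshold, marked, clusters
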