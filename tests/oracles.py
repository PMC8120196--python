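"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np


def brute_longest_common_substring(s1: str, s2: str) -> int:
    """O(n^2 * m) enumeration over all substring start pairs."""
    best = 0
    for i in range(len(s1)):
        for j in range(len(s2)):
            k = 0
            while (
                i + k < len(s1)
                and j + k < len(s2)
                and s1[i + k] == s2[j + k]
                and s1[i + k] in "ACGT"
            ):
                k += 1
            best = max(best, k)
    return best


def brute_dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Textbook DBSCAN: quadratic neighbour search + BFS over core points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 1)
    n = len(pts)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    neighbours = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbours])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            q = queue.pop()
            if not core[q]:
                continue
            for nb in neighbours[q]:
                if labels[nb] == -1:
                    labels[nb] = cluster
                    if core[nb]:
                        queue.append(nb)
        cluster += 1
    return labels


def canonical_partition(labels) -> list[frozenset]:
    """Order-free view of a clustering: the set of clusters as index sets."""
    groups: dict[int, set[int]] = {}
    for idx, lab in enumerate(labels):
        if lab != -1:
            groups.setdefault(int(lab), set()).add(idx)
    return sorted((frozenset(g) for g in groups.values()), key=min)
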