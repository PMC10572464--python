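"""Independent brute-force oracles used to validate the package.

The TFCE oracle re-derives the enhancement definition with explicit loops
and repeated flood-fill component labeling at every height level, sharing no
code with the implementation under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def _flood_fill_image(mask: np.ndarray) -> np.ndarray:
    """4-connectivity component labels of a 2-D boolean image (BFS)."""
    n, m = mask.shape
    labels = np.zeros((n, m), dtype=int)
    current = 0
    for si in range(n):
        for sj in range(m):
            if not mask[si, sj] or labels[si, sj]:
                continue
            current += 1
            queue = deque([(si, sj)])
            labels[si, sj] = current
            while queue:
                i, j = queue.popleft()
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < m and mask[a, b] and not labels[a, b]:
                        labels[a, b] = current
                        queue.append((a, b))
    return labels


def _flood_fill_edges(edges: list[tuple[int, int]]) -> list[set[int]]:
    """Components of edges where two edges are adjacent iff they share an ROI."""
    unvisited = set(range(len(edges)))
    comps = []
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            e = queue.popleft()
            for other in list(unvisited):
                if set(edges[e]) & set(edges[other]):
                    unvisited.discard(other)
                    comp.add(other)
                    queue.append(other)
        comps.append(comp)
    return comps


def tfce_bruteforce(
    stat: np.ndarray,
    roi_order: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    h0: float = 0.0,
    two_sided: bool = True,
    neighborhood: str = "matrix_image_4",
) -> np.ndarray:
    """Literal midpoint-rule TFCE with per-level flood fill."""
    stat = np.asarray(stat, dtype=float)
    n = stat.shape[0]
    order = np.asarray(roi_order)
    inv = np.empty_like(order)
    inv[order] = np.arange(n)
    sorted_stat = stat[np.ix_(order, order)]

    def one_tail(mat: np.ndarray) -> np.ndarray:
        out = np.zeros_like(mat)
        hmax = mat.max()
        if hmax <= h0:
            return out
        dh = (hmax - h0) / n_steps
        for k in range(n_steps):
            h = h0 + (k + 0.5) * dh
            mask = mat > h
            if neighborhood == "matrix_image_4":
                labels = _flood_fill_image(mask)
                for i in range(n):
                    for j in range(n):
                        if mask[i, j]:
                            extent = int(np.sum(labels == labels[i, j]))
                            out[i, j] += extent**E * h**H * dh
            else:
                edges = [
                    (i, j) for i in range(n) for j in range(i + 1, n) if mask[i, j]
                ]
                comps = _flood_fill_edges(edges)
                for comp in comps:
                    extent = len(comp)
                    for e in comp:
                        i, j = edges[e]
                        out[i, j] += extent**E * h**H * dh
        if neighborhood != "matrix_image_4":
            out = out + out.T
        return out

    result = one_tail(np.maximum(sorted_stat, 0.0))
    if two_sided:
        result = result - one_tail(np.maximum(-sorted_stat, 0.0))
    return result[np.ix_(inv, inv)]
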