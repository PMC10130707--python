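"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: full simplicial
enumeration, dense column reduction without optimizations, grid-based
landscape evaluation, exhaustive matching enumeration for Wasserstein.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_rips_h1(points: np.ndarray, max_scale: float | None = None):
    """Full boundary-matrix reduction over all simplices up to dim 2.

    Returns a sorted list of (birth, death) H1 pairs with birth < death.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dm = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    if max_scale is None:
        max_scale = dm.max(axis=1).min() if n > 1 else 0.0

    simplices = [((v,), 0.0) for v in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if dm[i, j] <= max_scale + 1e-12:
            simplices.append(((i, j), dm[i, j]))
    for i, j, k in itertools.combinations(range(n), 3):
        d = max(dm[i, j], dm[i, k], dm[j, k])
        if d <= max_scale + 1e-12:
            simplices.append(((i, j, k), d))
    # (diameter, dimension, lexicographic vertices) filtration order
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s[0]: i for i, s in enumerate(simplices)}

    columns = []
    for verts, _ in simplices:
        if len(verts) == 1:
            columns.append(set())
        else:
            faces = itertools.combinations(verts, len(verts) - 1)
            columns.append({index[f] for f in faces})

    low_to_col: dict[int, int] = {}
    pairs = []
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = max(col)
            other = low_to_col.get(low)
            if other is None:
                break
            col ^= columns[other]
        if col:
            low = max(col)
            low_to_col[low] = j
            if len(simplices[j][0]) == 3:  # triangle kills an edge-born class
                birth = simplices[low][1]
                death = simplices[j][1]
                if death - birth > 1e-12:
                    pairs.append((birth, death))
    return sorted(pairs)


def landscape_layer_on_grid(pairs: np.ndarray, k: int, grid: np.ndarray
                            ) -> np.ndarray:
    """k-th largest tent value (1-based k) at each grid abscissa."""
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if not len(pairs):
        return np.zeros(len(grid))
    vals = np.minimum(grid[:, None] - pairs[None, :, 0],
                      pairs[None, :, 1] - grid[:, None])
    vals = np.maximum(vals, 0.0)
    vals.sort(axis=1)
    if k > vals.shape[1]:
        return np.zeros(len(grid))
    return vals[:, -k]


def wasserstein_by_enumeration(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum cost over all partial matchings (L-inf ground metric)."""
    p = np.asarray(p, dtype=float).reshape(-1, 2)
    q = np.asarray(q, dtype=float).reshape(-1, 2)
    n, m = len(p), len(q)
    diag_p = (p[:, 1] - p[:, 0]) / 2
    diag_q = (q[:, 1] - q[:, 0]) / 2
    best = np.inf
    # choose an injection from a subset of p into q; the rest go diagonal
    for r in range(0, min(n, m) + 1):
        for subset_p in itertools.combinations(range(n), r):
            for subset_q in itertools.permutations(range(m), r):
                cost = 0.0
                for i, j in zip(subset_p, subset_q):
                    cost += max(abs(p[i, 0] - q[j, 0]), abs(p[i, 1] - q[j, 1]))
                cost += diag_p.sum() - diag_p[list(subset_p)].sum() \
                    if n else 0.0
                cost += diag_q.sum() - diag_q[list(subset_q)].sum() \
                    if m else 0.0
                best = min(best, cost)
    return float(best)
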