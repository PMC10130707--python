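"""Two-dimensional Isomap from a precomputed dissimilarity matrix.

Builds the symmetric k-nearest-neighbour graph weighted by the input
dissimilarities, computes geodesic distances by all-pairs shortest paths,
and applies classical multidimensional scaling to the geodesic matrix.
The sign/rotation ambiguity of MDS is removed by a fixed canonicalization
so embeddings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

DEFAULT_N_NEIGHBORS = 5


@dataclass(frozen=True)
class Embedding2D:
    ids: tuple
    coordinates: np.ndarray  # (n, 2)
    n_neighbors: int
    residual_variance: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "ids", tuple(self.ids))
        if coords.shape != (len(self.ids), 2):
            raise ValueError("coordinates must be one 2-vector per id")
        if not np.all(np.isfinite(coords)):
            raise ValueError("embedding coordinates must be finite")

    def to_frame(self, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"id": list(self.ids),
                           "x": self.coordinates[:, 0],
                           "y": self.coordinates[:, 1]})
        if metadata is not None:
            df = df.merge(metadata, how="left", on="id")
        return df

    def to_csv(self, path, metadata: pd.DataFrame | None = None) -> None:
        self.to_frame(metadata).to_csv(path, index=False)


def _knn_graph(values: np.ndarray, k: int) -> csr_matrix:
    n = len(values)
    rows, cols, data = [], [], []
    for i in range(n):
        order = np.argsort(values[i], kind="stable")  # ties: stable id order
        nbrs = [j for j in order if j != i][:k]
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            data.append(values[i, j])
    g = csr_matrix((data, (rows, cols)), shape=(n, n))
    return g.maximum(g.T)  # symmetrize: union of neighbourhoods


def _smallest_connecting_k(values: np.ndarray, k_start: int) -> int:
    n = len(values)
    for k in range(k_start, n):
        n_comp, _ = connected_components(_knn_graph(values, k), directed=False)
        if n_comp == 1:
            return k
    return n - 1


def isomap_2d(distances, n_neighbors: int = DEFAULT_N_NEIGHBORS) -> Embedding2D:
    """2-D Isomap of a dissimilarity matrix.

    Raises if the k-NN graph is disconnected, reporting the components and
    the smallest ``n_neighbors`` that would connect them.
    """
    values = np.asarray(getattr(distances, "values", distances), dtype=float)
    ids = tuple(getattr(distances, "ids", range(len(values))))
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 items to embed")
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")

    graph = _knn_graph(values, n_neighbors)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        comps = [sorted(np.nonzero(labels == c)[0].tolist())
                 for c in range(n_comp)]
        k_min = _smallest_connecting_k(values, n_neighbors + 1)
        raise ValueError(
            f"k-NN graph with n_neighbors={n_neighbors} is disconnected "
            f"(components by index: {comps}); smallest connecting "
            f"n_neighbors is {k_min}"
        )

    geo = shortest_path(graph, method="D", directed=False)

    # classical MDS on the geodesic matrix
    d2 = geo ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    top = np.argsort(eigvals)[::-1][:2]
    lam = np.clip(eigvals[top], 0.0, None)
    coords = eigvecs[:, top] * np.sqrt(lam)[None, :]

    # canonical orientation: non-negative skewness on axis 1, then the first
    # point gets a non-negative second coordinate
    for axis in range(2):
        c = coords[:, axis] - coords[:, axis].mean()
        skew = np.sum(c ** 3)
        flip = skew < -1e-12 if axis == 0 else coords[0, 1] < -1e-12
        if axis == 0 and abs(skew) <= 1e-12:
            flip = False
        if flip:
            coords[:, axis] = -coords[:, axis]

    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    gvec, evec = geo[iu], emb_d[iu]
    denom = np.std(gvec) * np.std(evec)
    if denom > 1e-15:
        r = np.corrcoef(gvec, evec)[0, 1]
        residual = float(max(0.0, 1.0 - r ** 2))
    else:
        residual = 0.0
    return Embedding2D(ids=ids, coordinates=coords, n_neighbors=n_neighbors,
                       residual_variance=residual)
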