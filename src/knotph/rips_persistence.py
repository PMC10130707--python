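"""Degree-1 Vietoris-Rips persistent homology over Z/2.

The filtration is the standard Rips filtration: vertices enter at scale 0,
an edge at its length, a triangle at its longest edge.  Persistence pairs
are obtained by column reduction of the triangle boundary matrix over the
edges; only edge-triangle (degree-1) pairs are kept and zero-persistence
pairs are discarded.  The reduced column of a death triangle is itself a
mod-2 cycle whose longest edge is the birth edge, and is returned verbatim
as the representative cycle of its pair.

Simplices are ordered by (diameter, dimension, lexicographic vertex tuple)
so that pairings are deterministic under distance ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

_TOL = 1e-12


def _as_points(points) -> np.ndarray:
    if hasattr(points, "points"):
        points = points.points
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return pts


def enclosing_radius(points) -> float:
    """min over points p of the max distance from p to any other point.

    The Rips complex at this scale is a cone over the minimising point, so
    every degree-1 class has died by then.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValueError("enclosing radius of an empty cloud is undefined")
    if len(pts) == 1:
        return 0.0
    dm = squareform(pdist(pts))
    return float(dm.max(axis=1).min())


@dataclass(frozen=True)
class PersistenceDiagram:
    """Finite multiset of (birth, death) pairs in one homology degree (Å)."""

    pairs: np.ndarray  # shape (k, 2)
    max_scale: float
    censored: np.ndarray = field(default=None)  # bool flags, death right-censored
    degree: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "pairs", pairs)
        cens = self.censored
        if cens is None:
            cens = np.zeros(len(pairs), dtype=bool)
        cens = np.asarray(cens, dtype=bool)
        object.__setattr__(self, "censored", cens)
        if len(cens) != len(pairs):
            raise ValueError("censored flags must match pair count")
        if len(pairs):
            if np.any(pairs[:, 0] < -_TOL) or np.any(pairs[:, 1] <= pairs[:, 0]):
                raise ValueError("diagram pairs must satisfy 0 <= birth < death")
            if np.any(pairs[:, 1] > self.max_scale + 1e-9):
                raise ValueError("deaths must not exceed max_scale")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def persistences(self) -> np.ndarray:
        return self.pairs[:, 1] - self.pairs[:, 0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"birth": self.pairs[:, 0], "death": self.pairs[:, 1],
             "censored": self.censored}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, max_scale: Optional[float] = None,
                 source_id: str = "") -> "PersistenceDiagram":
        df = pd.read_csv(path)
        pairs = df[["birth", "death"]].to_numpy(float)
        cens = df["censored"].to_numpy(bool) if "censored" in df else None
        if max_scale is None:
            max_scale = float(pairs[:, 1].max()) if len(pairs) else 0.0
        return cls(pairs=pairs, max_scale=max_scale, censored=cens,
                   source_id=source_id)


@dataclass(frozen=True)
class CycleRepresentative:
    """Mod-2 edge cycle representing one diagram point.

    Every vertex of ``edges`` has even degree and the longest edge has
    length equal to the birth scale of the pair.
    """

    pair: tuple[float, float]
    edges: frozenset  # frozenset of (i, j) point-index tuples, i < j

    @property
    def vertices(self) -> np.ndarray:
        return np.unique(np.array(sorted(self.edges)).ravel())

    def to_json(self, cloud=None) -> str:
        payload = {
            "pair": list(self.pair),
            "edges": sorted(map(list, self.edges)),
        }
        if cloud is not None:
            payload["segment_ranges"] = resolved_segment_ranges(self, cloud)
        return json.dumps(payload, indent=2)


def resolved_segment_ranges(cycle: CycleRepresentative, cloud) -> list[list[int]]:
    """Collapse the cycle's vertices to contiguous source-segment ranges."""
    segs = np.sort(np.unique(cloud.segment_index[cycle.vertices]))
    ranges: list[list[int]] = []
    for s in segs:
        if ranges and s == ranges[-1][1] + 1:
            ranges[-1][1] = int(s)
        else:
            ranges.append([int(s), int(s)])
    return ranges


class _Reduction:
    """One full H1 reduction of a cloud; holds columns for cycle extraction."""

    def __init__(self, points, max_scale: Optional[float] = None):
        pts = _as_points(points)
        self.points = pts
        n = len(pts)
        if max_scale is None:
            max_scale = enclosing_radius(pts) if n else 0.0
        self.max_scale = float(max_scale)
        self.pairs: list[tuple[float, float]] = []
        self.censored_flags: list[bool] = []
        self._pair_slot: list[int] = []
        self._columns: list[int] = []  # bitset columns over edge ranks
        self._edge_verts: np.ndarray = np.empty((0, 2), dtype=np.int32)
        self._edge_lengths: np.ndarray = np.empty(0)
        if n < 3:
            return
        self._run(pts, n)

    def _run(self, pts: np.ndarray, n: int) -> None:
        ms = self.max_scale
        dm = squareform(pdist(pts))

        iu, ju = np.triu_indices(n, 1)
        lengths = dm[iu, ju]
        keep = lengths <= ms + _TOL
        iu, ju, lengths = iu[keep], ju[keep], lengths[keep]
        order = np.lexsort((ju, iu, lengths))
        iu, ju, lengths = iu[order], ju[order], lengths[order]
        self._edge_verts = np.stack([iu, ju], axis=1).astype(np.int32)
        self._edge_lengths = lengths

        rank = np.full((n, n), -1, dtype=np.int64)
        rank[iu, ju] = np.arange(len(iu))
        rank[ju, iu] = rank[iu, ju]

        # enumerate triangles with diameter <= max_scale
        tri_e = []  # per-triangle edge ranks (3 columns)
        tri_diam = []
        tri_v = []
        adj = dm <= ms + _TOL
        for i in range(n - 2):
            nbrs = np.nonzero(adj[i, i + 1:])[0] + i + 1
            if len(nbrs) < 2:
                continue
            sub = adj[np.ix_(nbrs, nbrs)]
            jj, kk = np.nonzero(np.triu(sub, 1))
            if not len(jj):
                continue
            vj, vk = nbrs[jj], nbrs[kk]
            d = np.maximum(dm[i, vj], np.maximum(dm[i, vk], dm[vj, vk]))
            tri_diam.append(d)
            tri_e.append(np.stack([rank[i, vj], rank[i, vk], rank[vj, vk]], axis=1))
            tri_v.append(np.stack([np.full(len(vj), i), vj, vk], axis=1))
        if tri_e:
            e3 = np.concatenate(tri_e)
            diam = np.concatenate(tri_diam)
            verts = np.concatenate(tri_v)
            order = np.lexsort((verts[:, 2], verts[:, 1], verts[:, 0], diam))
            e3, diam = e3[order], diam[order]
        else:
            e3 = np.empty((0, 3), dtype=np.int64)
            diam = np.empty(0)

        pivot_of: dict[int, int] = {}  # edge rank -> column slot
        columns = self._columns
        lengths_ = self._edge_lengths
        pairs = self.pairs
        e3_rows = e3.tolist()
        piv_row = e3.max(axis=1).tolist() if len(e3) else []
        diam_row = diam.tolist()
        get_slot = pivot_of.get

        # columns are bitsets over edge ranks: XOR and bit_length make the
        # standard reduction cheap even when columns grow long
        for t, piv in enumerate(piv_row):
            a, b, c = e3_rows[t]
            col = (1 << a) | (1 << b) | (1 << c)
            slot = get_slot(piv)
            if slot is None:
                # apparent pair: the longest edge of this triangle is still
                # unpaired; birth == death so no diagram point is recorded
                pivot_of[piv] = len(columns)
                columns.append(col)
                continue
            while slot is not None:
                col ^= columns[slot]
                if not col:
                    break
                piv = col.bit_length() - 1
                slot = get_slot(piv)
            if col:
                pivot_of[piv] = len(columns)
                columns.append(col)
                birth = lengths_[piv]
                death = diam_row[t]
                if death - birth > _TOL:
                    pairs.append((float(birth), float(death)))
                    self.censored_flags.append(False)
                    self._pair_slot.append(len(columns) - 1)

        # unpaired cycle-creating edges are censored at max_scale
        paired = set(pivot_of)
        parent = np.arange(n)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in range(len(iu)):
            a, b = find(int(iu[e])), find(int(ju[e]))
            if a == b:
                if e not in paired and ms - lengths_[e] > _TOL:
                    pairs.append((float(lengths_[e]), ms))
                    self.censored_flags.append(True)
                    self._pair_slot.append(-1)
            else:
                parent[a] = b

    @property
    def diagram(self) -> PersistenceDiagram:
        pairs = np.array(self.pairs, dtype=float).reshape(-1, 2)
        cens = np.array(self.censored_flags, dtype=bool)
        if len(pairs):
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs, cens = pairs[order], cens[order]
        return PersistenceDiagram(pairs=pairs, max_scale=self.max_scale,
                                  censored=cens)

    def cycle(self, pair, tol: float = 1e-9) -> CycleRepresentative:
        birth, death = float(pair[0]), float(pair[1])
        for (b, d), slot, cens in zip(self.pairs, self._pair_slot,
                                      self.censored_flags):
            if abs(b - birth) <= tol and abs(d - death) <= tol:
                if cens or slot < 0:
                    raise ValueError(
                        "no representative available for a censored pair; "
                        "recompute with max_scale = enclosing_radius"
                    )
                col = self._columns[slot]
                ranks = []
                while col:
                    e = col.bit_length() - 1
                    ranks.append(e)
                    col ^= 1 << e
                edges = frozenset(
                    (int(self._edge_verts[e, 0]), int(self._edge_verts[e, 1]))
                    for e in ranks
                )
                return CycleRepresentative(pair=(b, d), edges=edges)
        raise ValueError(f"pair ({birth}, {death}) not found in diagram")


def rips_diagram_h1(points, max_scale: Optional[float] = None,
                    source_id: str = "") -> PersistenceDiagram:
    """Degree-1 Rips persistence diagram of a point cloud.

    With fewer than 3 points the diagram is empty.  If ``max_scale`` is
    omitted it defaults to the enclosing radius, which guarantees every
    class a finite death; smaller values may right-censor features, which
    are then reported with death = max_scale and a censored flag.
    """
    red = _Reduction(points, max_scale)
    dgm = red.diagram
    return PersistenceDiagram(pairs=dgm.pairs, max_scale=dgm.max_scale,
                              censored=dgm.censored, source_id=source_id)


def representative_cycle(points, pair, max_scale: Optional[float] = None
                         ) -> CycleRepresentative:
    """Mod-2 cycle (edge set) representing one diagram point of this cloud.

    Returns the reduced boundary column of the death triangle paired with
    the birth edge: all its edges exist at the birth scale and the cycle
    bounds at the death scale.
    """
    return _Reduction(points, max_scale).cycle(pair)


def reduction(points, max_scale: Optional[float] = None) -> _Reduction:
    """Run the reduction once and keep it for repeated cycle queries."""
    return _Reduction(points, max_scale)
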