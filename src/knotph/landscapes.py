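"""Exact piecewise-linear persistence landscapes.

A diagram point (b, d) contributes the tent function
``t -> max(0, min(t - b, d - t))``: a peak of height (d - b)/2 supported on
[b, d].  The k-th landscape layer is the pointwise k-th largest tent value.
Layers are stored exactly as ordered critical-point lists; no fixed grid is
ever introduced, so averages and L1/sup distances are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

DEFAULT_MAX_LAYERS = 10
_TOL = 1e-12


def _prune_collinear(t: np.ndarray, v: np.ndarray, tol: float = 1e-12
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Drop redundant critical points of a PL function.

    Sequential pruning: a point is dropped when it lies (within tol) on the
    chord from the last kept point to its successor.  Near-duplicate
    abscissae with equal values are merged first; removals are one at a
    time, so mutually redundant duplicates cannot erase a genuine kink.
    """
    if len(t) <= 2:
        return t, v
    idx = [0]
    for i in range(1, len(t)):
        if t[i] - t[idx[-1]] <= 1e-12 and abs(v[i] - v[idx[-1]]) <= 1e-9:
            continue
        idx.append(i)
    t, v = t[idx], v[idx]
    if len(t) <= 2:
        return t, v
    out_t, out_v = [t[0]], [v[0]]
    for i in range(1, len(t) - 1):
        t0, v0 = out_t[-1], out_v[-1]
        span = t[i + 1] - t0
        if span > 0:
            interp = v0 + (v[i + 1] - v0) * ((t[i] - t0) / span)
            if abs(v[i] - interp) <= tol * max(1.0, abs(v[i]) + 1):
                continue
        out_t.append(t[i])
        out_v.append(v[i])
    out_t.append(t[-1])
    out_v.append(v[-1])
    return np.asarray(out_t), np.asarray(out_v)


def _trim_support(t: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strip leading/trailing zero runs, keeping one zero at each end."""
    nz = np.nonzero(np.abs(v) > _TOL)[0]
    if not len(nz):
        return np.empty(0), np.empty(0)
    lo = max(nz[0] - 1, 0)
    hi = min(nz[-1] + 1, len(t) - 1)
    return t[lo:hi + 1], v[lo:hi + 1]


@dataclass(frozen=True)
class PersistenceLandscape:
    """Sequence of PL layer functions λ1 >= λ2 >= ... (critical-point lists).

    Each layer is a pair of arrays (t, value); value is 0 at both ends and
    the function is 0 outside the stored support.  A landscape with no
    layers is the zero landscape.
    """

    layers: tuple  # tuple of (t: ndarray, v: ndarray) pairs
    source_id: str = ""

    def __post_init__(self) -> None:
        norm = []
        for t, v in self.layers:
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.shape != v.shape or t.ndim != 1:
                raise ValueError("each layer needs matching 1-D (t, value) arrays")
            if len(t) and (np.any(np.diff(t) < 0) or np.any(v < -1e-9)):
                raise ValueError("layer abscissae must be sorted and values >= 0")
            norm.append((t, v))
        object.__setattr__(self, "layers", tuple(norm))

    @property
    def num_layers(self) -> int:
        return len(self.layers)

    def evaluate(self, k: int, t) -> np.ndarray:
        """Value of layer λk (1-based) at abscissae ``t``; 0 beyond support."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if k < 1 or k > len(self.layers):
            return np.zeros(len(t))
        xs, vs = self.layers[k - 1]
        if not len(xs):
            return np.zeros(len(t))
        return np.interp(t, xs, vs, left=0.0, right=0.0)

    def critical_abscissae(self) -> np.ndarray:
        if not self.layers:
            return np.empty(0)
        return np.unique(np.concatenate([t for t, _ in self.layers if len(t)] or
                                        [np.empty(0)]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_id": self.source_id,
                "layers": [np.stack([t, v], axis=1).tolist()
                           for t, v in self.layers],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PersistenceLandscape":
        data = json.loads(text)
        layers = []
        for layer in data["layers"]:
            arr = np.asarray(layer, dtype=float).reshape(-1, 2)
            layers.append((arr[:, 0], arr[:, 1]))
        return cls(layers=tuple(layers), source_id=data.get("source_id", ""))


def zero_landscape() -> PersistenceLandscape:
    return PersistenceLandscape(layers=())


def diagram_to_landscape(diagram, max_layers: int = DEFAULT_MAX_LAYERS
                         ) -> PersistenceLandscape:
    """Exact landscape of a persistence diagram.

    λk(t) is the k-th largest of the tent values max(0, min(t-b, d-t)).
    Critical abscissae can only occur at births, deaths, tent apexes and
    crossings of one tent's rising edge with another's falling edge; the
    k-th-largest envelope is linear between consecutive candidates, so
    evaluating on the full candidate set is exact.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    pairs = np.asarray(getattr(diagram, "pairs", diagram), dtype=float).reshape(-1, 2)
    if not len(pairs):
        return zero_landscape()
    b, d = pairs[:, 0], pairs[:, 1]

    cross = (b[:, None] + d[None, :]) / 2.0  # rising(i) meets falling(j)
    cand = np.unique(np.concatenate([b, d, cross.ravel()]))

    # tent values at all candidates: (n_cand, n_pairs)
    vals = np.minimum(cand[:, None] - b[None, :], d[None, :] - cand[:, None])
    np.maximum(vals, 0.0, out=vals)
    n_keep = min(max_layers, len(pairs))
    vals = -np.sort(-vals, axis=1)[:, :n_keep]

    layers = []
    for k in range(n_keep):
        t, v = _trim_support(cand, vals[:, k])
        if not len(t):
            break
        t, v = _prune_collinear(t, v)
        layers.append((t, v))
    return PersistenceLandscape(layers=tuple(layers),
                                source_id=getattr(diagram, "source_id", ""))


def average_landscape(landscapes: Sequence[PersistenceLandscape]
                      ) -> PersistenceLandscape:
    """Pointwise mean landscape, exact on the union of critical abscissae.

    Layers missing from a member count as the zero function.
    """
    landscapes = list(landscapes)
    if not landscapes:
        raise ValueError("cannot average an empty list of landscapes")
    n_layers = max((ls.num_layers for ls in landscapes), default=0)
    if n_layers == 0:
        return zero_landscape()
    layers = []
    for k in range(1, n_layers + 1):
        ts = [ls.layers[k - 1][0] for ls in landscapes
              if k <= ls.num_layers and len(ls.layers[k - 1][0])]
        if not ts:
            break
        grid = np.unique(np.concatenate(ts))
        acc = np.zeros(len(grid))
        for ls in landscapes:
            acc += ls.evaluate(k, grid)
        acc /= len(landscapes)
        t, v = _trim_support(grid, acc)
        if not len(t):
            continue
        t, v = _prune_collinear(t, v)
        layers.append((t, v))
    return PersistenceLandscape(layers=tuple(layers), source_id="average")


def _l1_between(t: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Exact integral of |a - b| for PL functions sharing abscissae ``t``."""
    d = a - b
    d0, d1 = d[:-1], d[1:]
    dt = np.diff(t)
    same = d0 * d1 >= 0
    area = np.where(
        same,
        0.5 * (np.abs(d0) + np.abs(d1)) * dt,
        # sign change: two triangles either side of the zero crossing
        0.5 * dt * (d0 * d0 + d1 * d1) / np.maximum(np.abs(d0 - d1), _TOL),
    )
    return float(area.sum())


def _layer_grids(a: PersistenceLandscape, b: PersistenceLandscape, k: int
                 ) -> Optional[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    ts = []
    for ls in (a, b):
        if k <= ls.num_layers and len(ls.layers[k - 1][0]):
            ts.append(ls.layers[k - 1][0])
    if not ts:
        return None
    grid = np.unique(np.concatenate(ts))
    return grid, a.evaluate(k, grid), b.evaluate(k, grid)


def landscape_distance(a: PersistenceLandscape, b: PersistenceLandscape,
                       norm: str = "L1",
                       layers: Optional[Iterable[int]] = None) -> float:
    """L1 or sup distance between two landscapes, exact from the PL form.

    ``layers`` optionally restricts to a subset of 1-based layer indices
    (e.g. ``[2]`` to compare only the λ2 layers).
    """
    if norm not in ("L1", "sup"):
        raise ValueError(f"unknown norm {norm!r}: expected 'L1' or 'sup'")
    n_layers = max(a.num_layers, b.num_layers)
    which = range(1, n_layers + 1) if layers is None else [int(k) for k in layers]
    total = 0.0
    for k in which:
        got = _layer_grids(a, b, k)
        if got is None:
            continue
        grid, va, vb = got
        if norm == "L1":
            total += _l1_between(grid, va, vb)
        else:
            total = max(total, float(np.max(np.abs(va - vb))))
    return total


def peak_to_pair(landscape: PersistenceLandscape, layer: int,
                 t_window: Optional[tuple[float, float]] = None
                 ) -> tuple[float, float]:
    """Invert a landscape peak to its diagram point.

    Finds the highest strict local maximum (t*, h) of layer ``layer``
    (1-based) within ``t_window`` and returns (t* - h, t* + h).  Plateau
    maxima (possible in averages) report the plateau midpoint.
    """
    if layer < 1 or layer > landscape.num_layers:
        raise ValueError(f"layer {layer} not present (landscape has "
                         f"{landscape.num_layers})")
    if t_window is None:
        t_window = (-np.inf, np.inf)
    lo, hi = t_window
    peaks = [(ts, h) for ts, h in local_maxima(landscape, layer)
             if lo - 1e-12 <= ts <= hi + 1e-12]
    if not peaks:
        raise ValueError("no strict local maximum of the layer inside the window")
    t_star, h = max(peaks, key=lambda p: p[1])
    return (t_star - h, t_star + h)


def local_maxima(landscape: PersistenceLandscape, layer: int
                 ) -> list[tuple[float, float]]:
    """All strict local maxima (t*, height) of one layer, in t order."""
    if layer < 1 or layer > landscape.num_layers:
        return []
    t, v = landscape.layers[layer - 1]
    out = []
    i, n = 0, len(t)
    while i < n:
        j = i
        while j + 1 < n and abs(v[j + 1] - v[i]) <= 1e-12:
            j += 1
        rising = i == 0 or v[i] > v[i - 1] + 1e-12
        falling = j == n - 1 or v[j + 1] < v[j] - 1e-12
        if rising and falling and v[i] > 1e-12:
            out.append((float(0.5 * (t[i] + t[j])), float(v[i])))
        i = j + 1
    return out
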