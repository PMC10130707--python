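"""Exact W1[L-infinity] Wasserstein distance between persistence diagrams.

Points may be matched to each other at L-infinity cost or projected to the
diagonal at cost (death - birth)/2; the minimum total cost over partial
matchings is found exactly as an assignment problem on the (n+m)-augmented
square cost matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .landscapes import PersistenceLandscape, landscape_distance

LANDSCAPE_METRICS = {
    "landscape_L1": {"norm": "L1", "layers": None},
    "landscape_L1_layer2": {"norm": "L1", "layers": [2]},
}
METRIC_NAMES = ("wasserstein_w1_linf",) + tuple(LANDSCAPE_METRICS)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError("distance matrix shape must match id count")
        if np.any(vals < -1e-9):
            raise ValueError("distances must be non-negative")
        if np.max(np.abs(vals - vals.T)) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(vals))) > 1e-9:
            raise ValueError("distance matrix must have a zero diagonal")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.ids),
                     columns=list(self.ids)).to_csv(path)

    def sidecar_json(self) -> str:
        return json.dumps({"metric_name": self.metric_name,
                           "ids": list(self.ids)})

    @classmethod
    def from_csv(cls, path, metric_name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=tuple(df.index), values=df.to_numpy(float),
                   metric_name=metric_name)


def _check_uncensored(diagram) -> np.ndarray:
    cens = getattr(diagram, "censored", None)
    if cens is not None and np.any(cens):
        raise ValueError(
            "diagram contains right-censored pairs; recompute with "
            "max_scale = enclosing_radius before taking Wasserstein distances"
        )
    return np.asarray(getattr(diagram, "pairs", diagram),
                      dtype=float).reshape(-1, 2)


def wasserstein_w1_linf(d1, d2) -> float:
    """Exact 1-Wasserstein distance with L-infinity ground metric."""
    p = _check_uncensored(d1)
    q = _check_uncensored(d2)
    n, m = len(p), len(q)
    if n == 0 and m == 0:
        return 0.0
    diag_p = (p[:, 1] - p[:, 0]) / 2.0
    diag_q = (q[:, 1] - q[:, 0]) / 2.0
    big = (diag_p.sum() if n else 0.0) + (diag_q.sum() if m else 0.0) + 1.0

    size = n + m
    cost = np.zeros((size, size))
    if n and m:
        cost[:n, :m] = np.max(
            np.abs(p[:, None, :] - q[None, :, :]), axis=2
        )
    cost[:n, m:] = big
    cost[:n, m:][np.arange(n), np.arange(n)] = diag_p
    cost[n:, :m] = big
    cost[n:, :m][np.arange(m), np.arange(m)] = diag_q
    # bottom-right block: diagonal to diagonal, free
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def pairwise_distances(items: Sequence, metric_name: str) -> DistanceMatrix:
    """Full symmetric distance matrix over diagrams or landscapes.

    ``metric_name`` is one of ``wasserstein_w1_linf`` (items are diagrams),
    ``landscape_L1`` or ``landscape_L1_layer2`` (items are landscapes).
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items for a distance matrix")
    if metric_name == "wasserstein_w1_linf":
        if any(isinstance(it, PersistenceLandscape) for it in items):
            raise TypeError("wasserstein_w1_linf expects persistence diagrams")
        dist = wasserstein_w1_linf
    elif metric_name in LANDSCAPE_METRICS:
        if not all(isinstance(it, PersistenceLandscape) for it in items):
            raise TypeError(f"{metric_name} expects persistence landscapes")
        opts = LANDSCAPE_METRICS[metric_name]
        def dist(a, b):
            return landscape_distance(a, b, norm=opts["norm"],
                                      layers=opts["layers"])
    else:
        raise ValueError(f"unknown metric {metric_name!r}; "
                         f"expected one of {METRIC_NAMES}")

    n = len(items)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = dist(items[i], items[j])
    ids = tuple(getattr(it, "source_id", "") or f"item_{k}"
                for k, it in enumerate(items))
    return DistanceMatrix(ids=ids, values=vals, metric_name=metric_name)
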