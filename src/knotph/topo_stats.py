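"""Group-label randomization test on average persistence landscapes.

The observed statistic is the distance between the two group average
landscapes.  The null distribution is built by Monte-Carlo shuffles of the
pooled group labels (group sizes preserved) and the p-value uses the
add-one estimator, so it can never be exactly zero.

For speed, every landscape is evaluated once on the union of all critical
abscissae; averages of piecewise-linear functions have critical points only
inside that union, so all recomputed statistics remain exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .landscapes import PersistenceLandscape, _l1_between


@dataclass(frozen=True)
class RandomizationResult:
    observed_statistic: float
    permutation_statistics: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    norm: str = "L1"
    layer_filter: Optional[tuple] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed_statistic": self.observed_statistic,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "norm": self.norm,
                "layer_filter": list(self.layer_filter)
                if self.layer_filter else None,
            }
        )


def _stack_on_grid(landscapes: Sequence[PersistenceLandscape],
                   layers: Optional[Iterable[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate all landscapes on the union grid; shape (n, L, G)."""
    n_layers = max((ls.num_layers for ls in landscapes), default=0)
    if layers is None:
        which = list(range(1, n_layers + 1))
    else:
        which = [int(k) for k in layers]
    ts = [ls.layers[k - 1][0] for ls in landscapes for k in which
          if k <= ls.num_layers and len(ls.layers[k - 1][0])]
    if not ts:
        grid = np.array([0.0, 1.0])
    else:
        grid = np.unique(np.concatenate(ts))
        if len(grid) < 2:
            grid = np.append(grid, grid[-1] + 1.0)
    mats = np.zeros((len(landscapes), len(which), len(grid)))
    for i, ls in enumerate(landscapes):
        for j, k in enumerate(which):
            mats[i, j] = ls.evaluate(k, grid)
    return grid, mats


def _group_statistic(grid: np.ndarray, mats: np.ndarray, mask: np.ndarray,
                     norm: str) -> float:
    mean_a = mats[mask].mean(axis=0)
    mean_b = mats[~mask].mean(axis=0)
    if norm == "sup":
        return float(np.max(np.abs(mean_a - mean_b)))
    return float(sum(_l1_between(grid, mean_a[j], mean_b[j])
                     for j in range(mats.shape[1])))


def randomization_test(group_a: Sequence[PersistenceLandscape],
                       group_b: Sequence[PersistenceLandscape],
                       n_permutations: int = 1000,
                       seed: int = 0,
                       norm: str = "L1",
                       layer_filter: Optional[Iterable[int]] = None
                       ) -> RandomizationResult:
    """Two-group randomization test for a difference in average landscapes."""
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if norm not in ("L1", "sup"):
        raise ValueError(f"unknown norm {norm!r}")

    pooled = group_a + group_b
    n_a = len(group_a)
    grid, mats = _stack_on_grid(pooled, layer_filter)

    mask = np.zeros(len(pooled), dtype=bool)
    mask[:n_a] = True
    observed = _group_statistic(grid, mats, mask, norm)

    # permutations run on a canonically sorted pool with the smaller group
    # size, so swapping the two group arguments cannot change the p-value
    order = np.lexsort(mats.reshape(len(pooled), -1).T[::-1])
    sorted_mats = mats[order]
    k = min(n_a, len(pooled) - n_a)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(len(pooled))
        perm_mask = np.zeros(len(pooled), dtype=bool)
        perm_mask[perm[:k]] = True
        perm_stats[p] = _group_statistic(grid, sorted_mats, perm_mask, norm)

    n_ge = int(np.sum(perm_stats >= observed - 1e-12))
    p_value = (1 + n_ge) / (1 + n_permutations)
    return RandomizationResult(
        observed_statistic=observed,
        permutation_statistics=perm_stats,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        norm=norm,
        layer_filter=tuple(layer_filter) if layer_filter is not None else None,
    )
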