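"""Seeded generators for open knotted/unknotted test curves.

The knotted core is sampled from the standard open trefoil parametrization
(sin t + 2 sin 2t, cos t - 2 cos 2t, -sin 3t) on [delta, 2*pi - delta] and
rescaled to a realistic consecutive-point spacing.  Straight, slightly
jittered tails appended at both ends control the knot depth; an unknotted
partner is produced by a tapered strand passage localized inside the core.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .curve_io import PointCloud

#: depth label thresholds on min(tail length) / total length
DEEP_FRACTION = 0.25
SHALLOW_FRACTION = 0.05

DEFAULT_SPACING = 3.8  # typical consecutive Cα distance, Å
DEFAULT_DELTA = 0.4  # opening gap of the parametric trefoil, radians


@dataclass(frozen=True)
class SyntheticCurve:
    """Open curve with ground-truth entanglement annotations."""

    points: np.ndarray  # (n, 3) Å
    knot_core: tuple[int, int]  # inclusive index interval of the core
    depth_category: str  # "deep" | "shallow" | "neither"
    knotted: bool
    seed: int
    params: dict = field(default_factory=dict)
    id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        lo, hi = self.knot_core
        if not (0 <= lo <= hi < len(pts)):
            raise ValueError("knot_core interval must lie within the index range")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("consecutive-point spacing must be positive")

    def __len__(self) -> int:
        return len(self.points)

    def to_cloud(self) -> PointCloud:
        n = len(self.points)
        return PointCloud(
            points=self.points,
            segment_index=np.minimum(np.arange(n), n - 2),
            fraction=np.where(np.arange(n) == n - 1, 1.0, 0.0),
            source_id=self.id,
        )

    def annotation_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "knot_core": list(self.knot_core),
                "depth_category": self.depth_category,
                "knotted": self.knotted,
                "seed": self.seed,
                "params": self.params,
            }
        )


def depth_label(min_tail: int, total: int) -> str:
    frac = min_tail / total
    if frac >= DEEP_FRACTION:
        return "deep"
    if frac <= SHALLOW_FRACTION:
        return "shallow"
    return "neither"


def _trefoil_core(n_core: int, delta: float) -> np.ndarray:
    t = np.linspace(delta, 2 * np.pi - delta, n_core)
    return np.stack(
        [np.sin(t) + 2 * np.sin(2 * t),
         np.cos(t) - 2 * np.cos(2 * t),
         -np.sin(3 * t)],
        axis=1,
    )


#: coiled-tail geometry, relative to the consecutive-point spacing: a wide
#: coil (8 points per turn) whose turns are persistent degree-1 rings, so
#: tail length — hence knot depth — is visible to the persistence stages
_HELIX_POINTS_PER_TURN = 8
_HELIX_TURN = 2 * np.pi / _HELIX_POINTS_PER_TURN
_HELIX_CHORD = 0.98  # fraction of the spacing spent on the turn circle


def _grow_tail(start: np.ndarray, direction: np.ndarray, length: int,
               spacing: float, rng: np.random.Generator, core: np.ndarray
               ) -> np.ndarray:
    """Coiled tail of ``length`` points winding away from the core.

    The tail is a regular helix around a jittered outward straight axis.
    Axial progress is strictly monotone, so the tail is isotopic to a
    straight ray and introduces no new entanglement; unlike a straight ray
    it carries persistent degree-1 rings of its own, which is what makes
    knot depth visible to the downstream persistence stages.

    A candidate axis is accepted when, beyond the attachment turn, its
    centre line keeps the whole coil body clear of every core point.
    """
    chord = _HELIX_CHORD * spacing
    radius = chord / (2 * np.sin(_HELIX_TURN / 2))
    rise = np.sqrt(spacing ** 2 - chord ** 2)
    clearance = radius + 0.5 * spacing
    for _ in range(100):
        jitter = rng.normal(scale=0.05, size=3)
        d = direction + jitter
        d /= np.linalg.norm(d)
        # orthonormal frame perpendicular to the axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        phase = rng.uniform(0, 2 * np.pi)
        k = np.arange(1, length + 1)[:, None]
        angles = _HELIX_TURN * k + phase
        offset = radius * (np.cos(phase) * u + np.sin(phase) * v)
        centres = start[None, :] + rise * k * d[None, :]
        pts = (centres - offset[None, :]
               + radius * (np.cos(angles) * u[None, :]
                           + np.sin(angles) * v[None, :]))
        far_centres = centres[_HELIX_POINTS_PER_TURN:]
        # the attachment neighbourhood is necessarily close; only core
        # points away from it can be threaded and must stay clear
        far_core = core[np.linalg.norm(core - start, axis=1) > 2 * clearance]
        if len(far_centres) and len(far_core):
            gap = np.linalg.norm(
                far_centres[:, None, :] - far_core[None, :, :], axis=2).min()
            if gap < clearance:
                continue
        return pts
    raise RuntimeError("could not grow a tail clear of the core "
                       "after 100 jitter retries")


def make_open_trefoil(n_core: int = 60,
                      tail_lengths: tuple[int, int] = (0, 0),
                      spacing: float = DEFAULT_SPACING,
                      seed: int = 0,
                      delta: float = DEFAULT_DELTA,
                      core_jitter: float = 0.12,
                      id: str = "") -> SyntheticCurve:
    """Open trefoil-knotted curve with tails controlling knot depth.

    The core is rescaled so the mean consecutive spacing equals ``spacing``;
    tails are coils around straight axes with small seeded angular jitter,
    directed outward from the core centroid, so they introduce no new
    entanglement while still carrying degree-1 structure of their own.
    """
    if n_core < 30:
        raise ValueError("n_core must be >= 30 to realize the trefoil geometry")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    t0, t1 = int(tail_lengths[0]), int(tail_lengths[1])
    if t0 < 0 or t1 < 0:
        raise ValueError("tail lengths must be >= 0")

    rng = np.random.default_rng(seed)
    core = _trefoil_core(n_core, delta)
    steps = np.linalg.norm(np.diff(core, axis=0), axis=1)
    core *= spacing / steps.mean()
    if core_jitter > 0:
        # smooth seeded deformation: same-parameter curves from different
        # seeds are distinct but keep the trefoil geometry
        rough = rng.normal(scale=core_jitter * spacing, size=core.shape)
        kernel = np.ones(5) / 5.0
        smooth = np.stack([np.convolve(rough[:, a], kernel, mode="same")
                           for a in range(3)], axis=1)
        core += smooth

    centroid = core.mean(axis=0)

    parts = []
    if t0:
        d = core[0] - centroid
        d /= np.linalg.norm(d)
        head = _grow_tail(core[0], d, t0, spacing, rng, core)[::-1]
        parts.append(head)
    parts.append(core)
    if t1:
        d = core[-1] - centroid
        d /= np.linalg.norm(d)
        parts.append(_grow_tail(core[-1], d, t1, spacing, rng, core))
    points = np.concatenate(parts)

    total = len(points)
    label = depth_label(min(t0, t1), total)
    return SyntheticCurve(
        points=points,
        knot_core=(t0, t0 + n_core - 1),
        depth_category=label,
        knotted=True,
        seed=seed,
        params={"n_core": n_core, "tail_lengths": [t0, t1],
                "spacing": spacing, "delta": delta,
                "core_jitter": core_jitter},
        id=id or f"trefoil_s{seed}",
    )


def crossing_windows(curve: SyntheticCurve, half_width: Optional[int] = None
                     ) -> list[tuple[int, int]]:
    """Index windows realizing the crossings of the standard xy projection.

    For each crossing of the trefoil's xy shadow, returns a window centred
    on the over-strand (larger z) point, restricted to the knot core.  Any
    of these windows is a valid argument to :func:`make_unknotted_partner`;
    wider windows (e.g. ``half_width=9`` on a 60-point core) spread the
    strand passage over a longer arc and remove the knotted-only
    persistence feature more reliably.
    """
    lo, hi = curve.knot_core
    pts = curve.points[lo:hi + 1]
    n = len(pts)
    if half_width is None:
        half_width = max(3, n // 10)
    xy = pts[:, :2]
    d2 = cdist(xy, xy)
    idx = np.arange(n)
    far = np.abs(idx[:, None] - idx[None, :]) > n // 6
    spacing = np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1))
    radius = max(3, n // 12)
    windows: list[tuple[int, int]] = []
    # widen the xy proximity threshold until the three standard-diagram
    # crossings are resolved (sampling phase can miss a crossing at 2x)
    for factor in (2.0, 2.5, 3.0, 3.5, 4.0):
        cand = np.argwhere(np.triu(far & (d2 < factor * spacing)))
        clusters: list[list[np.ndarray]] = []
        for pair in cand:
            for cl in clusters:
                if any(np.all(np.abs(pair - q) <= radius) for q in cl):
                    cl.append(pair)
                    break
            else:
                clusters.append([pair])
        windows = []
        for cl in clusters:
            arr = np.array(cl)
            i, j = arr[np.argmin(d2[arr[:, 0], arr[:, 1]])]
            over = i if pts[i, 2] > pts[j, 2] else j
            a = max(int(over) - half_width, 0)
            b = min(int(over) + half_width, n - 1)
            window = (int(lo + a), int(lo + b))
            # drop duplicates from clusters resolving to the same over-strand
            if all(w[1] < window[0] or window[1] < w[0] for w in windows):
                windows.append(window)
        if len(windows) >= 3:
            break
    windows.sort()
    return windows


def make_unknotted_partner(curve: SyntheticCurve,
                           window: tuple[int, int],
                           pass_scale: float = 2.0) -> SyntheticCurve:
    """Untie a knotted curve by one localized strand passage.

    Points inside ``window`` (inclusive) are displaced along a fixed
    direction — towards and past the nearest non-adjacent strand — with a
    cosine taper vanishing at the window boundaries.  Everything outside
    the window is bit-identical to the input.
    """
    lo, hi = window
    if not (0 <= lo <= hi < len(curve.points)):
        raise ValueError("window must lie within the curve index range")
    clo, chi = curve.knot_core
    if lo < clo or hi > chi:
        raise ValueError("window must lie inside the knot core")

    pts = curve.points.copy()
    centre = (lo + hi) // 2
    # the strand being crossed is the xy-nearest non-adjacent point: at a
    # projection crossing the two strands share xy but differ in z
    d_xy = np.linalg.norm(pts[:, :2] - pts[centre, :2], axis=1)
    idx = np.arange(len(pts))
    d_xy[np.abs(idx - centre) <= (hi - lo + 2)] = np.inf
    other = int(np.argmin(d_xy))
    separation = float(np.linalg.norm(pts[other] - pts[centre]))
    direction = pts[other] - pts[centre]
    direction /= np.linalg.norm(direction)
    amplitude = pass_scale * separation

    # cosine taper vanishing just outside the window, so every point inside
    # the window moves and the curve stays continuous at the boundaries
    rel = (idx[lo:hi + 1] - lo + 1) / (hi - lo + 2)
    taper = 0.5 * (1.0 - np.cos(2 * np.pi * rel))
    pts[lo:hi + 1] += amplitude * taper[:, None] * direction

    return SyntheticCurve(
        points=pts,
        knot_core=curve.knot_core,
        depth_category=curve.depth_category,
        knotted=False,
        seed=curve.seed,
        params={**curve.params, "passage_window": [int(lo), int(hi)],
                "pass_scale": pass_scale},
        id=(curve.id + "_unknotted") if curve.id else "unknotted_partner",
    )


def add_noise(cloud, sigma: float, seed: int = 0):
    """Perturb every coordinate by i.i.d. centred Gaussian noise (std sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(cloud, PointCloud):
        pts = cloud.points + rng.normal(scale=sigma, size=cloud.points.shape) \
            if sigma > 0 else cloud.points.copy()
        return PointCloud(points=pts, segment_index=cloud.segment_index,
                          fraction=cloud.fraction, source_id=cloud.source_id)
    if isinstance(cloud, SyntheticCurve):
        pts = cloud.points + rng.normal(scale=sigma, size=cloud.points.shape) \
            if sigma > 0 else cloud.points.copy()
        return SyntheticCurve(points=pts, knot_core=cloud.knot_core,
                              depth_category=cloud.depth_category,
                              knotted=cloud.knotted, seed=cloud.seed,
                              params={**cloud.params, "noise_sigma": sigma},
                              id=cloud.id)
    pts = np.asarray(cloud, dtype=float)
    return pts + rng.normal(scale=sigma, size=pts.shape) if sigma > 0 \
        else pts.copy()
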