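"""Backbone extraction and point-cloud construction.

A protein structure is modelled as the piecewise-linear curve through its
Cα atoms.  The point cloud fed to the persistence machinery consists of the
Cα positions themselves plus a fixed number of equidistant interior points
per backbone segment.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: consecutive-Cα distance above which a chain gap warning is emitted (Å)
GAP_WARN_DISTANCE = 4.5

#: default number of interior points interpolated per backbone segment
DEFAULT_POINTS_PER_GAP = 5


@dataclass(frozen=True)
class ChainAnnotations:
    """Optional per-chain metadata (labels supplied externally, never computed)."""

    homology_class: Optional[str] = None
    depth_category: Optional[str] = None  # "deep" | "shallow" | "neither"
    knot_core: Optional[tuple[int, int]] = None  # inclusive residue-number span


@dataclass(frozen=True)
class BackboneChain:
    """Ordered Cα trace of one protein chain.

    Parameters
    ----------
    id : str
        Structure identifier, e.g. ``"3KZK_A"``.
    residue_numbers : ndarray of int, shape (n,)
        Author residue numbers, strictly increasing (insertion-code
        duplicates keep file order and may repeat a number).
    coordinates : ndarray of float, shape (n, 3)
        Cα positions in Å, copied verbatim from the input.
    annotations : ChainAnnotations, optional
    """

    id: str
    residue_numbers: np.ndarray
    coordinates: np.ndarray
    annotations: ChainAnnotations = field(default_factory=ChainAnnotations)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        nums = np.asarray(self.residue_numbers, dtype=int)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "residue_numbers", nums)
        if len(nums) < 2:
            raise ValueError("backbone chain needs at least 2 residues")
        if coords.shape != (len(nums), 3):
            raise ValueError("coordinates must have shape (n_residues, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("backbone coordinates must be finite")
        if np.any(np.diff(nums) < 0):
            raise ValueError("residue numbers must be non-decreasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)


@dataclass(frozen=True)
class PointCloud:
    """Ordered 3-D points with provenance back to the source curve.

    ``segment_index[i]`` is the index of the backbone segment point *i* lies
    on (segment *s* joins curve vertices *s* and *s*+1); ``fraction[i]`` is
    its fractional position along that segment, in [0, 1].  A curve vertex
    *v* is encoded as segment ``v`` with fraction 0, except the final vertex
    which closes segment ``n-2`` with fraction 1.
    """

    points: np.ndarray
    segment_index: np.ndarray
    fraction: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        seg = np.asarray(self.segment_index, dtype=int)
        frac = np.asarray(self.fraction, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "segment_index", seg)
        object.__setattr__(self, "fraction", frac)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("point cloud must be an (n >= 2, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point-cloud coordinates must be finite")
        if seg.shape != (len(pts),) or frac.shape != (len(pts),):
            raise ValueError("provenance arrays must match point count")
        if np.any(frac < 0) or np.any(frac > 1):
            raise ValueError("provenance fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "segment_index": self.segment_index,
                "fraction": self.fraction,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source_id: str = "") -> "PointCloud":
        df = pd.read_csv(path)
        return cls(
            points=df[["x", "y", "z"]].to_numpy(float),
            segment_index=df["segment_index"].to_numpy(int),
            fraction=df["fraction"].to_numpy(float),
            source_id=source_id,
        )


def _select_altloc(atoms) -> "object":
    """Pick a single Cα among altloc duplicates.

    Highest occupancy wins; occupancy ties are broken by altloc letter order.
    """
    def key(atom):
        occ = atom.get_occupancy()
        occ = 0.0 if occ is None else float(occ)
        return (-occ, atom.get_altloc())

    return sorted(atoms, key=key)[0]


def read_backbone(
    pdb_text: str,
    chain_id: str,
    model_index: int = 0,
    structure_id: str = "",
    annotations: Optional[ChainAnnotations] = None,
) -> BackboneChain:
    """Parse PDB text and extract the Cα trace of one chain.

    Coordinates are copied verbatim (Å).  One entry is produced per residue
    possessing a Cα atom, in file order.  Altloc duplicates are resolved to
    the highest-occupancy conformer; the first model is used by default.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(structure_id or "structure", io.StringIO(pdb_text))

    models = list(structure)
    if model_index >= len(models) or model_index < 0:
        raise ValueError(
            f"model {model_index} not present; file has {len(models)} model(s)"
        )
    model = models[model_index]

    available = [c.id for c in model]
    if chain_id not in available:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(available)}"
        )
    chain = model[chain_id]

    numbers: list[int] = []
    coords: list[np.ndarray] = []
    for residue in chain:
        ca_atoms = []
        for atom in residue:
            if atom.get_name() != "CA":
                continue
            if (atom.element or "").strip().upper() == "CA":
                continue  # calcium ion, not an alpha carbon
            if atom.is_disordered():
                ca_atoms.extend(atom.disordered_get_list())
            else:
                ca_atoms.append(atom)
        if not ca_atoms:
            continue
        atom = ca_atoms[0] if len(ca_atoms) == 1 else _select_altloc(ca_atoms)
        numbers.append(residue.get_id()[1])
        coords.append(np.asarray(atom.get_coord(), dtype=float))

    if not coords:
        raise ValueError(f"chain {chain_id!r} contains no Cα atoms")

    chain_label = f"{structure_id}_{chain_id}" if structure_id else chain_id
    backbone = BackboneChain(
        id=chain_label,
        residue_numbers=np.array(numbers, dtype=int),
        coordinates=np.array(coords, dtype=float),
        annotations=annotations or ChainAnnotations(),
    )

    gaps = np.linalg.norm(np.diff(backbone.coordinates, axis=0), axis=1)
    for idx in np.nonzero(gaps > GAP_WARN_DISTANCE)[0]:
        logger.warning(
            "%s: consecutive Cα distance %.2f Å between residues %d and %d "
            "exceeds %.1f Å (chain gap?); interpolating across it",
            backbone.id, gaps[idx], numbers[idx], numbers[idx + 1], GAP_WARN_DISTANCE,
        )
    return backbone


def interpolate_cloud(
    chain_or_points, points_per_gap: int = DEFAULT_POINTS_PER_GAP, source_id: str = ""
) -> PointCloud:
    """Build the interpolated point cloud of a piecewise-linear curve.

    Every curve vertex is kept and ``points_per_gap`` strictly interior
    equidistant points are inserted per segment (at fractions k/(g+1)),
    giving ``n + points_per_gap * (n - 1)`` points in curve order.
    ``points_per_gap = 0`` yields the bare vertex cloud.
    """
    if points_per_gap < 0:
        raise ValueError("points_per_gap must be >= 0")

    if isinstance(chain_or_points, BackboneChain):
        vertices = chain_or_points.coordinates
        source_id = source_id or chain_or_points.id
    else:
        vertices = np.asarray(chain_or_points, dtype=float)

    n = len(vertices)
    g = points_per_gap
    fractions = np.arange(1, g + 1, dtype=float) / (g + 1)

    points = np.empty((n + g * (n - 1), 3), dtype=float)
    seg = np.empty(len(points), dtype=int)
    frac = np.empty(len(points), dtype=float)
    stride = g + 1
    points[::stride] = vertices
    seg[::stride] = np.minimum(np.arange(n), n - 2)
    frac[::stride] = 0.0
    frac[len(points) - 1] = 1.0
    for k, f in enumerate(fractions, start=1):
        points[k::stride] = vertices[:-1] + f * (vertices[1:] - vertices[:-1])
        seg[k::stride] = np.arange(n - 1)
        frac[k::stride] = f
    return PointCloud(points=points, segment_index=seg, fraction=frac,
                      source_id=source_id)


METADATA_COLUMNS = [
    "structure_id", "chain", "homology_class", "depth_category",
    "knot_core_start", "knot_core_end",
]


def read_metadata(path) -> pd.DataFrame:
    """Load the per-protein metadata table (labels are inputs, not computed).

    Columns: structure_id, chain, homology_class, depth_category,
    knot_core_start, knot_core_end (residue numbers, both ends inclusive).
    """
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table is missing columns: {missing}")
    return df


def annotations_for(df: pd.DataFrame, structure_id: str, chain: str) -> ChainAnnotations:
    """Look up one chain's annotations in the metadata table."""
    rows = df[(df["structure_id"] == structure_id) & (df["chain"] == chain)]
    if rows.empty:
        return ChainAnnotations()
    row = rows.iloc[0]
    core = None
    if pd.notna(row["knot_core_start"]) and pd.notna(row["knot_core_end"]):
        core = (int(row["knot_core_start"]), int(row["knot_core_end"]))
    return ChainAnnotations(
        homology_class=str(row["homology_class"]),
        depth_category=str(row["depth_category"]),
        knot_core=core,
    )
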