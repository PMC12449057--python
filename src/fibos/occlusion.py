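"""Occlusion engine: burial filtering and outward-normal ray casting.

For every surface dot of every atom, the engine

1. removes dots buried inside any other atom's vdW sphere, then
2. extends the outward radial normal from each retained dot until it either
   intersects a neighbouring atom's vdW sphere (the dot is *occluded*, with
   normal length L = the distance to the first intersection) or travels
   farther than the water diameter ``d_w`` (the dot is non-occluded: a water
   molecule could fit in the gap, so the dot is disregarded downstream).

Neighbour lookup uses a fixed-radius spatial query with cutoff
``2 r_max + d_w`` — sufficient for any dot-to-surface hit — so results are
identical to exhaustive all-pairs ray casting (verified against the
brute-force oracle in the test suite).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dots import DotCloud, dots_on_atom
from .structure import Atom, Structure

__all__ = [
    "DEFAULT_WATER_DIAMETER",
    "NeighborIndex",
    "OcclusionRecord",
    "build_neighbor_index",
    "remove_buried_dots",
    "cast_normal",
    "occlude_atom",
    "compute_occlusion",
    "records_to_frame",
]

#: default maximum normal extension: the diameter of a water molecule (A)
DEFAULT_WATER_DIAMETER = 2.8


@dataclasses.dataclass
class OcclusionRecord:
    """Outcome for one retained surface dot."""

    atom_serial: int
    dot_index: int
    dot_area: float  # A^2
    x: float
    y: float
    z: float
    occluded: bool
    length: float  # normal length L in A; meaningful only when occluded
    occluder_serial: int | None


class NeighborIndex:
    """Fixed-radius neighbour queries over atom centers (k-d tree backed).

    ``query`` returns exactly the atoms whose center lies within the cutoff
    of a point — equivalent to an all-pairs distance scan.
    """

    def __init__(self, structure: Structure, cutoff: float) -> None:
        self.structure = structure
        self.cutoff = float(cutoff)
        self._coords = structure.coords()
        self._radii = structure.radii() if len(structure) else np.zeros(0)
        self._tree = cKDTree(self._coords) if len(structure) else None
        self._serial_to_index = {a.serial: i for i, a in enumerate(structure)}

    def query_point(self, point: np.ndarray, cutoff: float | None = None) -> list[int]:
        """Indices of all atoms with center distance <= cutoff from point."""
        if self._tree is None:
            return []
        c = self.cutoff if cutoff is None else cutoff
        return sorted(self._tree.query_ball_point(np.asarray(point, dtype=float), c))

    def neighbors_of(self, atom_index: int) -> list[int]:
        """Indices of atoms within the cutoff of atom ``atom_index``, itself excluded."""
        hits = self.query_point(self._coords[atom_index])
        return [i for i in hits if i != atom_index]

    def neighbor_atoms(self, atom: Atom) -> list[Atom]:
        i = self._serial_to_index[atom.serial]
        return [self.structure[j] for j in self.neighbors_of(i)]


def build_neighbor_index(
    s: Structure, max_radius: float | None = None, d_w: float = DEFAULT_WATER_DIAMETER
) -> NeighborIndex:
    """Index with cutoff ``2 max_radius + d_w`` (covers every possible hit).

    A normal starts on a sphere of radius <= r_max, travels at most d_w, and
    can touch a sphere of radius <= r_max, so no occluding atom center can
    be farther than 2 r_max + d_w from the source atom center.
    """
    if max_radius is None:
        max_radius = float(s.radii().max()) if len(s) else 0.0
    return NeighborIndex(s, cutoff=2.0 * max_radius + d_w)


def _buried_mask(
    points: np.ndarray, nb_centers: np.ndarray, nb_radii: np.ndarray
) -> np.ndarray:
    """True where a dot lies strictly inside some neighbour sphere."""
    if len(nb_centers) == 0 or len(points) == 0:
        return np.zeros(len(points), dtype=bool)
    diff = points[:, None, :] - nb_centers[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    return np.any(d2 < nb_radii[None, :] ** 2, axis=1)


def remove_buried_dots(
    atom: Atom, dots: DotCloud, neighbors: Sequence[Atom]
) -> tuple[DotCloud, np.ndarray]:
    """Drop dots lying strictly inside any neighbouring atom's vdW sphere.

    A dot exactly on a neighbour's surface (distance == radius) is retained.
    Returns the filtered cloud and the original indices of the kept dots.
    """
    nb_centers = np.array([n.coord for n in neighbors], dtype=float).reshape(-1, 3)
    nb_radii = np.array([n.radius for n in neighbors], dtype=float)
    buried = _buried_mask(dots.points, nb_centers, nb_radii)
    keep = np.flatnonzero(~buried)
    cloud = DotCloud(
        dots.points[keep],
        dots.areas[keep],
        dots.method,
        center=dots.center,
        radius=dots.radius,
    )
    return cloud, keep


def _first_hits(
    origins: np.ndarray,
    directions: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """First ray-sphere intersection per ray.

    Solves |o + t d - c|^2 = r^2 for each ray/sphere pair and takes the
    smallest admissible t per ray: the smaller positive root when the origin
    is outside the sphere, t = 0 when the origin is inside (entry root
    non-positive, exit root positive).  Returns (t, sphere_index); rays that
    hit nothing get t = inf and index -1.
    """
    n = len(origins)
    if len(centers) == 0 or n == 0:
        return np.full(n, np.inf), np.full(n, -1, dtype=int)
    m = origins[:, None, :] - centers[None, :, :]  # (n, j, 3)
    b = np.einsum("ik,ijk->ij", directions, m)
    c = np.einsum("ijk,ijk->ij", m, m) - radii[None, :] ** 2
    disc = b * b - c
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(disc)
    t1 = -b - sq
    t2 = -b + sq
    t = np.where(t1 > 0.0, t1, np.where(t2 > 0.0, 0.0, np.inf))
    t = np.where(disc >= 0.0, t, np.inf)
    best = np.argmin(t, axis=1)
    tmin = t[np.arange(n), best]
    idx = np.where(np.isfinite(tmin), best, -1)
    return tmin, idx


def cast_normal(
    origin: np.ndarray,
    direction: np.ndarray,
    neighbors: Sequence[Atom],
    d_w: float = DEFAULT_WATER_DIAMETER,
) -> tuple[bool, float | None, int | None]:
    """Trace one normal: (occluded, length, occluder serial).

    ``length`` is the distance to the first vdW surface hit; the dot is
    occluded iff that distance is <= ``d_w``.  An origin strictly inside a
    neighbour sphere yields an occlusion of length 0.
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    if d_w <= 0:
        raise ValueError(f"d_w must be positive, got {d_w}")
    centers = np.array([a.coord for a in neighbors], dtype=float).reshape(-1, 3)
    radii = np.array([a.radius for a in neighbors], dtype=float)
    t, idx = _first_hits(
        np.asarray(origin, dtype=float)[None, :], direction[None, :], centers, radii
    )
    if t[0] <= d_w:
        return True, float(t[0]), neighbors[int(idx[0])].serial
    return False, None, None


def occlude_atom(
    atom: Atom,
    dots: DotCloud,
    neighbors: Sequence[Atom],
    d_w: float = DEFAULT_WATER_DIAMETER,
    dot_indices: np.ndarray | None = None,
) -> list[OcclusionRecord]:
    """Ray-cast every retained dot of one atom against its neighbours.

    ``dots`` must already be the post-burial surface dots scaled onto the
    atom; directions are radially outward from the atom center.
    ``dot_indices`` optionally carries the dots' indices in the original
    (pre-removal) cloud for traceability.
    """
    n = dots.n_dots
    if dot_indices is None:
        dot_indices = np.arange(n)
    centers = np.array([a.coord for a in neighbors], dtype=float).reshape(-1, 3)
    radii = np.array([a.radius for a in neighbors], dtype=float)
    dirs = dots.points - atom.coord
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / norms
    t, idx = _first_hits(dots.points, dirs, centers, radii)
    occluded = t <= d_w
    records = []
    for k in range(n):
        hit = bool(occluded[k])
        records.append(
            OcclusionRecord(
                atom_serial=atom.serial,
                dot_index=int(dot_indices[k]),
                dot_area=float(dots.areas[k]),
                x=float(dots.points[k, 0]),
                y=float(dots.points[k, 1]),
                z=float(dots.points[k, 2]),
                occluded=hit,
                length=float(t[k]) if hit else math.nan,
                occluder_serial=neighbors[int(idx[k])].serial if hit else None,
            )
        )
    return records


def compute_occlusion(
    structure: Structure,
    density: float = 5.0,
    method: str = "fibos",
    d_w: float = DEFAULT_WATER_DIAMETER,
    dot_clouds: Sequence[DotCloud] | None = None,
) -> list[OcclusionRecord]:
    """Full occlusion pass over a structure.

    Generates each atom's dot cloud (unless ``dot_clouds`` supplies
    pre-built ones, e.g. for rigid-motion experiments), removes buried dots,
    and ray-casts the rest.  Records are returned in atom order, retained
    dots only.
    """
    if dot_clouds is not None and len(dot_clouds) != len(structure):
        raise ValueError("dot_clouds must provide one cloud per atom")
    index = build_neighbor_index(structure, d_w=d_w)
    records: list[OcclusionRecord] = []
    for i, atom in enumerate(structure):
        cloud = dot_clouds[i] if dot_clouds is not None else dots_on_atom(
            atom, density=density, method=method
        )
        neighbors = [structure[j] for j in index.neighbors_of(i)]
        surface, kept = remove_buried_dots(atom, cloud, neighbors)
        records.extend(occlude_atom(atom, surface, neighbors, d_w=d_w, dot_indices=kept))
    return records


def records_to_frame(records: Sequence[OcclusionRecord], structure: Structure):
    """Normals table: one row per retained dot, annotated with atom identity."""
    import pandas as pd

    meta = {a.serial: a for a in structure}
    rows = []
    for r in records:
        a = meta[r.atom_serial]
        rows.append(
            {
                "atom_serial": r.atom_serial,
                "chain": a.chain_id,
                "res_seq": a.res_seq,
                "res_name": a.res_name,
                "atom_name": a.name,
                "dot_index": r.dot_index,
                "x": r.x,
                "y": r.y,
                "z": r.z,
                "occluded": r.occluded,
                "length": r.length,
                "occluder_serial": r.occluder_serial,
            }
        )
    columns = [
        "atom_serial", "chain", "res_seq", "res_name", "atom_name", "dot_index",
        "x", "y", "z", "occluded", "length", "occluder_serial",
    ]
    return pd.DataFrame(rows, columns=columns)
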