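"""Surface-dot lattices on the unit sphere and on atom vdW spheres.

Two deterministic constructions are provided:

* ``fibonacci_points`` — the golden-angle (Fibonacci) spiral lattice, giving
  near-uniform nearest-neighbour spacing and exactly equal per-dot areas.
  This is the default ("fibos") method.
* ``radial_points`` — the classical axis-referenced lattice: latitude bands
  equally spaced in polar angle about the z axis, each band carrying dots
  equally spaced in azimuth with count proportional to the band
  circumference.  It shows the known axial anisotropy and pole/equator area
  inhomogeneity that the Fibonacci lattice removes.

Each dot carries an area weight: a fraction of the unit sphere before
scaling, squared angstroms after ``dots_on_atom`` scales the cloud onto an
atom's van der Waals sphere.  Area is conserved exactly by construction.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .structure import Atom

__all__ = ["DotCloud", "GOLDEN_ANGLE", "fibonacci_points", "radial_points", "dots_on_atom"]

#: golden angle in radians, pi * (3 - sqrt(5))
GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: dot-generation methods; "fibos" is the default
METHODS = ("fibos", "os")


@dataclasses.dataclass
class DotCloud:
    """A set of surface dots with per-dot area weights.

    Before scaling, points are unit vectors and areas are fractions of the
    sphere summing to 1.  After scaling onto an atom, points are absolute
    coordinates (A) and areas are in A^2 summing to 4*pi*r^2.
    """

    points: np.ndarray  # (n, 3)
    areas: np.ndarray  # (n,)
    method: str
    center: np.ndarray | None = None  # set once scaled onto an atom
    radius: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.areas.shape != (self.points.shape[0],):
            raise ValueError("areas must match points in length")
        if np.any(self.areas <= 0):
            raise ValueError("all dot areas must be positive")

    @property
    def n_dots(self) -> int:
        return self.points.shape[0]

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "DotCloud":
        """Apply a rigid motion (rotation about the origin, then translation)."""
        pts = self.points
        ctr = self.center
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            pts = pts @ rotation.T
            if ctr is not None:
                ctr = rotation @ ctr
        pts = pts + translation
        if ctr is not None:
            ctr = ctr + translation
        return DotCloud(pts, self.areas.copy(), self.method, center=ctr, radius=self.radius)


def fibonacci_points(n: int) -> DotCloud:
    """Golden-angle spiral lattice of ``n`` dots on the unit sphere.

    z_i = 1 - 2(i + 1/2)/n places dots at equal-area latitudes (no dot sits
    exactly on a pole); the azimuth advances by the golden angle.  Every dot
    carries the same area fraction 1/n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * GOLDEN_ANGLE
    points = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    areas = np.full(n, 1.0 / n)
    return DotCloud(points, areas, method="fibos")


def radial_points(n_target: int) -> DotCloud:
    """Axis-referenced latitude-band lattice with ~``n_target`` dots.

    Bands are equally spaced in polar angle about z; dot counts per band are
    apportioned to band circumference (largest-remainder rounding, minimum
    one dot per band), and each dot's area fraction is its band's exact area
    fraction divided by the band's dot count.
    """
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    # bands are packed 1.5x tighter in polar angle than dots are in azimuth;
    # the rectangular patches carry the axial anisotropy characteristic of
    # the classical axis-referenced construction
    n_bands = max(1, round(1.5 * math.sqrt(math.pi * n_target) / 2.0))
    edges = np.linspace(0.0, math.pi, n_bands + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    band_area = 0.5 * (np.cos(edges[:-1]) - np.cos(edges[1:]))  # sums to 1

    counts = _apportion(np.sin(centers), n_target)

    pts: list[np.ndarray] = []
    areas: list[np.ndarray] = []
    for theta, frac, m in zip(centers, band_area, counts):
        phi = 2.0 * math.pi * np.arange(m) / m
        st, ct = math.sin(theta), math.cos(theta)
        pts.append(np.column_stack([st * np.cos(phi), st * np.sin(phi), np.full(m, ct)]))
        areas.append(np.full(m, frac / m))
    return DotCloud(np.vstack(pts), np.concatenate(areas), method="os")


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts proportional to weights: largest remainder, minimum 1."""
    quota = weights * (total / weights.sum())
    counts = np.floor(quota).astype(int)
    rem = total - int(counts.sum())
    if rem > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    # guarantee every band at least one dot, borrowing from the largest bands
    while np.any(counts < 1):
        need = counts < 1
        counts[need] = 1
        surplus = int(counts.sum()) - total
        donors = np.argsort(-counts, kind="stable")
        for d in donors:
            if surplus <= 0:
                break
            give = min(surplus, counts[d] - 1)
            counts[d] -= give
            surplus -= give
        break  # single pass suffices: donors stay >= 1
    return counts


def dots_on_atom(atom: Atom, density: float = 5.0, method: str = "fibos") -> DotCloud:
    """Generate surface dots on an atom's vdW sphere.

    ``density`` is in dots per square angstrom; the dot count is
    ``round(density * 4 pi r^2)`` with a minimum of one.  Per-dot areas are
    rescaled so they sum exactly to the sphere area.
    """
    if atom.radius is None:
        raise ValueError(f"atom {atom.serial} {atom.name} has no radius assigned")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    r = atom.radius
    sphere_area = 4.0 * math.pi * r * r
    n = max(1, round(density * sphere_area))
    cloud = fibonacci_points(n) if method == "fibos" else radial_points(n)
    return DotCloud(
        cloud.points * r + atom.coord,
        cloud.areas * sphere_area,
        method=cloud.method,
        center=atom.coord.copy(),
        radius=r,
    )
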