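"""Synthetic sphere-cluster fixtures and the brute-force occlusion oracle.

Every generator returns a valid :class:`~fibos.structure.Structure` labelled
with legal PDB residue/atom names (ALA/CA), so the whole stack — PDB round
trips, radius assignment, occlusion, metrics — can be exercised without any
external downloads.  Generation is deterministic given the seed.

``brute_force_occlusion`` re-implements the occlusion contract with plain
Python loops and no spatial index; it is the independent reference for
engine-equivalence tests and is guarded against large instances.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np

from .dots import DotCloud, dots_on_atom, fibonacci_points
from .occlusion import DEFAULT_WATER_DIAMETER, OcclusionRecord
from .structure import Atom, Structure

__all__ = [
    "FixtureSpec",
    "make_dimer",
    "make_shell",
    "make_lattice",
    "make_random_cluster",
    "make_chain",
    "PerturbedPair",
    "make_perturbed_pair",
    "brute_force_occlusion",
]

#: default vdW radius for fixture pseudo-atoms (carbon)
DEFAULT_RADIUS = 1.7


@dataclasses.dataclass
class FixtureSpec:
    """Provenance record for one generated fixture."""

    kind: str  # dimer | shell | lattice | random_cluster | perturbed_pair
    params: dict
    seed: int | None = None
    description: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _pseudo_atom(serial: int, res_seq: int, coord, r: float, chain: str = "A") -> Atom:
    return Atom(
        serial=serial,
        name="CA",
        element="C",
        res_name="ALA",
        chain_id=chain,
        res_seq=res_seq,
        coord=np.asarray(coord, dtype=float),
        radius=r,
    )


def make_dimer(r: float = DEFAULT_RADIUS, d: float = 3.4) -> Structure:
    """Two equal spheres on the z axis, ``d`` apart, as two ALA CA residues.

    ``d = 2r`` is vdW contact; ``d < 2r`` overlaps (the buried-dot fraction
    per atom is the spherical cap (1 - d/2r)/2); ``d > 2r + d_w`` is fully
    isolated at the default water diameter.
    """
    if d <= 0:
        raise ValueError(f"separation d must be positive, got {d}")
    s = Structure(
        [
            _pseudo_atom(1, 1, (0.0, 0.0, 0.0), r),
            _pseudo_atom(2, 2, (0.0, 0.0, d), r),
        ],
        id=f"dimer_r{r}_d{d}",
    )
    return s


def make_shell(
    r: float = DEFAULT_RADIUS,
    n_shell: int = 12,
    contact: bool = True,
    spacing: float | None = None,
) -> Structure:
    """A central atom surrounded by ``n_shell`` atoms on a Fibonacci shell.

    With ``contact`` the shell sits at center distance 2r (vdW contact),
    modelling a buried, well-packed atom; otherwise the shell is placed
    ``spacing`` away (default 10 A — far enough that nothing occludes at the
    default water diameter).
    """
    if n_shell < 4:
        raise ValueError(f"n_shell must be >= 4, got {n_shell}")
    dist = (2.0 * r) if contact else (10.0 if spacing is None else spacing)
    dirs = fibonacci_points(n_shell).points
    atoms = [_pseudo_atom(1, 1, (0.0, 0.0, 0.0), r)]
    for k, u in enumerate(dirs):
        atoms.append(_pseudo_atom(k + 2, k + 2, u * dist, r))
    return Structure(atoms, id=f"shell_{n_shell}_{'contact' if contact else 'spaced'}")


def make_lattice(
    shape: tuple[int, int, int] = (3, 3, 3),
    spacing: float = 3.6,
    r: float = DEFAULT_RADIUS,
) -> Structure:
    """Cubic lattice of equal spheres; interior atoms are the most packed."""
    atoms = []
    serial = 1
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                atoms.append(
                    _pseudo_atom(serial, serial, (i * spacing, j * spacing, k * spacing), r)
                )
                serial += 1
    return Structure(atoms, id=f"lattice_{shape[0]}x{shape[1]}x{shape[2]}")


def make_random_cluster(
    n: int = 20,
    box: float = 20.0,
    radius_range: tuple[float, float] = (1.4, 1.9),
    seed: int = 0,
) -> Structure:
    """``n`` spheres uniform in a cubic box with radii uniform in a range."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    radii = rng.uniform(radius_range[0], radius_range[1], size=n)
    atoms = [
        _pseudo_atom(i + 1, i + 1, coords[i], float(radii[i])) for i in range(n)
    ]
    return Structure(atoms, id=f"cluster_n{n}_seed{seed}")


_SIDE_CHAIN_NAMES = ("CB", "CG", "CD", "CE")


def make_chain(n_res: int = 40, r: float = DEFAULT_RADIUS, side_chains: bool = True) -> Structure:
    """A helical pseudo-peptide: CA trace plus stubby side chains.

    CA atoms follow the alpha-helix CA parameters (2.3 A helix radius,
    1.5 A rise, 100 degrees per residue, consecutive CAs ~3.8 A apart), so
    residues i and i+-1, i+-3, i+-4 pack against each other.  With
    ``side_chains`` each residue also carries 1-3 pseudo side-chain atoms
    (cycling with position) stepping 1.5 A radially outward from the helix
    axis; the varying side-chain length spreads the per-residue OSP the way
    buried/exposed residues do in a real protein.
    """
    if n_res < 1:
        raise ValueError(f"n_res must be >= 1, got {n_res}")
    atoms = []
    serial = 1
    for i in range(n_res):
        theta = math.radians(100.0) * i
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # outward direction
        ca = 2.3 * u + np.array([0.0, 0.0, 1.5 * i])
        atoms.append(_pseudo_atom(serial, i + 1, ca, r))
        serial += 1
        if side_chains:
            for k in range(1 + i % 3):
                pos = ca + (1.5 * (k + 1)) * u
                atom = _pseudo_atom(serial, i + 1, pos, r)
                atom.name = _SIDE_CHAIN_NAMES[k]
                atoms.append(atom)
                serial += 1
    return Structure(atoms, id=f"chain_{n_res}")


def make_micelle(n_res: int = 72, spacing: float = 4.0, tip_dist: float = 3.5) -> Structure:
    """A closed spherical shell of two-atom "dumbbell" residues.

    Residue sites lie on a Fibonacci lattice scaled so nearest sites are
    ``spacing`` apart; each residue is a CA sphere plus a side-chain tip
    (alternating CYS SG, r = 1.80 A, and SER OG, r = 1.52 A) at near-contact
    distance ``tip_dist`` along the outward radial, so the tip's occlusion
    is dominated by its own CA.  The closed surface gives every residue an
    equivalent environment and the S/O alternation two clean packing
    classes — the controlled background for paired-comparison studies, where
    a displaced tip must stand out against a calibrated dispersion.
    """
    if n_res < 4:
        raise ValueError(f"n_res must be >= 4, got {n_res}")
    dirs = fibonacci_points(n_res).points
    gc = np.arccos(np.clip(dirs @ dirs.T, -1.0, 1.0))
    np.fill_diagonal(gc, np.inf)
    shell_r = spacing / gc.min(axis=1).mean()
    atoms: list[Atom] = []
    serial = 1
    for i, u in enumerate(dirs):
        if i % 2 == 0:
            res_name, tip_name, tip_elem, tip_r = "CYS", "SG", "S", 1.80
        else:
            res_name, tip_name, tip_elem, tip_r = "SER", "OG", "O", 1.52
        ca = shell_r * u
        atoms.append(
            Atom(serial, "CA", "C", res_name, "A", i + 1, coord=ca, radius=1.7)
        )
        atoms.append(
            Atom(
                serial + 1,
                tip_name,
                tip_elem,
                res_name,
                "A",
                i + 1,
                coord=ca + tip_dist * u,
                radius=tip_r,
            )
        )
        serial += 2
    return Structure(atoms, id=f"micelle_{n_res}")


@dataclasses.dataclass
class PerturbedPair:
    """Conformer pair: the pristine copy, the perturbed copy, and which
    residues carry a planted outlier displacement."""

    a: Structure
    b: Structure
    planted: list[tuple[str, int, str, str]]  # residue keys of displaced atoms

    def __iter__(self):
        return iter((self.a, self.b))


#: background jitter (A) used for no-outlier null calibration runs
NULL_SIGMA = 0.02


def make_perturbed_pair(
    base: Structure,
    sigma: float = 0.0,
    n_outliers: int = 0,
    outlier_shift: float = 6.0,
    seed: int = 0,
) -> PerturbedPair:
    """Emulate a conformer pair of the same chain with controlled divergence.

    Copy A is the base; copy B gets isotropic Gaussian coordinate jitter of
    scale ``sigma`` plus ``n_outliers`` randomly chosen side-chain-like
    atoms (the terminal atom of a residue) displaced ``outlier_shift``
    (default 6 A, a side-chain-scale misplacement) away from the structure
    centroid — the "side chain extends away from its cluster" event.  With
    the defaults (sigma 0, no outliers) B is an exact copy.  Deterministic
    given ``seed``.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    a = base.copy()
    b = base.copy()
    n = len(b)
    centroid = base.coords().mean(axis=0) if n else np.zeros(3)
    if sigma > 0 and n:
        jitter = rng.normal(0.0, sigma, size=(n, 3))
        for atom, dx in zip(b.atoms, jitter):
            atom.coord = atom.coord + dx
    planted: list[tuple[str, int, str, str]] = []
    if n_outliers > 0:
        # the last atom of a residue is its most distal, side-chain-like one
        candidates = [res[-1] for res in b.residues().values()]
        picks = rng.choice(
            len(candidates), size=min(n_outliers, len(candidates)), replace=False
        )
        for i in picks:
            atom = candidates[i]
            u = atom.coord - centroid
            nrm = np.linalg.norm(u)
            if nrm < 1e-9:  # atom at the centroid: any direction will do
                u = rng.normal(size=3)
                nrm = np.linalg.norm(u)
            u = u / nrm
            atom.coord = atom.coord + outlier_shift * u
            planted.append(atom.residue_key)
    a.id = f"{base.id}_A"
    b.id = f"{base.id}_B"
    return PerturbedPair(a, b, planted)


def brute_force_occlusion(
    s: Structure,
    density: float = 5.0,
    method: str = "fibos",
    d_w: float = DEFAULT_WATER_DIAMETER,
    dot_clouds: Sequence[DotCloud] | None = None,
    max_atoms: int = 50,
) -> list[OcclusionRecord]:
    """Reference occlusion: exhaustive all-atom checks, plain Python loops.

    Same contract as :func:`fibos.occlusion.compute_occlusion` but with no
    spatial index and no vectorised ray casting — the independent oracle for
    equivalence tests.  Refuses instances above ``max_atoms`` to guard
    against the quadratic blow-up.
    """
    if len(s) > max_atoms:
        raise ValueError(
            f"brute-force oracle limited to {max_atoms} atoms, got {len(s)}"
        )
    records: list[OcclusionRecord] = []
    atoms = s.atoms
    for i, atom in enumerate(atoms):
        cloud = dot_clouds[i] if dot_clouds is not None else dots_on_atom(
            atom, density=density, method=method
        )
        others = [a for j, a in enumerate(atoms) if j != i]
        for k in range(cloud.n_dots):
            px, py, pz = cloud.points[k]
            # burial check against every other atom
            buried = False
            for nb in others:
                mx, my, mz = px - nb.coord[0], py - nb.coord[1], pz - nb.coord[2]
                if mx * mx + my * my + mz * mz < nb.radius * nb.radius:
                    buried = True
                    break
            if buried:
                continue
            dx, dy, dz = px - atom.coord[0], py - atom.coord[1], pz - atom.coord[2]
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx, dy, dz = dx / dn, dy / dn, dz / dn
            best_t = math.inf
            best: Atom | None = None
            for nb in others:
                mx, my, mz = px - nb.coord[0], py - nb.coord[1], pz - nb.coord[2]
                b = dx * mx + dy * my + dz * mz
                c = mx * mx + my * my + mz * mz - nb.radius * nb.radius
                disc = b * b - c
                if disc < 0:
                    continue
                sq = math.sqrt(disc)
                t1 = -b - sq
                t2 = -b + sq
                if t1 > 0.0:
                    t = t1
                elif t2 > 0.0:
                    t = 0.0
                else:
                    continue
                if t < best_t:
                    best_t = t
                    best = nb
            hit = best_t <= d_w
            records.append(
                OcclusionRecord(
                    atom_serial=atom.serial,
                    dot_index=k,
                    dot_area=float(cloud.areas[k]),
                    x=float(px),
                    y=float(py),
                    z=float(pz),
                    occluded=hit,
                    length=float(best_t) if hit else math.nan,
                    occluder_serial=best.serial if hit else None,
                )
            )
    return records
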