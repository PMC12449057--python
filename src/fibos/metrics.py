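"""Packing metrics: occluded surface areas, normal lengths, and OSP.

The occluded surface packing density (OSP) of an atom combines the two raw
occlusion observables — how much of the surface is occluded and how short
the normals are — into a single dimensionless density in [0, 1]:

    OSP = sum over occluded dots of  area_d * (1 - L_d / d_w)
          -------------------------------------------------
               sum over all retained dots of  area_d

An isolated atom has OSP 0; a perfectly enclosed atom whose normals all have
zero length has OSP 1.  Residue OSP is the unweighted mean over the
residue's atoms (an area-weighted variant is available), and a structure is
summarised by the mean and sample standard deviation of its residue OSPs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dots import METHODS
from .occlusion import (
    DEFAULT_WATER_DIAMETER,
    OcclusionRecord,
    compute_occlusion,
    records_to_frame,
)
from .structure import RadiiTable, Structure, assign_radii, read_pdb

__all__ = [
    "AtomPacking",
    "ResiduePacking",
    "StructureSummary",
    "atom_packing",
    "residue_table",
    "structure_summary",
    "PackingResult",
    "compute_packing",
]


@dataclasses.dataclass
class AtomPacking:
    """Aggregated occlusion of one atom."""

    atom_serial: int
    exposed_area: float  # A^2, sum of retained dot areas
    occluded_area: float  # A^2, sum of occluded dot areas
    mean_length: float  # A, area-weighted mean normal length (0 when none occluded)
    osp: float  # dimensionless, in [0, 1]
    n_dots: int
    n_occluded: int


@dataclasses.dataclass
class ResiduePacking:
    """Aggregated occlusion of one residue."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    n_atoms: int
    occluded_area: float
    mean_length: float
    osp: float

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.icode, self.res_name)


@dataclasses.dataclass
class StructureSummary:
    """Per-structure OSP summary over residues."""

    structure_id: str
    n_residues: int
    mean_osp: float
    sd_osp: float  # sample SD (n-1); defined as 0 for a single residue


def atom_packing(
    records: Sequence[OcclusionRecord], d_w: float = DEFAULT_WATER_DIAMETER
) -> AtomPacking:
    """Reduce one atom's occlusion records to areas, mean length, and OSP.

    An empty record list (an atom whose whole surface was buried) yields a
    zero-area packing with OSP 0.
    """
    if d_w <= 0:
        raise ValueError(f"d_w must be positive, got {d_w}")
    if not records:
        return AtomPacking(-1, 0.0, 0.0, 0.0, 0.0, 0, 0)
    serials = {r.atom_serial for r in records}
    if len(serials) != 1:
        raise ValueError(f"records span multiple atoms: {sorted(serials)}")
    areas = np.array([r.dot_area for r in records])
    occ = np.array([r.occluded for r in records], dtype=bool)
    lengths = np.array([r.length if r.occluded else 0.0 for r in records])
    exposed = float(areas.sum())
    occ_area = float(areas[occ].sum())
    if occ.any():
        w = areas[occ]
        mean_len = float((w * lengths[occ]).sum() / w.sum())
        osp = float((w * (1.0 - lengths[occ] / d_w)).sum() / exposed)
    else:
        mean_len = 0.0
        osp = 0.0
    return AtomPacking(
        atom_serial=records[0].atom_serial,
        exposed_area=exposed,
        occluded_area=occ_area,
        mean_length=mean_len,
        osp=osp,
        n_dots=len(records),
        n_occluded=int(occ.sum()),
    )


def _group_records(records: Sequence[OcclusionRecord]) -> dict[int, list[OcclusionRecord]]:
    grouped: dict[int, list[OcclusionRecord]] = {}
    for r in records:
        grouped.setdefault(r.atom_serial, []).append(r)
    return grouped


def residue_table(
    s: Structure,
    packings: Mapping[int, AtomPacking],
    area_weighted: bool = False,
) -> list[ResiduePacking]:
    """Aggregate atom packings per residue, in structure order.

    Residue OSP is the unweighted mean of member-atom OSPs by default;
    ``area_weighted`` weights each atom by its exposed dot area instead.
    """
    rows: list[ResiduePacking] = []
    for key, atoms in s.residues().items():
        osps, weights, occ_area, len_num, len_den = [], [], 0.0, 0.0, 0.0
        for a in atoms:
            p = packings.get(a.serial)
            if p is None:
                raise ValueError(
                    f"atom serial={a.serial} {a.res_name}{a.res_seq}/{a.name} "
                    "has no AtomPacking"
                )
            osps.append(p.osp)
            weights.append(p.exposed_area)
            occ_area += p.occluded_area
            len_num += p.mean_length * p.occluded_area
            len_den += p.occluded_area
        if area_weighted and sum(weights) > 0:
            osp = float(np.average(osps, weights=weights))
        else:
            osp = float(np.mean(osps))
        rows.append(
            ResiduePacking(
                chain_id=key[0],
                res_seq=key[1],
                icode=key[2],
                res_name=key[3],
                n_atoms=len(atoms),
                occluded_area=occ_area,
                mean_length=(len_num / len_den) if len_den > 0 else 0.0,
                osp=osp,
            )
        )
    return rows


def structure_summary(
    rows: Sequence[ResiduePacking], structure_id: str = ""
) -> StructureSummary:
    """Mean and sample SD (n-1) of residue OSP; sd is 0 for a single residue."""
    if not rows:
        raise ValueError("structure_summary requires at least one residue")
    osps = np.array([r.osp for r in rows])
    sd = float(osps.std(ddof=1)) if len(osps) > 1 else 0.0
    return StructureSummary(
        structure_id=structure_id,
        n_residues=len(rows),
        mean_osp=float(osps.mean()),
        sd_osp=sd,
    )


@dataclasses.dataclass
class PackingResult:
    """Everything one packing run produces, with table exporters."""

    structure: Structure
    method: str
    density: float
    d_w: float
    records: list[OcclusionRecord]
    atom_packings: dict[int, AtomPacking]
    residues: list[ResiduePacking]
    summary: StructureSummary

    def normals_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records, self.structure)

    def residue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": r.chain_id,
                    "res_seq": r.res_seq,
                    "res_name": r.res_name,
                    "n_atoms": r.n_atoms,
                    "occluded_area": r.occluded_area,
                    "mean_length": r.mean_length,
                    "osp": r.osp,
                }
                for r in self.residues
            ]
        )

    def summary_frame(self) -> pd.DataFrame:
        s = self.summary
        return pd.DataFrame(
            [
                {
                    "id": s.structure_id,
                    "n_res": s.n_residues,
                    "mean_osp": s.mean_osp,
                    "sd_osp": s.sd_osp,
                }
            ]
        )


def compute_packing(
    structure: Structure | str | Path,
    method: str = "fibos",
    density: float = 5.0,
    d_w: float = DEFAULT_WATER_DIAMETER,
    radii_table: RadiiTable | None = None,
    area_weighted_residues: bool = False,
    include_hetero: bool = False,
    keep_hydrogens: bool = False,
) -> PackingResult:
    """One-call packing pipeline: dots, occlusion, atom/residue/structure OSP.

    ``structure`` may be a :class:`Structure` (radii are assigned if any are
    missing) or a path to a PDB file.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if isinstance(structure, (str, Path)):
        structure = read_pdb(
            structure, include_hetero=include_hetero, keep_hydrogens=keep_hydrogens
        )
    if any(a.radius is None for a in structure):
        assign_radii(structure, radii_table)
    records = compute_occlusion(structure, density=density, method=method, d_w=d_w)
    grouped = _group_records(records)
    packings: dict[int, AtomPacking] = {}
    for a in structure:
        recs = grouped.get(a.serial, [])
        p = atom_packing(recs, d_w=d_w)
        p.atom_serial = a.serial
        packings[a.serial] = p
    residues = residue_table(structure, packings, area_weighted=area_weighted_residues)
    summary = structure_summary(residues, structure_id=structure.id)
    return PackingResult(
        structure=structure,
        method=method,
        density=density,
        d_w=d_w,
        records=records,
        atom_packings=packings,
        residues=residues,
        summary=summary,
    )
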