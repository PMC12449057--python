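"""Structure model: PDB reading/writing and van der Waals radius assignment.

The internal model is deliberately flat — a :class:`Structure` is an ordered
list of :class:`Atom` records grouped into residues on demand.  Only the
fixed-column PDB format is supported (mmCIF is out of scope); parsing and
serialisation are delegated to :mod:`gemmi`, with alternate-location
resolution (highest occupancy, ties broken by file order) layered on top.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "RadiiTable",
    "PDBParseError",
    "RadiusAssignmentError",
    "read_pdb",
    "write_pdb",
    "assign_radii",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class RadiusAssignmentError(KeyError):
    """Raised when no radius can be found for an atom."""


@dataclasses.dataclass
class Atom:
    """One coordinate record with residue identity and an assigned vdW radius.

    ``radius`` is ``None`` until :func:`assign_radii` runs; a zero sentinel is
    never used so an unset radius cannot silently act as a point sphere.
    """

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str = ""
    alt_loc: str = ""
    occupancy: float = 1.0
    coord: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(3))
    radius: float | None = None
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"coord must be a 3-vector, got shape {self.coord.shape}")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        """(chain_id, res_seq, icode, res_name) — the residue identity."""
        return (self.chain_id, self.res_seq, self.icode, self.res_name)

    def copy(self) -> "Atom":
        return dataclasses.replace(self, coord=self.coord.copy())


class Structure:
    """An ordered collection of atoms from one coordinate file."""

    def __init__(self, atoms: Iterable[Atom] = (), id: str = "") -> None:
        self.atoms: list[Atom] = list(atoms)
        self.id = id

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in file order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        """(n,) array of assigned radii; raises if any atom is unassigned."""
        vals = []
        for a in self.atoms:
            if a.radius is None:
                raise RadiusAssignmentError(
                    f"atom {a.serial} {a.res_name} {a.name} has no radius assigned"
                )
            vals.append(a.radius)
        return np.array(vals, dtype=float)

    def residues(self) -> dict[tuple[str, int, str, str], list[Atom]]:
        """Group atoms by residue, preserving first-appearance order.

        The grouping partitions the atom set: every atom appears in exactly
        one residue bucket.
        """
        groups: dict[tuple[str, int, str, str], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups

    def copy(self) -> "Structure":
        return Structure((a.copy() for a in self.atoms), id=self.id)


class RadiiTable:
    """Van der Waals radii: (res_name, atom_name) overrides + element fallback.

    The plain-text config format has one entry per line, ``ELEMENT RADIUS`` or
    ``RES:ATOM RADIUS``, with ``#`` comments.
    """

    #: elements any usable fallback table must cover
    REQUIRED_ELEMENTS = ("C", "N", "O", "S", "H", "P")

    def __init__(
        self,
        by_element: Mapping[str, float],
        by_atom: Mapping[tuple[str, str], float] | None = None,
        source: str = "custom",
    ) -> None:
        self.by_element = {k.upper(): float(v) for k, v in by_element.items()}
        self.by_atom = {
            (r.upper(), a.upper()): float(v) for (r, a), v in (by_atom or {}).items()
        }
        self.source = source
        for key, r in list(self.by_element.items()) + [
            (f"{r}:{a}", v) for (r, a), v in self.by_atom.items()
        ]:
            if not (0.5 < r < 3.0):
                raise ValueError(f"radius for {key} out of range (0.5, 3.0): {r}")
        missing = [e for e in self.REQUIRED_ELEMENTS if e not in self.by_element]
        if missing:
            raise ValueError(f"fallback table missing required elements: {missing}")

    def lookup(self, res_name: str, atom_name: str, element: str = "") -> float | None:
        """Radius for an atom, or None when neither lookup path matches."""
        r = self.by_atom.get((res_name.upper(), atom_name.upper()))
        if r is not None:
            return r
        if element:
            r = self.by_element.get(element.upper())
            if r is not None:
                return r
        return self._guess_from_name(atom_name)

    def _guess_from_name(self, atom_name: str) -> float | None:
        # PDB atom names encode the element in their leading letters
        letters = "".join(ch for ch in atom_name if ch.isalpha()).upper()
        if len(letters) >= 2 and letters[:2] in self.by_element:
            return self.by_element[letters[:2]]
        if letters and letters[0] in self.by_element:
            return self.by_element[letters[0]]
        return None

    @classmethod
    def from_file(cls, path: str | Path, source: str | None = None) -> "RadiiTable":
        by_element: dict[str, float] = {}
        by_atom: dict[tuple[str, str], float] = {}
        path = Path(path)
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'KEY RADIUS', got {raw!r}")
            key, val = parts
            try:
                radius = float(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad radius {val!r}") from exc
            if ":" in key:
                res, atom = key.split(":", 1)
                by_atom[(res, atom)] = radius
            else:
                by_element[key] = radius
        return cls(by_element, by_atom, source=source or str(path))

    @classmethod
    def default(cls) -> "RadiiTable":
        """The bundled protein vdW table (Bondi-style values)."""
        ref = importlib.resources.files("fibos.data") / "radii.txt"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path, source="bundled radii.txt")


def read_pdb(
    path: str | Path,
    include_hetero: bool = False,
    keep_hydrogens: bool = False,
) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Waters are always treated as hetero.  Alternate locations are resolved to
    the highest-occupancy conformer (ties: first in file).  Radii are left
    unset; call :func:`assign_radii` before any packing computation.
    """
    path = Path(path)
    if not path.is_file():
        raise PDBParseError(f"cannot read PDB file: {path}")
    # gemmi tolerates garbage in the coordinate fields; validate them first
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated coordinate record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}:{lineno}: malformed coordinate columns {lo + 1}-{hi}"
                    ) from None
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        # gemmi reports the offending line in its message
        raise PDBParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for res in chain:
                hetero = res.het_flag == "H" or res.is_water()
                if hetero and not include_hetero:
                    continue
                for at in res:
                    if at.is_hydrogen() and not keep_hydrogens:
                        continue
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=at.element.name if at.element.name != "X" else "",
                            res_name=res.name,
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            icode=res.seqid.icode.strip(),
                            alt_loc=at.altloc if at.has_altloc() else "",
                            occupancy=at.occ,
                            coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            is_hetero=hetero,
                        )
                    )
    return Structure(_resolve_altlocs(atoms), id=path.stem)


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per (residue, atom name): highest occupancy, tie -> first."""
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.residue_key, a.name)
        j = best.get(key)
        if j is None or a.occupancy > atoms[j].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [atoms[i] for i in keep]


def assign_radii(s: Structure, table: RadiiTable | None = None) -> Structure:
    """Assign a vdW radius to every atom in place; returns the structure.

    Lookup order: (res_name, atom_name) override, element fallback, then an
    element guess from the atom name.  An atom with no match raises
    :class:`RadiusAssignmentError` naming the offender.
    """
    if table is None:
        table = RadiiTable.default()
    for a in s.atoms:
        r = table.lookup(a.res_name, a.name, a.element)
        if r is None:
            raise RadiusAssignmentError(
                f"no vdW radius for atom serial={a.serial} "
                f"{a.chain_id}/{a.res_name}{a.res_seq}/{a.name} element={a.element!r}"
            )
        a.radius = r
    return s


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Write fixed-column PDB ATOM/HETATM records.

    Coordinates survive a read/write round trip to the PDB's 3-decimal
    precision; identities survive exactly.
    """
    path = Path(path)
    if not s.atoms:
        path.write_text("END\n")
        return path

    # group in file order: chain -> residue -> atoms (gemmi copies on add_*,
    # so build each object completely before inserting it)
    chain_order: list[str] = []
    per_chain: dict[str, dict[tuple, list[Atom]]] = {}
    for a in s.atoms:
        if a.chain_id not in per_chain:
            per_chain[a.chain_id] = {}
            chain_order.append(a.chain_id)
        per_chain[a.chain_id].setdefault(a.residue_key, []).append(a)

    st = gemmi.Structure()
    st.name = s.id or "fibos"
    model = gemmi.Model("1")
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for rkey, ratoms in per_chain[cid].items():
            res = gemmi.Residue()
            res.name = ratoms[0].res_name
            res.seqid = gemmi.SeqId(ratoms[0].res_seq, ratoms[0].icode or " ")
            res.het_flag = "H" if ratoms[0].is_hetero else "A"
            for a in ratoms:
                at = gemmi.Atom()
                at.name = a.name
                at.pos = gemmi.Position(*a.coord)
                at.occ = a.occupancy
                at.serial = a.serial
                if a.element:
                    at.element = gemmi.Element(a.element)
                if a.alt_loc:
                    at.altloc = a.alt_loc
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_minimal_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write PDB file {path}: {exc}") from exc
    return path
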