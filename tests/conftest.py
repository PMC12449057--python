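import numpy as np
import pytest

from fibos.fixtures import make_dimer, make_micelle, make_shell
from fibos.structure import Atom, Structure


@pytest.fixture(scope="session")
def contact_dimer():
    """Two carbon-like spheres at vdW contact (d = 2r = 3.4 A)."""
    return make_dimer(r=1.7, d=3.4)


@pytest.fixture(scope="session")
def shell12():
    """A buried central atom: 12-atom first coordination shell at contact."""
    return make_shell(r=1.7, n_shell=12, contact=True)


@pytest.fixture(scope="session")
def micelle():
    """The closed two-class dumbbell shell used for comparison studies."""
    return make_micelle()


@pytest.fixture()
def toy_structure():
    """Three residues, five atoms, mixed elements, radii unset."""
    return Structure(
        [
            Atom(1, "N", "N", "ALA", "A", 1, coord=[0.0, 0.0, 0.0]),
            Atom(2, "CA", "C", "ALA", "A", 1, coord=[1.5, 0.0, 0.0]),
            Atom(3, "CA", "C", "GLY", "A", 2, coord=[0.0, 3.8, 0.0]),
            Atom(4, "CA", "C", "SER", "A", 3, coord=[3.8, 3.8, 0.0]),
            Atom(5, "OG", "O", "SER", "A", 3, coord=[5.0, 4.5, 0.5]),
        ],
        id="toy",
    )


def pdb_text(lines):
    """Join PDB records with a terminating END line."""
    return "\n".join(list(lines) + ["END"]) + "\n"


def atom_line(serial, name, res_name, chain, res_seq, x, y, z,
              occ=1.0, element="C", alt_loc=" ", record="ATOM  "):
    """One fixed-column PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:>5d} {name_field}{alt_loc}{res_name:>3s} {chain}"
        f"{res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture()
def write_text(tmp_path):
    def _write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


def records_key(records):
    """Canonical comparison form of occlusion records (lengths rounded)."""
    return [
        (
            r.atom_serial,
            r.dot_index,
            r.occluded,
            r.occluder_serial,
            round(r.length, 9) if r.occluded else None,
        )
        for r in records
    ]


def nn_spacing_cv(points):
    """Coefficient of variation of nearest-neighbour great-circle spacing."""
    d = np.arccos(np.clip(points @ points.T, -1.0, 1.0))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    return nn.std() / nn.mean()
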