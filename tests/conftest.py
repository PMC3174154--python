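import numpy as np
import pytest

from xtalassoc.model import Atom, StructureModel, UnitCell


def make_atom(serial, name, element, resname, resnum, chain, pos, hetero=False, **kw):
    return Atom(
        serial=serial, name=name, element=element, alt_loc=kw.get("alt_loc", ""),
        residue_name=resname, residue_number=resnum,
        insertion_code=kw.get("insertion_code", ""), chain_id=chain,
        position=np.asarray(pos, dtype=float),
        occupancy=kw.get("occupancy", 1.0), b_factor=kw.get("b_factor", 0.0),
        is_hetero=hetero,
    )


@pytest.fixture
def toy_model():
    """Three-atom, one-chain model with a cell (round-trip fixture)."""
    atoms = [
        make_atom(1, "N", "N", "ALA", 1, "A", [0.123, 1.456, -2.789]),
        make_atom(2, "CA", "C", "ALA", 1, "A", [1.0, 2.0, 3.0]),
        make_atom(3, "C", "C", "ALA", 1, "A", [-4.5, 0.25, 7.125]),
    ]
    return StructureModel(atoms, cell=UnitCell(20, 30, 40), spacegroup_hm="P 1",
                          title="toy")


@pytest.fixture
def five_residue_chain():
    """Backbone-only 5-residue chain (4 atoms per residue)."""
    atoms = []
    serial = 1
    for i in range(5):
        base = np.array([3.8 * i, 0.0, 0.0])
        for name, elem, off in (("N", "N", [0, 0, 0]), ("CA", "C", [1.2, 0.8, 0]),
                                ("C", "C", [2.4, 0, 0]), ("O", "O", [2.4, -1.2, 0])):
            atoms.append(make_atom(serial, name, elem, "GLY", i + 1, "A",
                                   base + np.array(off)))
            serial += 1
    return StructureModel(atoms)
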