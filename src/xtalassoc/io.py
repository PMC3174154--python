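"""PDB reading and writing.

Parsing is delegated to gemmi; its hierarchy is flattened into the package's
:class:`~xtalassoc.model.StructureModel`.  Writing emits the fixed-column
subset actually consumed here (CRYST1/ATOM/HETATM/TER/END), with coordinates
at three decimals, so read -> write -> read is a fixed point on field values.
"""
from __future__ import annotations

import os
import warnings
from pathlib import Path

import gemmi

from .model import Atom, StructureModel, UnitCell

__all__ = ["read_pdb", "write_pdb", "PdbFormatWarning"]


class PdbFormatWarning(UserWarning):
    pass


def _cell_from_gemmi(st: gemmi.Structure) -> tuple[UnitCell | None, str | None]:
    cell = st.cell
    if not cell.is_crystal():
        return None, None
    try:
        uc = UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    except ValueError as exc:
        warnings.warn(f"malformed CRYST1 ignored: {exc}", PdbFormatWarning, stacklevel=3)
        return None, None
    hm = st.spacegroup_hm or None
    return uc, hm


def read_pdb(path: str | os.PathLike, altloc_policy: str = "first") -> StructureModel:
    """Read a PDB file into a StructureModel.

    altloc_policy
        ``"first"`` keeps blank and ``"A"`` conformers only (the analyses
        downstream assume a single conformer); ``"all"`` keeps every record.
    """
    if altloc_policy not in ("first", "all"):
        raise ValueError(f"unknown altloc_policy {altloc_policy!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(str(path))
    cell, hm = _cell_from_gemmi(st)

    atoms: list[Atom] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                het = res.het_flag == "H"
                for ga in res:
                    alt = ga.altloc if ga.altloc not in ("\0", " ") else ""
                    if altloc_policy == "first" and alt not in ("", "A"):
                        continue
                    atoms.append(
                        Atom(
                            serial=ga.serial,
                            name=ga.name,
                            element=ga.element.name.upper() or "X",
                            alt_loc=alt,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            insertion_code=(res.seqid.icode or "").strip(),
                            chain_id=chain.name,
                            position=[ga.pos.x, ga.pos.y, ga.pos.z],
                            occupancy=min(max(ga.occ, 0.0), 1.0),
                            b_factor=ga.b_iso,
                            is_hetero=het,
                        )
                    )
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return StructureModel(atoms, cell=cell, spacegroup_hm=hm, title=st.name)


def _format_atom_name(name: str, element: str) -> str:
    # Column 13 is reserved for two-letter element symbols; single-letter
    # elements with short names are indented one space.
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(model: StructureModel, path: str | os.PathLike) -> None:
    """Write the model in fixed-column PDB format (wwPDB v3.3 subset)."""
    path = Path(path)
    lines: list[str] = []
    if model.title:
        lines.append(f"TITLE     {model.title[:70]}")
    if model.cell is not None:
        c = model.cell
        sg = model.spacegroup_hm or "P 1"
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {sg:<11s}{1:4d}"
        )
    serial = 0
    prev_chain: str | None = None
    for a in model.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        rec = "HETATM" if a.is_hetero else "ATOM  "
        x, y, z = a.position
        lines.append(
            f"{rec}{serial % 100000:5d} {_format_atom_name(a.name, a.element)}"
            f"{a.alt_loc or ' ':1s}{a.residue_name:>3s} {a.chain_id[:1]:1s}"
            f"{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
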