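"""Published metadata of the ICA512 mature-ectodomain crystal forms.

These are the deposited crystal forms of the human ICA512 (PTPRN, IA-2)
mature ectodomain fragment (UniProt Q16849).  The table records, per form:
the PDB accession, crystallization pH, space group, unit-cell parameters,
molecules per asymmetric unit, and the published Matthews coefficient
(A^3/Da) and solvent content (%).  It serves as input for cell-content
arithmetic and consistency checks; the coordinates themselves are not
bundled and must be supplied by the user for coordinate-level analyses.
"""
from __future__ import annotations

from dataclasses import dataclass

from .model import UnitCell

__all__ = ["CrystalForm", "CRYSTAL_FORMS"]


@dataclass(frozen=True)
class CrystalForm:
    pdb_id: str
    variant: str
    ph: float
    spacegroup_hm: str
    cell: UnitCell
    z_asu: int
    v_m_published: float  # A^3/Da
    solvent_percent_published: float


CRYSTAL_FORMS: tuple[CrystalForm, ...] = (
    CrystalForm("3N4W", "S508A", 7.5, "P 21 21 21",
                UnitCell(31.47, 66.02, 73.60), 2, 2.02, 39.2),
    CrystalForm("3NG8", "S508A", 8.5, "P 21 21 21",
                UnitCell(31.55, 66.54, 73.71), 2, 2.05, 39.9),
    CrystalForm("3N01", "wild type", 8.5, "P 21 21 21",
                UnitCell(31.49, 66.68, 73.00), 2, 2.03, 39.3),
    CrystalForm("3NP5", "wild type", 4.5, "P 41",
                UnitCell(44.66, 44.66, 168.67), 4, 2.22, 44.7),
)
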