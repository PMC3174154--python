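"""Core coordinate model: atoms, chains, unit cell.

The model is a flat, ordered atom list annotated with crystallographic
metadata.  Residues are addressed exclusively by author numbering plus
insertion code; no renumbering is ever applied, so residue identifiers
printed in reports match the deposited coordinates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "UnitCell",
    "StructureModel",
    "ResidueKey",
    "select_atoms",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: (chain_id, residue_number, insertion_code)
ResidueKey = tuple[str, int, str]


@dataclass(slots=True)
class Atom:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: np.ndarray  # Cartesian, Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial} {self.name}: bad position")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_water(self) -> bool:
        return self.residue_name in ("HOH", "WAT", "DOD")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "Atom":
        a = replace(self)
        a.position = self.position.copy()
        return a


@dataclass(frozen=True, slots=True)
class UnitCell:
    """Crystallographic cell, lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise ValueError("degenerate cell (volume <= 0)")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (PDB convention: a along x, b in xy)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix)


class StructureModel:
    """Ordered atom collection with optional cell and space-group symbol.

    Chain ids are free-form strings internally (symmetry-mate copies use
    suffixed ids like ``"A*1"``); only single-character ids survive a PDB
    round trip.
    """

    def __init__(
        self,
        atoms: Iterable[Atom],
        cell: UnitCell | None = None,
        spacegroup_hm: str | None = None,
        title: str = "",
    ) -> None:
        self.atoms: list[Atom] = list(atoms)
        self.cell = cell
        self.spacegroup_hm = spacegroup_hm
        self.title = title

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.position for a in self.atoms])

    def residues(self, chain_id: str | None = None) -> list[ResidueKey]:
        """Distinct residue keys in atom order, optionally for one chain."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            if chain_id is None or a.chain_id == chain_id:
                seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_name(self, key: ResidueKey) -> str:
        for a in self.atoms:
            if a.residue_key == key:
                return a.residue_name
        raise KeyError(key)

    def atoms_of(self, key: ResidueKey) -> list[Atom]:
        return [a for a in self.atoms if a.residue_key == key]

    def copy(self) -> "StructureModel":
        return StructureModel(
            (a.copy() for a in self.atoms),
            cell=self.cell,
            spacegroup_hm=self.spacegroup_hm,
            title=self.title,
        )

    def validate(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            k = (a.chain_id, a.residue_number, a.insertion_code, a.name, a.alt_loc)
            if k in seen:
                raise ValueError(f"duplicate atom identity {k}")
            seen.add(k)


def select_atoms(
    model: StructureModel,
    chain_ids: Sequence[str] | set[str] | None = None,
    name_filter: Iterable[str] | None = None,
    hetero: str = "include",
) -> StructureModel:
    """Filter a model by chain, atom name, and hetero status.

    ``hetero`` is one of ``include`` (keep everything), ``exclude`` (drop
    HETATM records) or ``only``.  Order is preserved; the input model is
    untouched.
    """
    if hetero not in ("include", "exclude", "only"):
        raise ValueError(f"unknown hetero policy {hetero!r}")
    if chain_ids is not None:
        chain_ids = set(chain_ids)
        if not chain_ids:
            raise ValueError("empty chain selection")
        unknown = chain_ids - set(model.chain_ids)
        if unknown:
            raise KeyError(f"chains not in model: {sorted(unknown)}")
    names = set(name_filter) if name_filter is not None else None
    picked = []
    for a in model.atoms:
        if chain_ids is not None and a.chain_id not in chain_ids:
            continue
        if names is not None and a.name not in names:
            continue
        if hetero == "exclude" and a.is_hetero:
            continue
        if hetero == "only" and not a.is_hetero:
            continue
        picked.append(a.copy())
    return StructureModel(picked, cell=model.cell, spacegroup_hm=model.spacegroup_hm, title=model.title)
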