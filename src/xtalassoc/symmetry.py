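"""Space-group operators, fractional/Cartesian conversion, lattice neighbours.

Operator tables come from gemmi's space-group database keyed on the
Hermann-Mauguin symbol; the crystals analysed here use P 1, P 21 21 21 and
P 41, but any symbol gemmi resolves (or an explicit triplet list) works.
Neighbour expansion applies every non-identity (operator, lattice shift)
combination within a shift window and reports chain pairs with at least one
atom pair inside the distance cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel, UnitCell

__all__ = [
    "SymmetryOperator",
    "SpaceGroupSpec",
    "ContactMate",
    "operators_for",
    "spacegroup_spec",
    "frac_to_cart",
    "cart_to_frac",
    "expand_neighbors",
    "apply_operator",
]


@dataclass(frozen=True)
class SymmetryOperator:
    """Rotation (integer matrix, fractional basis) + fractional translation.

    ``lattice_shift`` is the integer cell translation applied on top of the
    group operation when generating a neighbour copy.
    """

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # 3 floats, fractions of cell edges
    lattice_shift: tuple = (0, 0, 0)

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def tran(self) -> np.ndarray:
        return np.array(self.translation, dtype=float) + np.array(self.lattice_shift, dtype=float)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.rot.T + self.tran

    def is_identity(self) -> bool:
        return (
            np.array_equal(self.rot, np.eye(3))
            and np.allclose(np.array(self.translation), 0)
            and self.lattice_shift == (0, 0, 0)
        )

    def with_shift(self, shift: tuple[int, int, int]) -> "SymmetryOperator":
        return SymmetryOperator(self.rotation, self.translation, tuple(int(s) for s in shift))

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self o other (apply ``other`` first)."""
        r = self.rot @ other.rot
        t = self.rot @ other.tran + self.tran
        return SymmetryOperator(_int_matrix(r), tuple(t), (0, 0, 0))

    def inverse(self) -> "SymmetryOperator":
        rinv = np.linalg.inv(self.rot)
        t = -rinv @ self.tran
        return SymmetryOperator(_int_matrix(rinv), tuple(t), (0, 0, 0))

    def triplet(self) -> str:
        """Human-readable "x,y+1/2,-z" form (lattice shift folded in)."""
        op = gemmi.Op()
        op.rot = [[int(round(v * 24)) for v in row] for row in self.rot]
        op.tran = [int(round(v * 24)) for v in self.tran]
        return op.triplet()


def _int_matrix(m: np.ndarray) -> tuple:
    mi = np.rint(m).astype(int)
    if not np.allclose(m, mi, atol=1e-9):
        raise ValueError("non-integer rotation in fractional basis")
    return tuple(tuple(int(v) for v in row) for row in mi)


def _op_from_gemmi(op: gemmi.Op) -> SymmetryOperator:
    # gemmi stores rot/tran entries scaled by 24
    rot = np.array(op.rot, dtype=float) / 24.0
    return SymmetryOperator(_int_matrix(rot), tuple(v / 24.0 for v in op.tran))


def operators_for(
    hermann_mauguin: str, overrides: list[str] | None = None
) -> list[SymmetryOperator]:
    """Full list of general-position operators for a space-group symbol.

    ``overrides`` is a list of triplet strings ("-x,y+1/2,-z+1/2") used when
    the symbol is not in gemmi's tables (or to force a non-standard setting).
    """
    if overrides:
        ops = [_op_from_gemmi(gemmi.Op(t)) for t in overrides]
    else:
        sg = gemmi.find_spacegroup_by_name(hermann_mauguin)
        if sg is None:
            raise ValueError(
                f"unsupported space-group symbol {hermann_mauguin!r}; "
                "supply operator triplets explicitly"
            )
        ops = [_op_from_gemmi(op) for op in sg.operations()]
    if not any(op.is_identity() for op in ops):
        raise ValueError("operator list lacks the identity")
    return ops


@dataclass(frozen=True)
class SpaceGroupSpec:
    hermann_mauguin: str
    operators: tuple = ()

    @staticmethod
    def from_symbol(hm: str, overrides: list[str] | None = None) -> "SpaceGroupSpec":
        return SpaceGroupSpec(hm, tuple(operators_for(hm, overrides)))

    @property
    def n_asu(self) -> int:
        return len(self.operators)


def spacegroup_spec(hm: str, overrides: list[str] | None = None) -> SpaceGroupSpec:
    return SpaceGroupSpec.from_symbol(hm, overrides)


def frac_to_cart(cell: UnitCell, frac: np.ndarray) -> np.ndarray:
    """Fractional -> Cartesian (rows are points)."""
    return np.asarray(frac, dtype=float) @ cell.orth_matrix.T


def cart_to_frac(cell: UnitCell, cart: np.ndarray) -> np.ndarray:
    return np.asarray(cart, dtype=float) @ cell.frac_matrix.T


def apply_operator(
    cell: UnitCell, op: SymmetryOperator, cart: np.ndarray
) -> np.ndarray:
    """Apply a symmetry operator (incl. lattice shift) to Cartesian points."""
    return frac_to_cart(cell, op.apply(cart_to_frac(cell, cart)))


@dataclass
class ContactMate:
    """A symmetry-related copy touching the asymmetric unit."""

    operator: SymmetryOperator
    source_chain: str  # chain in the ASU
    target_chain: str  # chain of the transformed copy
    min_distance: float
    atom_pair_count: int


def expand_neighbors(
    model: StructureModel,
    cutoff: float,
    shift_window: int = 1,
    overrides: list[str] | None = None,
) -> list[ContactMate]:
    """Enumerate lattice neighbours with any atom within ``cutoff`` of the ASU.

    One record per (operator+shift, ASU chain, mate chain).  For distinct
    chain pairs the duplicate related by the inverse operator is collapsed
    onto the lexicographically smaller (source, target) ordering; self pairs
    (same chain id) are reported for every generating operator, so a single
    chain in a P1 cell sees each face neighbour individually.
    """
    if model.cell is None or not model.spacegroup_hm:
        raise ValueError("model lacks cell or space-group metadata")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cell = model.cell
    ops = operators_for(model.spacegroup_hm, overrides)
    atoms = [a for a in model.atoms if not a.is_hydrogen]
    if not atoms:
        raise ValueError("no heavy atoms")
    cart = np.array([a.position for a in atoms])
    chains = [a.chain_id for a in atoms]
    frac = cart_to_frac(cell, cart)
    tree = cKDTree(cart)

    w = int(shift_window)
    shifts = [
        (i, j, k)
        for i in range(-w, w + 1)
        for j in range(-w, w + 1)
        for k in range(-w, w + 1)
    ]
    results: list[ContactMate] = []
    for base in ops:
        for shift in shifts:
            op = base.with_shift(shift)
            if op.is_identity():
                continue
            mate_cart = frac_to_cart(cell, op.apply(frac))
            pairs = tree.query_ball_point(mate_cart, r=cutoff)
            per_pair: dict[tuple[str, str], list[float]] = {}
            for mi, asu_idx in enumerate(pairs):
                if not asu_idx:
                    continue
                d = np.linalg.norm(cart[asu_idx] - mate_cart[mi], axis=1)
                for j, dist in zip(asu_idx, d):
                    key = (chains[j], chains[mi])
                    per_pair.setdefault(key, []).append(float(dist))
            for (src, tgt), dists in per_pair.items():
                if src > tgt:
                    continue  # kept as the (tgt, src) record of the inverse op
                results.append(
                    ContactMate(
                        operator=op,
                        source_chain=src,
                        target_chain=tgt,
                        min_distance=min(dists),
                        atom_pair_count=len(dists),
                    )
                )
    results.sort(
        key=lambda m: (m.source_chain, m.target_chain, m.operator.rotation, m.operator.tran.tolist())
    )
    return results
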