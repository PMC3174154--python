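"""Rigid-body superposition, two-fold symmetry deviation, dihedrals, turns,
and unit-cell content arithmetic.

The deviation of a dimer from ideal C2 symmetry is measured by superposing
the chain-swapped copy (coordinates of B followed by A, residue-matched by
author number) onto the original (A followed by B): a perfect two-fold dimer
gives RMSD 0, and the value is invariant under rigid motion of the whole
assembly and symmetric in the two chains.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model import BACKBONE_ATOMS, StructureModel, select_atoms

__all__ = [
    "SuperpositionResult",
    "DihedralRecord",
    "CellContent",
    "superpose",
    "c2_deviation",
    "pairwise_protomer_rmsd",
    "backbone_dihedrals",
    "classify_beta_turn",
    "matthews",
    "solvent_percent_from_vm",
    "dihedral_angle",
]

#: Matthews solvent constant, Da/A^3 scale factor derived from a protein
#: partial specific volume of 0.74 cm^3/g.
MATTHEWS_CONSTANT = 1.23


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthonormal
    translation: np.ndarray  # applied after rotation, Angstrom
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (Kabsch).

    Reflections are rejected: the returned rotation always has determinant
    +1, so a mirror-related pair keeps a nonzero RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - mc, reference - rc
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    fitted = x @ rot.T
    rmsd = math.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1)))
    return SuperpositionResult(rotation=rot, translation=rc - rot @ mc, rmsd=rmsd, n_atoms=n)


def _paired_coords(
    model: StructureModel, chain_a: str, chain_b: str, atom_names
) -> tuple[np.ndarray, np.ndarray]:
    """Residue-matched coordinate arrays for two chains (author numbering)."""
    names = set(atom_names)

    def chain_map(cid):
        out = {}
        for a in model.atoms:
            if a.chain_id == cid and a.name in names and not a.is_hetero:
                out[(a.residue_number, a.insertion_code, a.name)] = a.position
        return out

    ma, mb = chain_map(chain_a), chain_map(chain_b)
    common = sorted(set(ma) & set(mb))
    if len(common) < 3:
        raise ValueError(
            f"chains {chain_a}/{chain_b} share only {len(common)} selected atoms"
        )
    return np.array([ma[k] for k in common]), np.array([mb[k] for k in common])


def c2_deviation(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    atom_selection=BACKBONE_ATOMS,
) -> float:
    """RMSD between the dimer and its chain-swapped copy after superposition."""
    ca, cb = _paired_coords(model, chain_a, chain_b, atom_selection)
    original = np.vstack([ca, cb])
    swapped = np.vstack([cb, ca])
    return superpose(swapped, original).rmsd


def pairwise_protomer_rmsd(
    models: list[tuple[StructureModel, str]] | list[StructureModel],
    atom_selection=BACKBONE_ATOMS,
):
    """All-pairs backbone RMSD over protomers.

    ``models`` is either a list of (model, chain_id) pairs or a list of
    models whose every chain becomes one protomer.  Returns
    (mean, sd, matrix); the sd is over the n*(n-1)/2 unordered pairs
    (population sd, ddof=0).
    """
    protomers: list[dict] = []
    names = set(atom_selection)
    flat: list[tuple[StructureModel, str]] = []
    for entry in models:
        if isinstance(entry, tuple):
            flat.append(entry)
        else:
            flat.extend((entry, cid) for cid in entry.chain_ids)
    for model, cid in flat:
        amap = {}
        for a in model.atoms:
            if a.chain_id == cid and a.name in names and not a.is_hetero:
                amap[(a.residue_number, a.insertion_code, a.name)] = a.position
        protomers.append(amap)
    n = len(protomers)
    if n < 2:
        raise ValueError("need at least two protomers")
    matrix = np.zeros((n, n))
    vals = []
    for i, j in combinations(range(n), 2):
        common = sorted(set(protomers[i]) & set(protomers[j]))
        if len(common) < 3:
            raise ValueError(f"protomers {i} and {j} share <3 selected atoms")
        xi = np.array([protomers[i][k] for k in common])
        xj = np.array([protomers[j][k] for k in common])
        r = superpose(xi, xj).rmsd
        matrix[i, j] = matrix[j, i] = r
        vals.append(r)
    vals = np.array(vals)
    return float(vals.mean()), float(vals.std()), matrix


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion in degrees, IUPAC sign convention, range (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


@dataclass
class DihedralRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    phi: float | None
    psi: float | None
    omega: float | None


def backbone_dihedrals(model: StructureModel, chain_id: str) -> list[DihedralRecord]:
    """phi/psi/omega for every residue of one chain with complete backbone.

    Angles needing a neighbour are None at termini; residues with missing
    backbone atoms are skipped with a warning.
    """
    residues = []
    for key in model.residues(chain_id):
        atoms = {a.name: a for a in model.atoms_of(key) if not a.is_hetero}
        if not atoms:
            continue
        if not {"N", "CA", "C"} <= set(atoms):
            warnings.warn(f"residue {key}: incomplete backbone, skipped", stacklevel=2)
            continue
        residues.append((key, atoms))

    out = []
    for i, (key, atoms) in enumerate(residues):
        prev_atoms = residues[i - 1][1] if i > 0 else None
        next_atoms = residues[i + 1][1] if i + 1 < len(residues) else None
        phi = psi = omega = None
        if prev_atoms is not None:
            phi = dihedral_angle(
                prev_atoms["C"].position, atoms["N"].position,
                atoms["CA"].position, atoms["C"].position,
            )
            omega = dihedral_angle(
                prev_atoms["CA"].position, prev_atoms["C"].position,
                atoms["N"].position, atoms["CA"].position,
            )
        if next_atoms is not None:
            psi = dihedral_angle(
                atoms["N"].position, atoms["CA"].position,
                atoms["C"].position, next_atoms["N"].position,
            )
        out.append(
            DihedralRecord(
                chain_id=key[0],
                residue_number=key[1],
                insertion_code=key[2],
                residue_name=atoms["CA"].residue_name,
                phi=phi, psi=psi, omega=omega,
            )
        )
    return out


#: canonical (phi, psi) of the two central residues for each beta-turn type
_TURN_CANON = {
    "I": ((-60.0, -30.0), (-90.0, 0.0)),
    "I'": ((60.0, 30.0), (90.0, 0.0)),
    "II": ((-60.0, 120.0), (80.0, 0.0)),
    "II'": ((60.0, -120.0), (-80.0, 0.0)),
}


def classify_beta_turn(
    phi_i1: float | None, psi_i1: float | None,
    phi_i2: float | None, psi_i2: float | None,
    tolerance: float = 45.0, slack: float = 55.0,
) -> str:
    """Type a four-residue turn from the (phi, psi) of residues i+1 and i+2.

    Nearest canonical type wins if all four angles fall within ``tolerance``
    degrees, with one angle allowed to stray up to ``slack``; anything else
    is "other".
    """
    angles = (phi_i1, psi_i1, phi_i2, psi_i2)
    if any(a is None for a in angles):
        return "other"

    def circ(a, b):
        return abs((a - b + 180.0) % 360.0 - 180.0)

    best, best_dev = "other", None
    for label, ((cph1, cps1), (cph2, cps2)) in _TURN_CANON.items():
        devs = sorted(
            (circ(phi_i1, cph1), circ(psi_i1, cps1), circ(phi_i2, cph2), circ(psi_i2, cps2)),
            reverse=True,
        )
        if devs[0] <= slack and devs[1] <= tolerance:
            total = sum(devs)
            if best_dev is None or total < best_dev:
                best, best_dev = label, total
    return best


@dataclass
class CellContent:
    """Matthews coefficient and solvent content of a crystal form."""

    cell: object
    z_asu: int
    n_asu: int
    mw: float  # Da per molecule

    @property
    def v_m(self) -> float:
        return self.cell.volume / (self.z_asu * self.n_asu * self.mw)

    @property
    def solvent_fraction(self) -> float:
        return 1.0 - MATTHEWS_CONSTANT / self.v_m


def matthews(cell, spacegroup_hm: str, z_asu: int, mw: float) -> CellContent:
    """Cell-content arithmetic: V_M = V_cell / (Z_asu * N_asu * MW)."""
    from .symmetry import operators_for

    if z_asu <= 0 or mw <= 0:
        raise ValueError("z_asu and mw must be positive")
    n_asu = len(operators_for(spacegroup_hm))
    return CellContent(cell=cell, z_asu=z_asu, n_asu=n_asu, mw=mw)


def solvent_percent_from_vm(v_m: float) -> float:
    """Solvent content (%) implied by a Matthews coefficient."""
    if v_m <= 0:
        raise ValueError("V_M must be positive")
    return 100.0 * (1.0 - MATTHEWS_CONSTANT / v_m)
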