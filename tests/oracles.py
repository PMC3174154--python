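"""Independent reference implementations used only as test oracles.

Nothing here imports the code paths it checks: neighbour enumeration is a
plain nested loop over gemmi operators, superposition goes through
scipy.spatial.transform, and chain building uses textbook internal
coordinates.
"""
from __future__ import annotations

import math

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_neighbors(model, cutoff: float, window: int = 2):
    """Exhaustive (operator x shift x chain pair) contact enumeration.

    Returns a set of (triplet, source_chain, target_chain, pair_count,
    rounded min distance) tuples, applying the same keep-rule as the
    implementation: cross-chain pairs only with source <= target.
    """
    cell = gemmi.UnitCell(model.cell.a, model.cell.b, model.cell.c,
                          model.cell.alpha, model.cell.beta, model.cell.gamma)
    sg = gemmi.find_spacegroup_by_name(model.spacegroup_hm)
    atoms = [a for a in model.atoms if not a.is_hydrogen]
    cart = [a.position for a in atoms]
    chains = [a.chain_id for a in atoms]
    frac = [cell.fractionalize(gemmi.Position(*p)) for p in cart]
    out = set()
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / 24.0
        tran = np.array(op.tran, dtype=float) / 24.0
        for sx in range(-window, window + 1):
            for sy in range(-window, window + 1):
                for sz in range(-window, window + 1):
                    shift = np.array([sx, sy, sz], dtype=float)
                    if (np.allclose(rot, np.eye(3)) and np.allclose(tran, 0)
                            and sx == sy == sz == 0):
                        continue
                    per_pair: dict = {}
                    for mi, f in enumerate(frac):
                        fv = rot @ np.array([f.x, f.y, f.z]) + tran + shift
                        p = cell.orthogonalize(gemmi.Fractional(*fv))
                        mate = np.array([p.x, p.y, p.z])
                        for j, q in enumerate(cart):
                            d = float(np.linalg.norm(mate - np.asarray(q)))
                            if d <= cutoff:
                                key = (chains[j], chains[mi])
                                per_pair.setdefault(key, []).append(d)
                    trip = _triplet(rot, tran + shift)
                    for (src, tgt), ds in per_pair.items():
                        if src > tgt:
                            continue
                        out.add((trip, src, tgt, len(ds), round(min(ds), 6)))
    return out


def _triplet(rot, tran):
    op = gemmi.Op()
    op.rot = [[int(round(v * 24)) for v in row] for row in rot]
    op.tran = [int(round(v * 24)) for v in tran]
    return op.triplet()


def superpose_rmsd_scipy(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Best-fit proper-rotation RMSD via scipy's align_vectors."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(rc, mc)
    return float(rssd / math.sqrt(len(mobile)))


def swap_superpose_rmsd(model, chain_a: str, chain_b: str, atom_names=("N", "CA", "C", "O")) -> float:
    """Generic chain-swap superposition RMSD, built on scipy only."""
    names = set(atom_names)

    def cmap(cid):
        return {
            (a.residue_number, a.insertion_code, a.name): a.position
            for a in model.atoms
            if a.chain_id == cid and a.name in names and not a.is_hetero
        }

    ma, mb = cmap(chain_a), cmap(chain_b)
    common = sorted(set(ma) & set(mb))
    ca = np.array([ma[k] for k in common])
    cb = np.array([mb[k] for k in common])
    original = np.vstack([ca, cb])
    swapped = np.vstack([cb, ca])
    return superpose_rmsd_scipy(swapped, original)


# ---------------------------------------------------------------------------
# internal-coordinate chain building (for dihedral round-trip tests)

def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d given three predecessors and internal coordinates."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phis, psis, omega: float = 180.0) -> list[tuple[str, np.ndarray]]:
    """N/CA/C trace with prescribed torsions (standard bond geometry).

    ``phis[i]`` applies to residue i (ignored for residue 0), ``psis[i]``
    to residue i (ignored for the last).  Returns [(atom_name, position)]
    grouped three per residue.
    """
    n_res = len(phis)
    atoms: list[tuple[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.2)
    c0 = ca0 + 1.525 * np.array([-math.cos(ang), math.sin(ang), 0.0])
    atoms += [("N", n0), ("CA", ca0), ("C", c0)]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = (atoms[-3][1], atoms[-2][1], atoms[-1][1])
        n_i = _place(n_prev, ca_prev, c_prev, 1.329, 116.2, psis[i - 1])
        ca_i = _place(ca_prev, c_prev, n_i, 1.458, 121.7, omega)
        c_i = _place(c_prev, n_i, ca_i, 1.525, 111.2, phis[i])
        atoms += [("N", n_i), ("CA", ca_i), ("C", c_i)]
    return atoms
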