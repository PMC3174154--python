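"""Seeded synthetic fixtures: sphere sets, C2 dimers, beta-strand pairs,
toy crystals, alignments and binding isotherms.

Every generator is a pure function of its arguments (one integer seed per
call, numpy Generator underneath), and emits machine-readable ground truth
alongside the coordinates, so every downstream stage can be tested against
construction rather than against itself.  Toy monomers are backbone-only
(N, CA, C, O) pseudo-proteins; nothing here is energy-minimised or intended
to be physically foldable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .equilibrium import Isotherm, predicted_rs
from .model import Atom, StructureModel, UnitCell
from .sasa import SasaParams
from .symmetry import expand_neighbors

__all__ = [
    "make_sphere_set",
    "make_c2_dimer",
    "make_beta_pair",
    "make_toy_crystal",
    "make_alignment",
    "make_isotherm",
]

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


def _atom(serial, name, element, resname, resnum, chain, pos, hetero=False) -> Atom:
    return Atom(
        serial=serial, name=name, element=element, alt_loc="",
        residue_name=resname, residue_number=resnum, insertion_code="",
        chain_id=chain, position=np.asarray(pos, dtype=float), is_hetero=hetero,
    )


def make_sphere_set(radii, positions, probe_radius: float = 1.4,
                    n_sphere_points: int = 960,
                    chains=None) -> tuple[StructureModel, SasaParams]:
    """Pseudo-atom spheres with explicit radii, for SASA oracle fixtures.

    ``chains`` optionally assigns a chain id per sphere (default all "A"),
    which lets a two-sphere fixture stand in for a two-chain complex in
    buried-surface oracles.
    """
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if len(radii) != len(positions):
        raise ValueError("radii and positions must have the same length")
    if chains is None:
        chains = ["A"] * len(positions)
    elif len(chains) != len(positions):
        raise ValueError("chains and positions must have the same length")
    if len(positions) > 1:
        from scipy.spatial.distance import pdist

        if pdist(positions).min() < 1e-9:
            raise ValueError("coincident sphere positions")
    atoms = [
        _atom(i + 1, f"X{i + 1}", "C", "SPH", i + 1, chains[i], positions[i])
        for i in range(len(positions))
    ]
    table = tuple((f"X{i + 1}", float(radii[i])) for i in range(len(radii)))
    params = SasaParams(probe_radius=probe_radius, n_sphere_points=n_sphere_points,
                        radii_table=table)
    return StructureModel(atoms, title="sphere set"), params


def _random_backbone(n_residues: int, rng: np.random.Generator,
                     chain: str, start_serial: int = 1) -> list[Atom]:
    """Compact random-walk backbone (CA steps of 3.8 A with a soft confinement)."""
    ca = np.zeros((n_residues, 3))
    direction = rng.normal(size=3)
    for i in range(1, n_residues):
        direction = 0.6 * direction + rng.normal(size=3)
        direction -= 0.02 * ca[i - 1]  # pull toward the origin: compactness
        direction /= np.linalg.norm(direction)
        ca[i] = ca[i - 1] + 3.8 * direction
    atoms = []
    serial = start_serial
    for i in range(n_residues):
        # schematic local frame for N, C, O around each CA
        u = rng.normal(size=3); u /= np.linalg.norm(u)
        v = rng.normal(size=3); v -= (v @ u) * u; v /= np.linalg.norm(v)
        n_pos = ca[i] + 1.45 * u
        c_pos = ca[i] - 1.52 * u + 0.3 * v
        o_pos = c_pos + 1.23 * v
        for name, elem, pos in (("N", "N", n_pos), ("CA", "C", ca[i]),
                                ("C", "C", c_pos), ("O", "O", o_pos)):
            atoms.append(_atom(serial, name, elem, "GLY", i + 1, chain, pos))
            serial += 1
    return atoms


def _rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


@dataclass
class C2DimerTruth:
    axis: tuple
    center: tuple
    noise_sd: float


def make_c2_dimer(
    monomer_size: int = 20,
    axis=(0.0, 0.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    separation: float = 12.0,
) -> tuple[StructureModel, C2DimerTruth]:
    """Two-chain dimer: B is the exact 180-degree rotation of A about ``axis``
    through a center offset, plus optional Gaussian noise on B only."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    chain_a = _random_backbone(monomer_size, rng, "A")
    rot = _rotation_about_axis(axis, 180.0)
    # put the two-fold axis off to the side so the chains do not overlap
    axis_u = np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    perp = np.array([1.0, 0.0, 0.0])
    if abs(perp @ axis_u) > 0.9:
        perp = np.array([0.0, 1.0, 0.0])
    perp -= (perp @ axis_u) * axis_u
    center = separation * perp / np.linalg.norm(perp)
    chain_b = []
    for a in chain_a:
        b = a.copy()
        b.chain_id = "B"
        b.position = rot @ (a.position - center) + center
        if noise_sd > 0:
            b.position = b.position + rng.normal(scale=noise_sd, size=3)
        chain_b.append(b)
    model = StructureModel(chain_a + chain_b, title="synthetic C2 dimer")
    return model, C2DimerTruth(tuple(axis_u), tuple(center), noise_sd)


@dataclass
class BetaPairTruth:
    """Designed cross-strand bond ledger: (donor chain, donor residue,
    acceptor chain, acceptor residue, realised distance)."""

    bonds: list


def make_beta_pair(
    n_residues: int = 8,
    register_shift: int = 0,
    twist: float = 0.0,
    spacing: float = 4.8,
    ladder_distance: float = 2.9,
) -> tuple[StructureModel, BetaPairTruth]:
    """Two schematic antiparallel strands with an O...N hydrogen-bond ladder.

    Strand T (chain B) runs antiparallel above strand S (chain A); paired
    residues exchange two main-chain bonds (N_S->O_T and N_T->O_S) at
    ``ladder_distance``.  ``register_shift`` slides strand B along the strand
    axis by whole residue steps, shortening the ladder; ``twist`` (degrees)
    rotates strand B about the vertical axis through the ladder midpoint so
    that designed bonds far from the centre stretch and break.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues per strand")
    dx = 1.4
    y2 = ladder_distance
    atoms: list[Atom] = []
    serial = 1
    # strand A: residue i (1-based) anchored at x = spacing * (i-1)
    for i in range(n_residues):
        x = spacing * i
        for name, elem, pos in (
            ("N", "N", (x, 0.0, 0.0)),
            ("CA", "C", (x + 0.5, -1.0, 0.0)),
            ("C", "C", (x + dx, -1.0, 0.0)),
            ("O", "O", (x + dx, 0.0, 0.0)),
        ):
            atoms.append(_atom(serial, name, elem, "GLY", i + 1, "A", pos))
            serial += 1
    # strand B: residue k pairs with A residue i = n-1-k+shift (0-based)
    pairing = {}
    b_atoms: list[Atom] = []
    for k in range(n_residues):
        i = n_residues - 1 - k + register_shift
        x = spacing * i
        if 0 <= i < n_residues:
            pairing[k + 1] = i + 1
        for name, elem, pos in (
            ("N", "N", (x + dx, y2, 0.0)),
            ("CA", "C", (x + dx - 0.5, y2 + 1.0, 0.0)),
            ("C", "C", (x, y2 + 1.0, 0.0)),
            ("O", "O", (x, y2, 0.0)),
        ):
            b_atoms.append(_atom(serial, name, elem, "GLY", k + 1, "B", pos))
            serial += 1
    if twist != 0.0:
        xc = spacing * (n_residues - 1) / 2.0
        rot = _rotation_about_axis((0.0, 1.0, 0.0), twist)
        pivot = np.array([xc, 0.0, 0.0])
        for a in b_atoms:
            a.position = rot @ (a.position - pivot) + pivot
    atoms += b_atoms
    model = StructureModel(atoms, title="synthetic beta pair")

    def pos_of(chain, resnum, name):
        for a in atoms:
            if a.chain_id == chain and a.residue_number == resnum and a.name == name:
                return a.position
        raise KeyError((chain, resnum, name))

    bonds = []
    for kb, ia in pairing.items():
        d1 = float(np.linalg.norm(pos_of("B", kb, "N") - pos_of("A", ia, "O")))
        d2 = float(np.linalg.norm(pos_of("A", ia, "N") - pos_of("B", kb, "O")))
        bonds.append(("B", kb, "A", ia, d1))
        bonds.append(("A", ia, "B", kb, d2))
    return model, BetaPairTruth(bonds=bonds)


def make_toy_crystal(
    monomer: StructureModel,
    spacegroup_hm: str,
    cell: UnitCell,
    placement=(0.25, 0.25, 0.25),
    clash_tolerance: float = 1.5,
) -> StructureModel:
    """Place a monomer in a cell under a space group, as one ASU.

    The monomer centroid is moved to the fractional ``placement``; the
    result carries CRYST1 metadata so lattice mates can be generated.  A
    mate atom closer than ``clash_tolerance`` to the ASU is a placement
    error.
    """
    from .symmetry import frac_to_cart

    target = frac_to_cart(cell, np.asarray(placement, dtype=float))
    centroid = monomer.coords().mean(axis=0)
    shift = target - centroid
    atoms = []
    for a in monomer.atoms:
        b = a.copy()
        b.position = a.position + shift
        atoms.append(b)
    model = StructureModel(atoms, cell=cell, spacegroup_hm=spacegroup_hm,
                           title=monomer.title or "toy crystal")
    mates = expand_neighbors(model, cutoff=max(clash_tolerance, 2.0))
    for m in mates:
        if m.min_distance < clash_tolerance:
            raise ValueError(
                f"placement clash: mate {m.operator.triplet()} at {m.min_distance:.2f} A"
            )
    return model


def make_alignment(
    width: int = 60,
    n_seqs: int = 22,
    conserved_columns=(),
    seed: int = 0,
    max_variable_identity: float = 0.85,
) -> tuple[MultipleSeqAlignment, set[int]]:
    """Alignment with designated fully conserved columns.

    Non-designated columns get a modal residue whose frequency is drawn
    below ``max_variable_identity`` so conservation calls at the usual 0.90
    threshold recover exactly the designed set.  Returns (alignment,
    0-based conserved column indices).
    """
    conserved = set(int(c) for c in conserved_columns)
    if conserved and (min(conserved) < 0 or max(conserved) >= width):
        raise ValueError("conserved_columns outside [0, width)")
    rng = np.random.default_rng(seed)
    cols = []
    for j in range(width):
        aa = _AMINO[rng.integers(len(_AMINO))]
        if j in conserved:
            cols.append([aa] * n_seqs)
        else:
            n_modal = int(rng.integers(n_seqs // 3, int(max_variable_identity * n_seqs)))
            others = [c for c in _AMINO if c != aa]
            col = [aa] * n_modal + [
                others[rng.integers(len(others))] for _ in range(n_seqs - n_modal)
            ]
            rng.shuffle(col)
            cols.append(col)
    records = [
        SeqRecord(Seq("".join(cols[j][s] for j in range(width))), id=f"seq{s + 1:02d}",
                  description="")
        for s in range(n_seqs)
    ]
    return MultipleSeqAlignment(records), conserved


def make_isotherm(
    k_d: float = 0.8,
    rs_m: float = 2.6,
    rs_d: float = 3.4,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Isotherm, dict]:
    """Monomer-dimer isotherm sampled from the closed-form model.

    Default concentrations are 20 points log-spaced over 0.01-100 uM around
    a sub-micromolar K_D, the regime of the SEC-style dilution series this
    emulates.  Gaussian noise of sd ``noise_sd`` (same units as the radii)
    is added when requested.
    """
    if concentrations is None:
        concentrations = np.logspace(-2, 2, 20)
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    rs = predicted_rs(c, k_d, rs_m, rs_d)
    if noise_sd > 0:
        rs = rs + rng.normal(scale=noise_sd, size=c.shape)
    truth = {"k_d": k_d, "rs_m": rs_m, "rs_d": rs_d, "noise_sd": noise_sd}
    return Isotherm(c_total=c, rs_observed=np.maximum(rs, 1e-6), noise_sd=noise_sd or None), truth
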