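"""Protein-protein interface catalog: contacts, hydrogen bonds, bridging
waters, metal sites, and secondary-structure-based classification.

Hydrogen bonds use geometric criteria on heavy atoms only (donor-acceptor
distance and antecedent-donor-acceptor angle); donors and acceptors are
assigned from standard amino-acid N/O atom-name tables.  All distance
comparisons are closed intervals at the cutoff.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, ResidueKey, StructureModel, select_atoms
from .sasa import DeltaAsaRecord, SasaParams, delta_asa
from .symmetry import ContactMate, apply_operator, expand_neighbors

__all__ = [
    "HydrogenBond",
    "MetalSite",
    "InterfaceRecord",
    "CatalogConfig",
    "contact_atoms",
    "find_hbonds",
    "find_bridging_waters",
    "find_metal_sites",
    "classify_interface",
    "catalog_interfaces",
    "assign_sse_from_dihedrals",
]

# ---------------------------------------------------------------------------
# donor / acceptor chemistry tables (heavy atoms; hydrogens are ignored)

_MAINCHAIN_DONOR = "N"
_MAINCHAIN_ACCEPTOR = ("O", "OXT")

_SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

_SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}


def _is_donor(a: Atom) -> bool:
    if a.is_water:
        return a.element == "O"
    if a.name == _MAINCHAIN_DONOR and a.residue_name != "PRO":
        return True
    return a.name in _SIDECHAIN_DONORS.get(a.residue_name, ())


def _is_acceptor(a: Atom) -> bool:
    if a.is_water:
        return a.element == "O"
    if a.name in _MAINCHAIN_ACCEPTOR:
        return True
    return a.name in _SIDECHAIN_ACCEPTORS.get(a.residue_name, ())


def _is_mainchain(a: Atom) -> bool:
    return a.name in ("N", "CA", "C", "O", "OXT")


@dataclass
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    distance: float
    antecedent_angle: float | None  # antecedent-donor-acceptor, degrees

    @property
    def mainchain_mainchain(self) -> bool:
        return _is_mainchain(self.donor) and _is_mainchain(self.acceptor)


@dataclass
class MetalSite:
    metal: Atom
    ligands: list  # (Atom, distance) pairs
    @property
    def chains_involved(self) -> frozenset:
        return frozenset(a.chain_id for a, _ in self.ligands)

    @property
    def inter_chain(self) -> bool:
        return len(self.chains_involved) >= 2

    @property
    def bidentate_carboxylates(self) -> list[ResidueKey]:
        """Residues donating both carboxylate oxygens (OD1+OD2 or OE1+OE2)."""
        by_res: dict[ResidueKey, set[str]] = {}
        for a, _ in self.ligands:
            by_res.setdefault(a.residue_key, set()).add(a.name)
        out = []
        for key, names in by_res.items():
            if {"OD1", "OD2"} <= names or {"OE1", "OE2"} <= names:
                out.append(key)
        return out


@dataclass
class CatalogConfig:
    """Tunable thresholds of the interface catalog (Angstrom, degrees)."""

    contact_cutoff: float = 6.5
    hbond_max_distance: float = 3.5
    hbond_min_angle: float = 90.0
    metal_cutoff: float = 3.0
    metal_elements: frozenset = frozenset({"CA", "ZN", "MG", "MN", "NA", "K"})
    min_delta_asa: float = 400.0
    lattice_cutoff: float = 5.0
    shift_window: int = 1
    expand_symmetry: bool = True
    sasa: SasaParams = field(default_factory=SasaParams)


def _protein_heavy(model: StructureModel, chains) -> list[Atom]:
    chains = set(chains)
    return [
        a for a in model.atoms
        if a.chain_id in chains and not a.is_hydrogen and not a.is_hetero and not a.is_water
    ]


def contact_atoms(
    model: StructureModel, chains_a, chains_b, cutoff: float = 6.5
) -> list[tuple[Atom, Atom, float]]:
    """All cross-chain heavy-atom pairs within ``cutoff`` (closed interval)."""
    chains_a, chains_b = set(chains_a), set(chains_b)
    if chains_a & chains_b:
        raise ValueError("chain sets overlap")
    aa = _protein_heavy(model, chains_a)
    ab = _protein_heavy(model, chains_b)
    if not aa or not ab:
        raise ValueError("empty selection on one side")
    pa = np.array([a.position for a in aa])
    pb = np.array([a.position for a in ab])
    tree = cKDTree(pb)
    out = []
    # closed interval: pad the query radius and filter exactly
    for i, hits in enumerate(tree.query_ball_point(pa, r=cutoff * (1 + 1e-12) + 1e-9)):
        for j in hits:
            d = float(np.linalg.norm(pa[i] - pb[j]))
            if d <= cutoff:
                out.append((aa[i], ab[j], d))
    return out


def _antecedent(model: StructureModel, donor: Atom) -> Atom | None:
    """Nearest heavy atom of the same residue: the donor's covalent anchor."""
    best, best_d = None, None
    for a in model.atoms_of(donor.residue_key):
        if a is donor or a.is_hydrogen:
            continue
        d = float(np.linalg.norm(a.position - donor.position))
        if d < 2.0 and (best_d is None or d < best_d):
            best, best_d = a, d
    return best


def _angle(p0, p1, p2) -> float:
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    c = float(np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def find_hbonds(
    model: StructureModel,
    chains_a,
    chains_b,
    max_distance: float = 3.5,
    min_angle: float = 90.0,
) -> list[HydrogenBond]:
    """Cross-chain hydrogen bonds between two disjoint chain sets.

    A bond requires a donor on one side and an acceptor on the other with
    heavy-atom distance <= ``max_distance`` and, when the donor has a
    resolvable covalent antecedent, an antecedent-donor-acceptor angle
    >= ``min_angle``.  The returned list covers both donor directions.
    """
    chains_a, chains_b = set(chains_a), set(chains_b)
    if chains_a & chains_b:
        raise ValueError("chain sets overlap")
    bonds = []
    for donors_side, acceptors_side in ((chains_a, chains_b), (chains_b, chains_a)):
        donors = [
            a for a in model.atoms
            if a.chain_id in donors_side and not a.is_water and _is_donor(a)
        ]
        acceptors = [
            a for a in model.atoms
            if a.chain_id in acceptors_side and not a.is_water and _is_acceptor(a)
        ]
        if not donors or not acceptors:
            continue
        pa = np.array([a.position for a in acceptors])
        tree = cKDTree(pa)
        for d_atom in donors:
            for j in tree.query_ball_point(d_atom.position, r=max_distance + 1e-9):
                acc = acceptors[j]
                dist = float(np.linalg.norm(d_atom.position - acc.position))
                if dist > max_distance:
                    continue
                ante = _antecedent(model, d_atom)
                ang = None
                if ante is not None:
                    ang = _angle(ante.position, d_atom.position, acc.position)
                    if ang < min_angle:
                        continue
                bonds.append(HydrogenBond(d_atom, acc, dist, ang))
    bonds.sort(key=lambda b: (b.donor.chain_id, b.donor.residue_number, b.donor.name,
                              b.acceptor.chain_id, b.acceptor.residue_number, b.acceptor.name))
    return bonds


def find_bridging_waters(
    model: StructureModel,
    chains_a,
    chains_b,
    max_distance: float = 3.5,
) -> list[tuple[Atom, HydrogenBond, HydrogenBond]]:
    """Waters hydrogen-bonded to polar atoms of both partners.

    Returns (water O, closest bond to side A, closest bond to side B); the
    donor/acceptor direction through the water is not resolved (no
    hydrogens), so each leg is reported as water-donor to protein-acceptor
    or protein-donor to water-acceptor, whichever is chemically possible.
    """
    chains_a, chains_b = set(chains_a), set(chains_b)
    waters = [a for a in model.atoms if a.is_water and a.element == "O"]
    out = []
    for w in waters:
        legs: dict[str, list[tuple[Atom, float]]] = {"a": [], "b": []}
        for a in model.atoms:
            if a.is_water or a.is_hydrogen:
                continue
            side = "a" if a.chain_id in chains_a else "b" if a.chain_id in chains_b else None
            if side is None or not (_is_donor(a) or _is_acceptor(a)):
                continue
            d = float(np.linalg.norm(a.position - w.position))
            if d <= max_distance:
                legs[side].append((a, d))
        if legs["a"] and legs["b"]:
            pa, da = min(legs["a"], key=lambda t: t[1])
            pb, db = min(legs["b"], key=lambda t: t[1])
            out.append((w, HydrogenBond(w, pa, da, None), HydrogenBond(w, pb, db, None)))
    return out


def find_metal_sites(
    model: StructureModel,
    metal_elements=frozenset({"CA", "ZN", "MG", "MN", "NA", "K"}),
    cutoff: float = 3.0,
) -> list[MetalSite]:
    """Coordination environment of every metal hetero atom.

    Ligands are protein N/O (and S) atoms within ``cutoff``; a site with no
    ligand is still returned (so it can be reported as lattice-occluded) but
    carries no interface attribution.
    """
    metal_elements = {e.upper() for e in metal_elements}
    metals = [a for a in model.atoms if a.is_hetero and not a.is_water
              and a.element.upper() in metal_elements]
    protein = [a for a in model.atoms
               if not a.is_hetero and not a.is_water and a.element in ("N", "O", "S")]
    sites = []
    if protein:
        pos = np.array([a.position for a in protein])
        tree = cKDTree(pos)
        for m in metals:
            ligands = []
            for j in tree.query_ball_point(m.position, r=cutoff + 1e-9):
                d = float(np.linalg.norm(pos[j] - m.position))
                if d <= cutoff:
                    ligands.append((protein[j], d))
            ligands.sort(key=lambda t: t[1])
            sites.append(MetalSite(metal=m, ligands=ligands))
    else:
        sites = [MetalSite(metal=m, ligands=[]) for m in metals]
    return sites


# ---------------------------------------------------------------------------
# classification

def classify_interface(
    contact_residues_a,
    contact_residues_b,
    sse_annotation: dict,
) -> str:
    """Label an interface "X--Y" from the secondary-structure elements that
    dominate each side's contact residues.

    ``sse_annotation`` maps chain id -> list of (start, end, label) residue
    ranges (author numbering, inclusive).  Each side votes by element
    membership; if the winning element holds less than half the contact
    residues on either side, or ties, the interface is "other".
    """
    def winner(residues) -> str | None:
        votes: dict[str, int] = {}
        total = 0
        for (chain, num, _icode) in residues:
            total += 1
            label = None
            for start, end, lab in sse_annotation.get(chain, ()):
                if start <= num <= end:
                    label = lab
                    break
            votes[label or "loop"] = votes.get(label or "loop", 0) + 1
        if not votes or total == 0:
            return None
        ranked = sorted(votes.items(), key=lambda kv: -kv[1])
        top_label, top_n = ranked[0]
        if 2 * top_n < total:
            return None
        if len(ranked) > 1 and ranked[1][1] == top_n:
            return None  # tie
        return top_label

    wa = winner(contact_residues_a)
    wb = winner(contact_residues_b)
    if wa is None or wb is None or "loop" in (wa, wb):
        return "other"
    lo, hi = sorted((wa, wb))
    return f"{lo}--{hi}"


def assign_sse_from_dihedrals(model: StructureModel, chain_id: str) -> list[tuple[int, int, str]]:
    """Fallback phi/psi secondary-structure assigner for one chain.

    Helix: phi in [-100, -30] and psi in [-80, -5]; strand: phi in
    [-180, -40] and psi in [90, 180] or [-180, -170].  Runs shorter than 3
    residues are dropped.  Annotation files, when available, take precedence
    over this assigner.
    """
    from .geometry import backbone_dihedrals

    recs = backbone_dihedrals(model, chain_id)
    labels = []
    for r in recs:
        lab = "loop"
        if r.phi is not None and r.psi is not None:
            if -100 <= r.phi <= -30 and -80 <= r.psi <= -5:
                lab = "helix"
            elif -180 <= r.phi <= -40 and (90 <= r.psi <= 180 or -180 <= r.psi <= -170):
                lab = "strand"
        labels.append((r.residue_number, lab))
    ranges = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j][1] == labels[i][1]:
            j += 1
        if labels[i][1] != "loop" and j - i >= 3:
            ranges.append((labels[i][0], labels[j - 1][0], labels[i][1]))
        i = j
    return ranges


# ---------------------------------------------------------------------------
# catalog

@dataclass
class InterfaceRecord:
    partner_a: str
    partner_b: str
    operator_triplet: str | None  # None for an intra-ASU pair
    delta_asa: DeltaAsaRecord
    contact_residues_a: list
    contact_residues_b: list
    hbonds: list
    bridging_waters: list
    metal_sites: list
    c2_rmsd: float | None
    classification: str

    def to_dict(self) -> dict:
        return {
            "partner_a": self.partner_a,
            "partner_b": self.partner_b,
            "operator": self.operator_triplet,
            "delta_asa_total": round(self.delta_asa.delta, 2),
            "delta_asa_per_monomer": round(self.delta_asa.delta_per_monomer, 2),
            "n_contact_residues_a": len(self.contact_residues_a),
            "n_contact_residues_b": len(self.contact_residues_b),
            "n_hbonds": len(self.hbonds),
            "n_bridging_waters": len(self.bridging_waters),
            "n_interface_metals": len(self.metal_sites),
            "c2_rmsd": None if self.c2_rmsd is None else round(self.c2_rmsd, 4),
            "classification": self.classification,
        }


def _dedup_self_mates(mates: list[ContactMate]) -> list[ContactMate]:
    """Collapse same-chain mates related by the inverse operator.

    A chain touching its own copy under g also touches the copy under
    g^-1; the two describe one physical interface, so the catalog keeps a
    single representative (expand_neighbors itself reports both, which is
    what lattice-coordination counts need).
    """
    def op_key(op):
        rot = tuple(tuple(int(round(v)) for v in row) for row in op.rot)
        tran = tuple(round(float(v), 6) for v in op.tran)
        return (rot, tran)

    kept: list[ContactMate] = []
    seen: set = set()
    for m in mates:
        if m.source_chain != m.target_chain:
            kept.append(m)
            continue
        k = op_key(m.operator)
        ki = op_key(m.operator.inverse())
        if min(k, ki) in seen:
            continue
        seen.add(min(k, ki))
        kept.append(m)
    return kept


def _merge_mate(model: StructureModel, mate: ContactMate, tag: str) -> tuple[StructureModel, str]:
    """Model containing the ASU plus a transformed copy of the mate chain."""
    new_chain = f"{mate.target_chain}{tag}"
    copies = []
    for a in model.atoms:
        if a.chain_id != mate.target_chain:
            continue
        b = a.copy()
        b.position = apply_operator(model.cell, mate.operator, a.position[None, :])[0]
        b.chain_id = new_chain
        copies.append(b)
    merged = StructureModel(
        [a.copy() for a in model.atoms] + copies,
        cell=model.cell,
        spacegroup_hm=model.spacegroup_hm,
        title=model.title,
    )
    return merged, new_chain


def _build_record(
    merged: StructureModel,
    chain_a: str,
    chain_b: str,
    operator_triplet: str | None,
    config: CatalogConfig,
    sse_annotation: dict | None,
) -> InterfaceRecord | None:
    try:
        dasa = delta_asa(merged, {chain_a}, {chain_b}, config.sasa)
    except ValueError:
        return None
    contacts = contact_atoms(merged, {chain_a}, {chain_b}, config.contact_cutoff)
    res_a = sorted({a.residue_key for a, _, _ in contacts})
    res_b = sorted({b.residue_key for _, b, _ in contacts})
    hbonds = find_hbonds(merged, {chain_a}, {chain_b},
                         config.hbond_max_distance, config.hbond_min_angle)
    waters = find_bridging_waters(merged, {chain_a}, {chain_b}, config.hbond_max_distance)
    metals = [
        s for s in find_metal_sites(merged, config.metal_elements, config.metal_cutoff)
        if {chain_a, chain_b} <= s.chains_involved
    ]
    try:
        from .geometry import c2_deviation

        c2 = c2_deviation(merged, chain_a, chain_b)
    except ValueError:
        c2 = None
    if sse_annotation:
        annotation = dict(sse_annotation)
        # a symmetry-mate chain inherits its parent chain's annotation
        for cid in (chain_a, chain_b):
            if cid not in annotation and cid[:1] in annotation:
                annotation[cid] = annotation[cid[:1]]
        classification = classify_interface(res_a, res_b, annotation)
    else:
        classification = "other"
    return InterfaceRecord(
        partner_a=chain_a,
        partner_b=chain_b,
        operator_triplet=operator_triplet,
        delta_asa=dasa,
        contact_residues_a=res_a,
        contact_residues_b=res_b,
        hbonds=hbonds,
        bridging_waters=waters,
        metal_sites=metals,
        c2_rmsd=c2,
        classification=classification,
    )


def catalog_interfaces(
    model: StructureModel,
    config: CatalogConfig | None = None,
    sse_annotation: dict | None = None,
) -> list[InterfaceRecord]:
    """Catalog of chain-pair interfaces within the ASU and across the lattice.

    Records with total buried surface below ``config.min_delta_asa`` are
    dropped; the rest are sorted by descending buried surface.  Output is a
    deterministic function of (model, config, annotation).
    """
    config = config or CatalogConfig()
    protein_chains = sorted(
        {a.chain_id for a in model.atoms if not a.is_hetero and not a.is_water}
    )
    records: list[InterfaceRecord] = []
    for i, ca in enumerate(protein_chains):
        for cb in protein_chains[i + 1:]:
            rec = _build_record(model, ca, cb, None, config, sse_annotation)
            if rec is not None:
                records.append(rec)
    if config.expand_symmetry and model.cell is not None and model.spacegroup_hm:
        protein_only = select_atoms(model, hetero="exclude")
        mates = expand_neighbors(protein_only, config.lattice_cutoff, config.shift_window)
        mates = _dedup_self_mates(mates)
        for k, mate in enumerate(mates):
            merged, mate_chain = _merge_mate(model, mate, tag=f"*{k}")
            rec = _build_record(
                merged, mate.source_chain, mate_chain,
                mate.operator.triplet(), config, sse_annotation,
            )
            if rec is not None:
                records.append(rec)
    records = [r for r in records if r.delta_asa.delta >= config.min_delta_asa]
    records.sort(key=lambda r: (-r.delta_asa.delta, r.partner_a, r.partner_b))
    return records


def catalog_to_json(records: list[InterfaceRecord]) -> str:
    return json.dumps([r.to_dict() for r in records], indent=2)


def catalog_to_tsv(records: list[InterfaceRecord]) -> str:
    import pandas as pd

    return pd.DataFrame([r.to_dict() for r in records]).to_csv(sep="\t", index=False)
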