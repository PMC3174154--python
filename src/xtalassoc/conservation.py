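"""Per-column conservation of a multiple alignment, mapped onto structure
residues and interface membership.

Identity is the frequency of the modal residue among the non-gap entries of
a column; all-gap columns score 0 and columns with more than half gaps are
flagged low-confidence.  "Conserved" means identity strictly above the
threshold (default 0.90, i.e. more than 90% of the sequences).
"""
from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.SeqUtils import seq1

from .model import ResidueKey, StructureModel

__all__ = [
    "ConservationProfile",
    "InterfaceConservationReport",
    "read_alignment",
    "column_identity",
    "conserved_positions",
    "map_profile_to_chain",
    "interface_conservation",
]

GAP_CHARS = frozenset("-.")


def read_alignment(path: str | os.PathLike) -> MultipleSeqAlignment:
    """Read a FASTA or Clustal alignment; sequences are upper-cased.

    The format is sniffed from the first non-blank character ('>' means
    FASTA).  Ragged inputs raise a ValueError.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    fmt = "fasta" if stripped.startswith(">") else "clustal"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid {fmt} alignment ({exc})") from exc
    if len(aln) < 2:
        raise ValueError(f"{path}: need at least two sequences")
    for rec in aln:
        rec.seq = rec.seq.upper()
    return aln


@dataclass
class ConservationProfile:
    """Per-column identity fractions plus an optional structure mapping."""

    columns: list  # (column index, modal residue or None, fraction, low_confidence)
    master_id: str
    master_seq: str  # aligned master sequence (with gaps)
    master_map: dict | None = None  # column index -> ResidueKey

    @property
    def fractions(self) -> list[float]:
        return [c[2] for c in self.columns]


def column_identity(aln: MultipleSeqAlignment, master_id: str | None = None) -> ConservationProfile:
    """Identity fraction of the modal non-gap residue, per column."""
    n_cols = aln.get_alignment_length()
    columns = []
    for j in range(n_cols):
        col = [str(rec.seq[j]).upper() for rec in aln]
        residues = [c for c in col if c not in GAP_CHARS]
        n_gaps = len(col) - len(residues)
        low_conf = n_gaps > len(col) / 2
        if not residues:
            columns.append((j, None, 0.0, True))
            continue
        residue, count = Counter(residues).most_common(1)[0]
        columns.append((j, residue, count / len(residues), low_conf))
    if master_id is None:
        master = aln[0]
    else:
        match = [r for r in aln if r.id == master_id]
        if not match:
            raise KeyError(f"master sequence {master_id!r} not in alignment")
        master = match[0]
    return ConservationProfile(columns=columns, master_id=master.id, master_seq=str(master.seq))


def conserved_positions(profile: ConservationProfile, threshold: float = 0.90) -> set[int]:
    """Columns whose identity fraction is strictly greater than ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    return {j for j, _res, frac, _lc in profile.columns if frac > threshold}


def _chain_sequence(model: StructureModel, chain_id: str) -> tuple[str, list[ResidueKey]]:
    keys = []
    letters = []
    for key in model.residues(chain_id):
        atoms = model.atoms_of(key)
        if all(a.is_hetero or a.is_water for a in atoms):
            continue
        letters.append(seq1(atoms[0].residue_name, undef_code="X"))
        keys.append(key)
    return "".join(letters), keys


def map_profile_to_chain(
    profile: ConservationProfile, model: StructureModel, chain_id: str
) -> ConservationProfile:
    """Attach a column -> residue mapping by exact ungapped subsequence match.

    The master sequence with gaps removed must occur exactly once... if it
    does not occur in the chain sequence a ValueError shows both sequences.
    """
    chain_seq, keys = _chain_sequence(model, chain_id)
    ungapped = "".join(c for c in profile.master_seq if c not in GAP_CHARS)
    start = chain_seq.find(ungapped)
    if start < 0:
        # also try the chain as a subsequence of the master
        start2 = ungapped.find(chain_seq)
        if start2 < 0:
            raise ValueError(
                "master sequence does not match the chain:\n"
                f"  master: {ungapped}\n  chain : {chain_seq}"
            )
        # chain covers a window of the master
        mapping = {}
        pos = 0  # index in ungapped master
        for j, c in enumerate(profile.master_seq):
            if c in GAP_CHARS:
                continue
            k = pos - start2
            if 0 <= k < len(keys):
                mapping[j] = keys[k]
            pos += 1
        profile.master_map = mapping
        return profile
    mapping = {}
    pos = 0
    for j, c in enumerate(profile.master_seq):
        if c in GAP_CHARS:
            continue
        mapping[j] = keys[start + pos]
        pos += 1
    profile.master_map = mapping
    return profile


@dataclass
class InterfaceConservationReport:
    label: str
    n_contact_residues: int
    n_conserved_contact: int
    background_fraction: float

    @property
    def fraction_conserved_contact(self) -> float:
        if self.n_contact_residues == 0:
            return 0.0
        return self.n_conserved_contact / self.n_contact_residues


def interface_conservation(
    profile: ConservationProfile,
    catalog: list,
    master_chain: str,
    threshold: float = 0.90,
) -> list[InterfaceConservationReport]:
    """Fraction of conserved contact residues per interface.

    ``catalog`` is a list of InterfaceRecord; residues of each record whose
    chain matches ``master_chain`` (symmetry-mate copies included) are looked
    up through the profile's structure mapping.  The background is the
    conserved fraction over all mapped positions of the chain.
    """
    if profile.master_map is None:
        raise ValueError("profile has no structure mapping; call map_profile_to_chain first")
    conserved_cols = conserved_positions(profile, threshold)
    residue_to_col = {}
    for col, key in profile.master_map.items():
        residue_to_col[(key[1], key[2])] = col  # (resnum, icode); chain handled below
    mapped = set(residue_to_col)
    background = (
        sum(1 for rk, col in residue_to_col.items() if col in conserved_cols) / len(mapped)
        if mapped else 0.0
    )

    def is_master(chain_id: str) -> bool:
        return chain_id == master_chain or chain_id.startswith(master_chain + "*")

    reports = []
    for rec in catalog:
        contact = set()
        for key in list(rec.contact_residues_a) + list(rec.contact_residues_b):
            if is_master(key[0]) and (key[1], key[2]) in mapped:
                contact.add((key[1], key[2]))
        n_cons = sum(1 for rk in contact if residue_to_col[rk] in conserved_cols)
        label = f"{rec.classification}:{rec.partner_a}-{rec.partner_b}"
        reports.append(
            InterfaceConservationReport(
                label=label,
                n_contact_residues=len(contact),
                n_conserved_contact=n_cons,
                background_fraction=background,
            )
        )
    return reports
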