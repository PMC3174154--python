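"""Contacts, hydrogen bonds, bridging waters, metal sites, classification,
and the interface catalog on designed fixtures."""
import numpy as np
import pytest

from xtalassoc.interfaces import (
    CatalogConfig,
    catalog_interfaces,
    classify_interface,
    contact_atoms,
    find_bridging_waters,
    find_hbonds,
    find_metal_sites,
)
from xtalassoc.model import StructureModel, UnitCell, select_atoms
from xtalassoc.sasa import SasaParams
from xtalassoc.synth import make_beta_pair, make_c2_dimer, make_toy_crystal

from conftest import make_atom


class TestContacts:
    def test_distant_chains_empty(self):
        atoms = [make_atom(1, "CA", "C", "GLY", 1, "A", [0, 0, 0]),
                 make_atom(2, "CA", "C", "GLY", 1, "B", [20, 0, 0])]
        assert contact_atoms(StructureModel(atoms), {"A"}, {"B"}) == []

    def test_cutoff_is_closed_interval(self):
        atoms = [make_atom(1, "CA", "C", "GLY", 1, "A", [0, 0, 0]),
                 make_atom(2, "CA", "C", "GLY", 1, "B", [6.5, 0, 0])]
        pairs = contact_atoms(StructureModel(atoms), {"A"}, {"B"})
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(6.5)

    def test_matches_brute_force_on_beta_pair(self):
        m, _ = make_beta_pair(8)
        got = {(a.serial, b.serial) for a, b, _ in contact_atoms(m, {"A"}, {"B"}, 6.5)}
        expect = set()
        for a in m.atoms:
            for b in m.atoms:
                if a.chain_id == "A" and b.chain_id == "B":
                    if np.linalg.norm(a.position - b.position) <= 6.5:
                        expect.add((a.serial, b.serial))
        assert got == expect

    def test_empty_selection_errors(self):
        m, _ = make_beta_pair(4)
        with pytest.raises(ValueError):
            contact_atoms(m, {"A"}, {"A"})


class TestHbonds:
    @pytest.mark.parametrize("shift", [0, 1, 2])
    def test_ladder_recovered_exactly(self, shift):
        m, truth = make_beta_pair(8, register_shift=shift)
        found = find_hbonds(m, {"A"}, {"B"})
        got = {(b.donor.chain_id, b.donor.residue_number,
                b.acceptor.chain_id, b.acceptor.residue_number) for b in found}
        expect = {(dc, dr, ac, ar) for dc, dr, ac, ar, _d in truth.bonds}
        assert got == expect
        assert all(b.mainchain_mainchain for b in found)
        assert all(b.distance <= 3.5 for b in found)

    def test_registers_give_distinct_ledgers(self):
        _, t1 = make_beta_pair(8, register_shift=1)
        _, t2 = make_beta_pair(8, register_shift=2)
        assert len(t1.bonds) == 14 and len(t2.bonds) == 12
        assert {b[:4] for b in t1.bonds} != {b[:4] for b in t2.bonds}

    def test_twist_breaks_distal_bonds(self):
        m, truth = make_beta_pair(10, twist=8.0)
        surviving = {b[:4] for b in truth.bonds if b[4] <= 3.5}
        broken = {b[:4] for b in truth.bonds if b[4] > 3.5}
        assert broken, "twist should break at least one designed bond"
        got = {(b.donor.chain_id, b.donor.residue_number,
                b.acceptor.chain_id, b.acceptor.residue_number)
               for b in find_hbonds(m, {"A"}, {"B"})}
        assert got <= surviving
        assert not (got & broken)

    def test_distant_chains_no_bonds(self):
        atoms = [make_atom(1, "N", "N", "GLY", 1, "A", [0, 0, 0]),
                 make_atom(2, "O", "O", "GLY", 1, "B", [20, 0, 0])]
        assert find_hbonds(StructureModel(atoms), {"A"}, {"B"}) == []

    def test_symmetric_under_partner_swap(self):
        m, _ = make_beta_pair(6, register_shift=1)
        ab = find_hbonds(m, {"A"}, {"B"})
        ba = find_hbonds(m, {"B"}, {"A"})
        key = lambda b: (b.donor.serial, b.acceptor.serial)
        assert sorted(map(key, ab)) == sorted(map(key, ba))

    def test_angle_criterion_rejects_blocked_donor(self):
        # acceptor placed on the same side as the antecedent: angle ~ 35 deg
        atoms = [
            make_atom(1, "N", "N", "GLY", 1, "A", [0.0, 0.0, 0.0]),
            make_atom(2, "CA", "C", "GLY", 1, "A", [1.45, 0.0, 0.0]),
            make_atom(3, "O", "O", "GLY", 1, "B", [2.4, 1.6, 0.0]),
        ]
        assert find_hbonds(StructureModel(atoms), {"A"}, {"B"}) == []
        # move the acceptor to the opposite side: accepted
        atoms[2].position[:] = [-2.0, 1.6, 0.0]
        assert len(find_hbonds(StructureModel(atoms), {"A"}, {"B"})) == 1


class TestBridgingWaters:
    def test_no_waters_empty(self):
        m, _ = make_beta_pair(4)
        assert find_bridging_waters(m, {"A"}, {"B"}) == []

    def test_constructed_bridge_found(self):
        atoms = [
            make_atom(1, "O", "O", "GLY", 1, "A", [0.0, 0.0, 0.0]),
            make_atom(2, "O", "O", "GLY", 1, "B", [5.6, 0.0, 0.0]),
            make_atom(3, "O", "O", "HOH", 101, "W", [2.8, 0.0, 0.0], hetero=True),
        ]
        bridges = find_bridging_waters(StructureModel(atoms), {"A"}, {"B"})
        assert len(bridges) == 1
        w, ba, bb = bridges[0]
        assert w.residue_name == "HOH"
        assert ba.distance == pytest.approx(2.8)
        assert bb.distance == pytest.approx(2.8)

    def test_one_sided_water_is_not_a_bridge(self):
        atoms = [
            make_atom(1, "O", "O", "GLY", 1, "A", [0.0, 0.0, 0.0]),
            make_atom(2, "O", "O", "GLY", 1, "B", [12.0, 0.0, 0.0]),
            make_atom(3, "O", "O", "HOH", 101, "W", [2.8, 0.0, 0.0], hetero=True),
        ]
        assert find_bridging_waters(StructureModel(atoms), {"A"}, {"B"}) == []


class TestMetalSites:
    def test_interchain_site(self):
        atoms = [
            make_atom(1, "OD1", "O", "ASP", 10, "A", [2.4, 0.0, 0.0]),
            make_atom(2, "O", "O", "GLY", 11, "A", [0.0, 2.4, 0.0]),
            make_atom(3, "ND1", "N", "HIS", 30, "B", [0.0, 0.0, 2.4]),
            make_atom(4, "CA", "CA", "CA", 90, "A", [0.0, 0.0, 0.0], hetero=True),
        ]
        sites = find_metal_sites(StructureModel(atoms), cutoff=3.0)
        assert len(sites) == 1
        s = sites[0]
        assert len(s.ligands) == 3
        assert s.inter_chain
        assert s.chains_involved == {"A", "B"}

    def test_empty_coordination_shell(self):
        atoms = [
            make_atom(1, "O", "O", "GLY", 1, "A", [4.0, 0.0, 0.0]),
            make_atom(2, "CA", "CA", "CA", 90, "A", [0.0, 0.0, 0.0], hetero=True),
        ]
        sites = find_metal_sites(StructureModel(atoms), cutoff=3.0)
        assert len(sites) == 1
        assert sites[0].ligands == []
        assert not sites[0].inter_chain

    def test_bidentate_carboxylate_flagged(self):
        atoms = [
            make_atom(1, "OD1", "O", "ASP", 5, "A", [2.3, 0.0, 0.0]),
            make_atom(2, "OD2", "O", "ASP", 5, "A", [0.0, 2.3, 0.0]),
            make_atom(3, "O", "O", "GLY", 6, "A", [0.0, 0.0, 2.4]),
            make_atom(4, "ND1", "N", "HIS", 40, "B", [-2.4, 0.0, 0.0]),
            make_atom(5, "CA", "CA", "CA", 90, "A", [0.0, 0.0, 0.0], hetero=True),
        ]
        sites = find_metal_sites(StructureModel(atoms), cutoff=3.0)
        assert sites[0].bidentate_carboxylates == [("A", 5, "")]
        assert sites[0].inter_chain

    def test_ligand_count_bounded_by_brute_force(self):
        m, _ = make_c2_dimer(monomer_size=10, seed=5)
        m.atoms.append(make_atom(999, "CA", "CA", "CA", 90, "A",
                                 m.coords().mean(axis=0), hetero=True))
        cutoff = 3.0
        for s in find_metal_sites(m, cutoff=cutoff):
            n_geom = sum(
                1 for a in m.atoms
                if not a.is_hetero and a.element in ("N", "O", "S")
                and np.linalg.norm(a.position - s.metal.position) <= cutoff
            )
            assert len(s.ligands) == n_geom


class TestClassification:
    ANNOT = {"A": [(1, 10, "b2"), (20, 30, "b4")],
             "B": [(1, 10, "b2"), (20, 30, "b4")]}

    def test_pure_element_contact(self):
        res_a = [("A", i, "") for i in range(1, 6)]
        res_b = [("B", i, "") for i in range(2, 7)]
        assert classify_interface(res_a, res_b, self.ANNOT) == "b2--b2"

    def test_mixed_element_label_sorted(self):
        res_a = [("A", i, "") for i in range(1, 6)]
        res_b = [("B", i, "") for i in range(20, 25)]
        assert classify_interface(res_a, res_b, self.ANNOT) == "b2--b4"

    def test_fifty_fifty_tie_is_other(self):
        res_a = [("A", 1, ""), ("A", 2, ""), ("A", 21, ""), ("A", 22, "")]
        res_b = [("B", 1, ""), ("B", 2, ""), ("B", 3, "")]
        assert classify_interface(res_a, res_b, self.ANNOT) == "other"

    def test_unannotated_contacts_are_other(self):
        res = [("A", 50, ""), ("A", 51, ""), ("A", 52, "")]
        assert classify_interface(res, res, self.ANNOT) == "other"


def _toy_p1_crystal(seed=3, margin=0.5):
    dm, _ = make_c2_dimer(monomer_size=12, seed=seed)
    mono = select_atoms(dm, chain_ids={"A"})
    ext = mono.coords().max(0) - mono.coords().min(0)
    cell = UnitCell(ext[0] + margin, ext[1] + 30, ext[2] + 30)
    return make_toy_crystal(mono, "P 1", cell, (0.5, 0.5, 0.5))


FAST = CatalogConfig(min_delta_asa=5.0, lattice_cutoff=5.0,
                     sasa=SasaParams(n_sphere_points=240))


class TestCatalog:
    def test_single_designed_contact_yields_one_record(self):
        cry = _toy_p1_crystal()
        recs = catalog_interfaces(cry, FAST)
        assert len(recs) == 1
        r = recs[0]
        assert r.operator_triplet is not None
        assert r.delta_asa.delta > 5.0
        assert r.contact_residues_a and r.contact_residues_b

    def test_catalog_deterministic(self):
        cry = _toy_p1_crystal()
        r1 = catalog_interfaces(cry, FAST)
        r2 = catalog_interfaces(cry, FAST)
        assert [x.to_dict() for x in r1] == [x.to_dict() for x in r2]

    def test_relabeling_chains_preserves_records(self):
        m, _ = make_beta_pair(8)
        cfg = CatalogConfig(min_delta_asa=1.0, expand_symmetry=False,
                            sasa=SasaParams(n_sphere_points=240))
        recs = catalog_interfaces(m, cfg)
        swapped = m.copy()
        for a in swapped.atoms:
            a.chain_id = {"A": "B", "B": "A"}[a.chain_id]
        recs2 = catalog_interfaces(swapped, cfg)
        assert len(recs) == len(recs2) == 1
        assert recs[0].delta_asa.delta == pytest.approx(recs2[0].delta_asa.delta)
        assert len(recs[0].hbonds) == len(recs2[0].hbonds)

    def test_min_delta_asa_filters(self):
        cry = _toy_p1_crystal()
        high = CatalogConfig(min_delta_asa=5000.0, lattice_cutoff=5.0,
                             sasa=SasaParams(n_sphere_points=240))
        assert catalog_interfaces(cry, high) == []

    def test_records_sorted_by_buried_surface(self):
        m, _ = make_beta_pair(10)
        cfg = CatalogConfig(min_delta_asa=1.0, expand_symmetry=False,
                            sasa=SasaParams(n_sphere_points=240))
        recs = catalog_interfaces(m, cfg)
        deltas = [r.delta_asa.delta for r in recs]
        assert deltas == sorted(deltas, reverse=True)
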