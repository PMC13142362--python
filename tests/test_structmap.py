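"""Structure parsing, mapping, superposition, SASA and interface analysis."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from faakit.structmap import (
    VDW_RADII,
    buried_interface,
    chain_sequence,
    emit_annotation_script,
    kabsch,
    ligand_contacts,
    map_consensus_to_chain,
    read_structure,
    sasa,
    sphere_points,
    superpose,
)
from faakit.synthetic_data import simulate_structure, write_pdb
from conftest import rotation_matrix

SEQ20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def toy_pdb(tmp_path):
    model, _ = simulate_structure(SEQ20, ligand_placements={10: 3.5})
    p = tmp_path / "toy.pdb"
    write_pdb(model, p)
    return p


class TestReadStructure:
    def test_round_trip_chain_and_ligand(self, toy_pdb):
        model = read_structure(toy_pdb)
        assert set(model.chains) == {"A"}
        assert len(model.chains["A"]) == 20
        assert chain_sequence(model.chains["A"]) == SEQ20
        assert [res.name for _, res in model.ligands] == ["LIG"]

    def test_two_chain_file(self, tmp_path):
        model, _ = simulate_structure(
            SEQ20, dimer_transform=(np.eye(3), np.array([0.0, 50.0, 0.0]))
        )
        p = tmp_path / "dimer.pdb"
        write_pdb(model, p)
        back = read_structure(p)
        assert set(back.chains) == {"A", "B"}
        assert len(back.chains["A"]) == len(back.chains["B"]) == 20

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40  0.00           C\n"
            "END\n"
        )
        model = read_structure(p)
        (res,) = model.chains["A"]
        assert len(res.atoms) == 1
        assert res.atoms[0].coords[0] == pytest.approx(0.0)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(p)


class TestResidueMap:
    def test_identity_mapping(self, toy_pdb):
        model = read_structure(toy_pdb)
        rmap = map_consensus_to_chain(SEQ20, model.chains["A"], "A")
        assert rmap.unmapped == []
        assert rmap.percent_identity == pytest.approx(100.0)
        assert rmap.mapping[1] == ("A", 1, "")
        assert rmap.mapping[20] == ("A", 20, "")

    def test_internal_deletion_leaves_one_residue_unpaired(self, toy_pdb):
        model = read_structure(toy_pdb)
        consensus = SEQ20[:10] + SEQ20[11:]  # drop the 11th residue
        rmap = map_consensus_to_chain(consensus, model.chains["A"], "A")
        assert len(rmap.mapping) == 19
        assert rmap.unmapped == []
        mapped_residues = {num for _, num, _ in rmap.mapping.values()}
        assert 11 not in mapped_residues
        # injective on mapped positions
        assert len(set(rmap.mapping.values())) == len(rmap.mapping)

    def test_empty_chain_errors(self):
        with pytest.raises(ValueError):
            map_consensus_to_chain(SEQ20, [], "A")


class TestLigandContacts:
    @pytest.mark.parametrize(
        "distance,in_contact", [(3.9, True), (4.0, True), (4.1, False)]
    )
    def test_cutoff_inclusive(self, tmp_path, distance, in_contact):
        model, _ = simulate_structure(SEQ20, ligand_placements={10: distance})
        contacts = ligand_contacts(model, "LIG", cutoff=4.0)
        assert (("A", 10, "") in contacts) is in_contact
        if in_contact:
            assert contacts.min_distances[("A", 10, "")] == pytest.approx(distance)

    def test_monotone_in_cutoff(self):
        model, _ = simulate_structure(
            SEQ20, ligand_placements={5: 3.0, 12: 5.0, 18: 7.0}
        )
        sizes = [len(ligand_contacts(model, "LIG", cutoff=c)) for c in (3.5, 5.5, 8.0)]
        assert sizes == sorted(sizes)

    def test_missing_ligand_errors(self):
        model, _ = simulate_structure(SEQ20)
        with pytest.raises(ValueError, match="no ligand"):
            ligand_contacts(model, "DAV")


class TestSuperpose:
    def test_self_superposition_rmsd_zero(self):
        model, _ = simulate_structure(SEQ20)
        result = superpose(model.chains["A"], model.chains["A"])
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_matched == 20

    def test_rigid_copy_rmsd_zero(self):
        R = rotation_matrix([1, 2, 3], 1.1)
        model, _ = simulate_structure(
            SEQ20, dimer_transform=(R, np.array([7.0, -4.0, 11.0]))
        )
        result = superpose(model.chains["A"], model.chains["B"])
        assert result.rmsd < 1e-6
        assert result.n_matched == 20
        # rotation is proper orthonormal
        assert np.allclose(result.rotation @ result.rotation.T, np.eye(3))
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_rmsd_symmetric_and_rigid_invariant(self, nprng):
        P = nprng.normal(size=(15, 3)) * 5
        Q = P + nprng.normal(size=(15, 3)) * 0.4
        r1, r2 = kabsch(P, Q), kabsch(Q, P)
        assert r1.rmsd == pytest.approx(r2.rmsd, abs=1e-9)
        R = rotation_matrix([0, 1, 1], 0.8)
        r3 = kabsch(P @ R.T + np.array([3.0, 2.0, 1.0]), Q)
        assert r3.rmsd == pytest.approx(r1.rmsd, abs=1e-9)

    def test_matches_scipy_svd_oracle(self, nprng):
        """Perturbed 4-point set: residual must equal scipy's closed-form
        Kabsch (Rotation.align_vectors) result."""
        P = np.array(
            [[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 3.8]]
        )
        Q = P.copy()
        Q[2] += [0.5, -0.3, 0.2]
        ours = kabsch(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        rot, rssd = Rotation.align_vectors(Qc, Pc)
        assert ours.rmsd == pytest.approx(rssd / math.sqrt(len(P)), abs=1e-9)
        assert np.allclose(ours.rotation, rot.as_matrix(), atol=1e-9)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSasa:
    def test_single_sphere_matches_analytic_area(self):
        for element, r in (("C", 1.70), ("O", 1.52)):
            area = sasa(np.zeros((1, 3)), [element], probe=1.4, n_points=960)
            analytic = 4 * math.pi * (r + 1.4) ** 2
            assert abs(area[0] - analytic) / analytic < 0.01

    def test_disjoint_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        areas = sasa(coords, ["C", "C"])
        single = sasa(np.zeros((1, 3)), ["C"])[0]
        assert areas[0] == pytest.approx(single)
        assert areas[1] == pytest.approx(single)

    def test_overlapping_spheres_match_dense_quadrature(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        total = sasa(coords, ["C", "N"], n_points=960).sum()
        dense = sasa(coords, ["C", "N"], n_points=100_000).sum()
        assert abs(total - dense) / dense < 0.01

    def test_buried_atom_has_zero_area(self):
        # central atom fully enclosed by a tight shell of neighbours
        shell = sphere_points(30) * 1.0
        coords = np.vstack([np.zeros(3), shell])
        areas = sasa(coords, ["C"] * len(coords))
        assert areas[0] == 0.0

    def test_unknown_element_uses_default_radius(self):
        area = sasa(np.zeros((1, 3)), ["ZZ"])
        expected = 4 * math.pi * (1.70 + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=0.01)


class TestBuriedInterface:
    def test_distant_chains_bury_nothing(self):
        model, _ = simulate_structure(
            "ACDEFGHIKL", dimer_transform=(np.eye(3), np.array([0.0, 100.0, 0.0]))
        )
        report = buried_interface(model, "A", "B")
        assert report.total_buried == pytest.approx(0.0, abs=1e-9)
        assert report.interface_residues == {"A": [], "B": []}

    def test_touching_dimer_matches_dense_quadrature(self):
        model, _ = simulate_structure(
            SEQ20, dimer_transform=(np.eye(3), np.array([0.0, 4.5, 0.0]))
        )
        report = buried_interface(model, "A", "B", n_points=960)
        dense = buried_interface(model, "A", "B", n_points=100_000)
        assert dense.total_buried > 0
        for ch in ("A", "B"):
            rel = abs(report.buried_area[ch] - dense.buried_area[ch])
            assert rel / dense.buried_area[ch] < 0.02

    def test_total_is_sum_of_protomer_burials(self):
        model, _ = simulate_structure(
            SEQ20, dimer_transform=(np.eye(3), np.array([0.0, 4.5, 0.0]))
        )
        report = buried_interface(model, "A", "B")
        assert report.total_buried == pytest.approx(
            report.buried_area["A"] + report.buried_area["B"]
        )
        # symmetric dimer: both protomers bury equal area
        assert report.buried_area["A"] == pytest.approx(
            report.buried_area["B"], rel=0.05
        )

    def test_interface_residue_burials_bounded_by_total(self):
        model, _ = simulate_structure(
            SEQ20, dimer_transform=(np.eye(3), np.array([0.0, 4.5, 0.0]))
        )
        report = buried_interface(model, "A", "B")
        for ch in ("A", "B"):
            per_res = sum(b for *_, b in report.interface_residues[ch])
            assert per_res <= report.buried_area[ch] + 1.0


class TestAnnotationScript:
    def test_lists_residues_per_category(self):
        script = emit_annotation_script({"sdp": [("A", 12), ("A", 45)]})
        assert "select /A:12 /A:45" in script
        assert "color sel red" in script

    def test_empty_categories_give_header_only(self):
        script = emit_annotation_script({"sdp": []})
        assert script.startswith("# residue annotations")
        assert "color" not in script

    def test_deterministic(self):
        cats = {"sdp": [("A", 45), ("A", 12)], "contact": [("B", 3)]}
        assert emit_annotation_script(cats) == emit_annotation_script(
            {"contact": [("B", 3)], "sdp": [("A", 12), ("A", 45)]}
        )
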