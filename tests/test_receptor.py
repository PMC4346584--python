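"""Threading, rotamer ensembles and geometric pocket detection."""

import itertools

import numpy as np
import pytest

from pocketpharm.alignment import ResidueRef
from pocketpharm.fixtures import make_helical_bundle
from pocketpharm.receptor import (
    DEFAULT_ROTAMER_STATES,
    GeometryError,
    RotamerLibraryError,
    attach_rotamers,
    detect_pocket,
    lining_residues,
    model_heavy_atoms,
    prune_tetrahedra,
    read_mol2_atoms,
    read_pdb,
    thread_target,
    write_mol2,
    write_pdb,
)


def _bw_map_from(template, mutations=None):
    mutations = mutations or {}
    return {
        r.bw_label: ResidueRef(
            r.bw_label, r.res_id, mutations.get(r.bw_label, r.amino_acid)
        )
        for r in template.residues
    }


class TestThreading:
    def test_identity_threading(self):
        template = make_helical_bundle(seed=1)
        model, unmatched = thread_target(template, _bw_map_from(template))
        assert unmatched == []
        for orig, new in zip(template.residues, model.residues):
            assert new.amino_acid == orig.amino_acid
            for name in orig.backbone:
                assert np.array_equal(new.backbone[name], orig.backbone[name])

    def test_single_substitution_keeps_backbone(self):
        template = make_helical_bundle(seed=1)
        model, _ = thread_target(template, _bw_map_from(template, {"6.55": "F"}))
        changed = [r for r in model.residues if r.bw_label == "6.55"]
        assert changed[0].amino_acid == "F"
        assert np.array_equal(
            model.backbone_coords(), template.backbone_coords()
        )

    def test_bundle_round_trip_rmsd_zero(self):
        template = make_helical_bundle(seed=2)
        model, _ = thread_target(template, _bw_map_from(template))
        assert model.backbone_coords().shape == template.backbone_coords().shape
        rmsd = np.sqrt(
            np.mean((model.backbone_coords() - template.backbone_coords()) ** 2)
        )
        assert rmsd == 0.0
        assert len(model.helices()) == 7

    def test_unmatched_labels_reported(self):
        template = make_helical_bundle(seed=1)
        bw = _bw_map_from(template)
        removed = "1.40"
        del bw[removed]
        model, unmatched = thread_target(template, bw)
        assert unmatched == [removed]


class TestRotamers:
    def test_alanine_single_state(self):
        template = make_helical_bundle(seed=1, inward_residues={(3, 36): "A"})
        ensemble = attach_rotamers(template)
        res = next(r for r in template.residues if r.bw_label == "3.36")
        states = ensemble.states[res.res_id]
        assert len(states) == 1
        assert states[0].weight == pytest.approx(1.0)

    def test_weights_renormalized(self):
        template = make_helical_bundle(seed=1, inward_residues={(3, 36): "N"})
        library = dict(DEFAULT_ROTAMER_STATES)
        library["N"] = [(0.5, 0.0), (0.3, 40.0), (0.2, -40.0)]
        ensemble = attach_rotamers(template, library)
        res = next(r for r in template.residues if r.bw_label == "3.36")
        weights = [s.weight for s in ensemble.states[res.res_id]]
        assert sum(weights) == pytest.approx(1.0)
        assert weights == pytest.approx([0.5, 0.3, 0.2])

    def test_unnormalized_library_weights(self):
        template = make_helical_bundle(seed=1, inward_residues={(3, 36): "N"})
        library = dict(DEFAULT_ROTAMER_STATES)
        library["N"] = [(2.0, 0.0), (1.0, 40.0), (1.0, -40.0)]
        ensemble = attach_rotamers(template, library)
        res = next(r for r in template.residues if r.bw_label == "3.36")
        weights = [s.weight for s in ensemble.states[res.res_id]]
        assert weights == pytest.approx([0.5, 0.25, 0.25])

    def test_missing_residue_type_raises(self):
        template = make_helical_bundle(seed=1)
        library = {k: v for k, v in DEFAULT_ROTAMER_STATES.items() if k != "L"}
        with pytest.raises(RotamerLibraryError, match="'L'"):
            attach_rotamers(template, library)

    def test_every_residue_has_a_rotamer(self):
        template = make_helical_bundle(seed=3)
        ensemble = attach_rotamers(template)
        for res in template.residues:
            assert len(ensemble.states[res.res_id]) >= 1


def _brute_force_retained(points, cutoff, tri):
    keep = []
    for si, simplex in enumerate(tri.simplices):
        ok = True
        for i, j in itertools.combinations(range(4), 2):
            if np.linalg.norm(points[simplex[i]] - points[simplex[j]]) > cutoff:
                ok = False
                break
        if ok:
            keep.append(si)
    return np.array(keep)


class TestPruning:
    def test_regular_tetrahedron_short_edges_retained(self):
        pts = 5.0 * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        ) / np.sqrt(8)  # regular tetrahedron, edge 5 A
        tri, retained = prune_tetrahedra(pts, 8.0)
        assert len(retained) == 1

    def test_regular_tetrahedron_long_edges_removed(self):
        pts = 9.0 * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        ) / np.sqrt(8)  # edge 9 A
        _, retained = prune_tetrahedra(pts, 8.0)
        assert len(retained) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 20, size=(50, 3))
        tri, retained = prune_tetrahedra(pts, 8.0)
        assert np.array_equal(np.sort(retained), np.sort(_brute_force_retained(pts, 8.0, tri)))

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 20, size=(60, 3))
        _, r1 = prune_tetrahedra(pts, 6.0)
        _, r2 = prune_tetrahedra(pts, 9.0)
        assert set(r1.tolist()) <= set(r2.tolist())

    def test_degenerate_coplanar_rejected(self):
        pts = np.zeros((10, 3))
        pts[:, :2] = np.random.default_rng(0).uniform(0, 5, size=(10, 2))
        with pytest.raises(GeometryError):
            prune_tetrahedra(pts, 8.0)


class TestPocket:
    def test_rigid_motion_equivariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 20, size=(60, 3))
        pocket = detect_pocket(pts, 8.0)
        R = Rotation.from_euler("xyz", [0.3, -0.9, 1.7]).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = detect_pocket(pts @ R.T + t, 8.0)
        # triangulations agree combinatorially (qhull may reorder simplices)
        def vertex_sets(p):
            return {
                frozenset(s.tolist()) for s in p.delaunay.simplices[p.retained]
            }
        assert vertex_sets(pocket) == vertex_sets(moved)
        expected = np.array(sorted((pocket.cloud @ R.T + t).round(5).tolist()))
        got = np.array(sorted(moved.cloud.round(5).tolist()))
        assert np.allclose(expected, got, atol=1e-6)

    def test_pocket_points_inside_convex_hull(self, scenario_chain):
        pocket = scenario_chain["pocket"]
        hull = pocket.delaunay  # the triangulation covers the hull
        assert np.all(hull.find_simplex(pocket.cloud) >= 0)

    def test_central_pocket_lined_by_three_helices(self, scenario_chain):
        pocket = scenario_chain["pocket"]
        tri = pocket.delaunay
        assert len(pocket.pocket_simplices) > 0
        # pocket cloud hugs the bundle axis, not the membrane side
        radial = np.linalg.norm(pocket.cloud[:, :2], axis=1)
        assert np.median(radial) < 6.0

    def test_lining_includes_paper_key_residues(self, scenario_chain):
        labels = {r.bw_label for r in scenario_chain["lining"]}
        assert {"3.36", "5.45", "6.55", "7.39"} <= labels

    def test_zero_contact_distance_empty_lining(self, scenario_chain):
        lining = lining_residues(
            scenario_chain["pocket"],
            scenario_chain["model"],
            scenario_chain["ensemble"],
            contact_distance=0.0,
        )
        assert lining == set()

    def test_inward_residues_line_the_pocket(self):
        bundle = make_helical_bundle(
            seed=4, inward_residues={(3, 36): "N", (5, 45): "T"}
        )
        ensemble = attach_rotamers(bundle)
        coords, elements, helices = model_heavy_atoms(bundle, ensemble)
        pocket = detect_pocket(coords, 8.0, elements=elements, atom_helices=helices)
        lining = lining_residues(pocket, bundle, ensemble)
        labels = {r.bw_label for r in lining}
        assert {"3.36", "5.45"} <= labels


class TestStructureIO:
    def test_mol2_round_trip(self, tmp_path):
        bundle = make_helical_bundle(seed=1)
        ensemble = attach_rotamers(bundle)
        path = tmp_path / "model.mol2"
        write_mol2(bundle, path, ensemble)
        coords, names, res_ids, res_names = read_mol2_atoms(path)
        expected, _, _ = model_heavy_atoms(bundle, ensemble)
        assert coords.shape == expected.shape
        assert np.allclose(coords, expected, atol=1e-3)

    def test_pdb_round_trip(self, tmp_path):
        bundle = make_helical_bundle(seed=1)
        path = tmp_path / "model.pdb"
        write_pdb(bundle, path)
        again = read_pdb(path)
        assert len(again.residues) == len(bundle.residues)
        orig = np.array([r.ca for r in bundle.residues])
        back = np.array([r.ca for r in again.residues])
        assert np.allclose(orig, back, atol=1e-2)
        assert [r.amino_acid for r in again.residues] == [
            r.amino_acid for r in bundle.residues
        ]
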