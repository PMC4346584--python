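"""Compound preparation, typing and combinatorial subset matching."""

import itertools
import math

import numpy as np
import pytest

from pocketpharm.screening import (
    Compound,
    TypedPoint,
    _evaluate_assignment,
    _type_assignments,
    assign_types,
    conformer_point_sets,
    enumerate_subsets,
    generate_conformers,
    load_compounds,
    match_subset,
    screen_library,
)

FLAVANONE_6_OME = "O=C1CC(c2ccccc2)Oc2ccc(OC)cc21"
KAEMPFEROL = "O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12"


def _mol(smiles):
    from rdkit import Chem

    return Chem.MolFromSmiles(smiles)


class TestLoading:
    def test_racemic_flavanone_expands_to_two_enantiomers(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text(
            "id\tsmiles\tactivity\nblocker1\t" + FLAVANONE_6_OME + "\tblocker\n"
        )
        compounds, errors = load_compounds(str(path))
        assert errors == []
        assert len(compounds) == 2
        assert {c.parent_id for c in compounds} == {"blocker1"}
        assert {c.stereo for c in compounds} == {"R", "S"}

    def test_achiral_compound_stays_single(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text("id\tsmiles\tactivity\nx\tc1ccccc1O\tactive\n")
        compounds, errors = load_compounds(str(path))
        assert len(compounds) == 1 and errors == []

    def test_unparsable_record_collected_not_fatal(self, tmp_path):
        path = tmp_path / "lib.tsv"
        path.write_text(
            "id\tsmiles\tactivity\nok\tCCO\tactive\nbad\tnot_a_smiles(\tactive\n"
        )
        compounds, errors = load_compounds(str(path))
        assert len(compounds) == 1
        assert len(errors) == 1 and "bad" in errors[0]

    def test_lab_set_scale_counts(self, tmp_path):
        """An 85-row table with 66 actives and 19 inactives keeps its label
        split through loading."""
        rows = ["id\tsmiles\tactivity"]
        for i in range(66):
            rows.append(f"a{i}\tCCO\tactive")
        for i in range(19):
            rows.append(f"i{i}\tCCN\tinactive")
        path = tmp_path / "lab.tsv"
        path.write_text("\n".join(rows) + "\n")
        compounds, errors = load_compounds(str(path))
        labels = [c.activity for c in compounds]
        assert labels.count("active") == 66
        assert labels.count("inactive") == 19


class TestConformers:
    def test_benzene_single_conformer(self):
        comp = Compound("benzene", "benzene", "unknown", mol=_mol("c1ccccc1"))
        mol = generate_conformers(comp, seed=3)
        assert mol.GetNumConformers() == 1

    def test_butane_multiple_rotamer_families(self):
        comp = Compound("butane", "butane", "unknown", mol=_mol("CCCC"))
        mol = generate_conformers(comp, seed=3)
        assert mol.GetNumConformers() >= 2
        # anti/gauche families differ in the C1-C4 distance
        d14 = []
        for conf in mol.GetConformers():
            heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C"]
            p = conf.GetPositions()
            d14.append(np.linalg.norm(p[heavy[0]] - p[heavy[3]]))
        assert max(d14) - min(d14) > 0.3

    def test_seeded_determinism(self):
        comp = Compound("nar", "nar", "unknown", mol=_mol("O=C1CC(c2ccccc2)Oc2ccccc21"))
        m1 = generate_conformers(comp, seed=11)
        m2 = generate_conformers(comp, seed=11)
        assert m1.GetNumConformers() == m2.GetNumConformers()
        for c1, c2 in zip(m1.GetConformers(), m2.GetConformers()):
            assert np.allclose(c1.GetPositions(), c2.GetPositions())

    def test_conformation_limit_respected(self):
        comp = Compound("flex", "flex", "unknown", mol=_mol("CCCCCCCCCC"))
        mol = generate_conformers(comp, params={"conformation_limit": 5}, seed=1)
        assert mol.GetNumConformers() <= 5


class TestTyping:
    def _typed(self, smiles, seed=5):
        comp = Compound("x", "x", "unknown", mol=_mol(smiles))
        mol = generate_conformers(comp, params={"conformation_limit": 3}, seed=seed)
        return assign_types(mol, mol.GetConformers()[0].GetId())

    def test_methoxyflavanone_has_no_donor(self):
        points = self._typed(FLAVANONE_6_OME)
        assert sum(1 for p in points if p.type == "donor") == 0
        assert sum(1 for p in points if p.type == "acceptor") >= 2

    def test_kaempferol_donor_acceptor_counts(self):
        points = self._typed(KAEMPFEROL)
        assert sum(1 for p in points if p.type == "donor") >= 4
        assert sum(1 for p in points if p.type == "acceptor") >= 4

    def test_phenol_typing(self):
        points = self._typed("Oc1ccccc1")
        by_type = {
            t: sum(1 for p in points if p.type == t)
            for t in ("donor", "acceptor", "hydrophobic")
        }
        assert by_type == {"donor": 1, "acceptor": 1, "hydrophobic": 1}

    def test_fluorine_weak_acceptor_flag(self):
        comp = Compound("fb", "fb", "unknown", mol=_mol("Fc1ccccc1"))
        mol = generate_conformers(comp, params={"conformation_limit": 1}, seed=2)
        on = assign_types(mol, fluorine_acceptor=True)
        off = assign_types(mol, fluorine_acceptor=False)
        n_on = sum(1 for p in on if p.type == "acceptor")
        n_off = sum(1 for p in off if p.type == "acceptor")
        assert n_on == n_off + 1


def _points_at(pharm, indices, jitter=0.0, rng=None, extra=()):
    pts = []
    for i in indices:
        f = pharm[i]
        pos = f.center.copy()
        if jitter and rng is not None:
            pos = pos + rng.normal(scale=jitter, size=3)
        pts.append(TypedPoint(f.type, pos, (i,)))
    pts.extend(extra)
    return pts


class TestMatching:
    def test_identity_geometry_matches_with_zero_rmsd(self, simple_pharmacophore):
        subset = [0, 3, 6, 7, 8]
        points = _points_at(simple_pharmacophore, subset)
        result = match_subset(points, simple_pharmacophore.subset(subset))
        assert result.matched
        assert result.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_beyond_radius_displacement_never_matches(self, simple_pharmacophore):
        subset = [0, 3, 6, 7, 8]
        points = _points_at(simple_pharmacophore, subset)
        # push one point 2 x radius along the line away from the others
        centroid = np.mean([p.position for p in points], axis=0)
        p0 = points[0]
        direction = p0.position - centroid
        direction = direction / np.linalg.norm(direction)
        moved = TypedPoint(p0.type, p0.position + 2.0 * 1.0 * direction * 2, (0,))
        result = match_subset(
            [moved] + points[1:], simple_pharmacophore.subset(subset)
        )
        assert not result.matched

    def test_rigid_motion_invariance(self, simple_pharmacophore):
        from scipy.spatial.transform import Rotation

        subset = [0, 3, 6, 7, 8]
        rng = np.random.default_rng(6)
        points = _points_at(simple_pharmacophore, subset, jitter=0.2, rng=rng)
        base = match_subset(points, simple_pharmacophore.subset(subset))
        R = Rotation.from_euler("zyx", [1.1, -0.4, 2.2]).as_matrix()
        t = np.array([13.0, -7.0, 4.0])
        moved = [TypedPoint(p.type, R @ p.position + t, p.source_atoms) for p in points]
        again = match_subset(moved, simple_pharmacophore.subset(subset))
        assert base.matched == again.matched
        assert base.max_normalized_deviation == pytest.approx(
            again.max_normalized_deviation, abs=1e-6
        )

    def test_six_subset_match_implies_contained_five_subsets(
        self, simple_pharmacophore
    ):
        rng = np.random.default_rng(9)
        subset6 = (0, 1, 3, 6, 7, 8)
        for _ in range(5):
            points = _points_at(simple_pharmacophore, subset6, jitter=0.25, rng=rng)
            res6 = match_subset(points, simple_pharmacophore.subset(subset6))
            if not res6.matched:
                continue
            for subset5 in itertools.combinations(subset6, 5):
                res5 = match_subset(points, simple_pharmacophore.subset(subset5))
                assert res5.matched, subset5

    def test_missing_type_cannot_match(self, simple_pharmacophore):
        subset = [0, 3, 6, 7, 8]  # contains donor feature 3
        points = [
            p
            for p in _points_at(simple_pharmacophore, subset)
            if p.type != "donor"
        ]
        result = match_subset(points, simple_pharmacophore.subset(subset))
        assert not result.matched
        assert result.assignment is None

    def test_mirror_symmetry_of_matching(self, simple_pharmacophore):
        """Reflecting both ligand and features preserves the verdict."""
        from pocketpharm.pharmacophore import Feature, Pharmacophore

        subset = [0, 3, 6, 7, 8]
        rng = np.random.default_rng(21)
        points = _points_at(simple_pharmacophore, subset, jitter=0.3, rng=rng)
        mirror = np.diag([-1.0, 1.0, 1.0])
        mirrored_points = [
            TypedPoint(p.type, mirror @ p.position, p.source_atoms) for p in points
        ]
        mirrored_features = [
            Feature(
                index=f.index,
                type=f.type,
                center=mirror @ f.center,
                radius=f.radius,
                contributions=f.contributions,
            )
            for f in simple_pharmacophore.subset(subset)
        ]
        r1 = match_subset(points, simple_pharmacophore.subset(subset))
        r2 = match_subset(mirrored_points, mirrored_features)
        assert r1.matched == r2.matched
        assert r1.max_normalized_deviation == pytest.approx(
            r2.max_normalized_deviation, abs=1e-5
        )

    def test_enumeration_matches_brute_force(self, simple_pharmacophore):
        """The assignment search visits exactly the type-compatible
        injections an independent itertools enumeration produces."""
        rng = np.random.default_rng(31)
        subset = [0, 3, 6, 7, 8]
        features = simple_pharmacophore.subset(subset)
        extra = [
            TypedPoint("hydrophobic", rng.uniform(0, 10, 3), (91,)),
            TypedPoint("acceptor", rng.uniform(0, 10, 3), (92,)),
            TypedPoint("donor", rng.uniform(0, 10, 3), (93,)),
        ]
        points = _points_at(simple_pharmacophore, subset, jitter=0.4, rng=rng, extra=extra)
        got = sorted(_type_assignments(points, features))

        slots = {t: [i for i, f in enumerate(features) if f.type == t] for t in
                 ("acceptor", "donor", "hydrophobic")}
        cands = {t: [i for i, p in enumerate(points) if p.type == t] for t in slots}
        expected = set()
        for pa in itertools.permutations(cands["acceptor"], len(slots["acceptor"])):
            for pd in itertools.permutations(cands["donor"], len(slots["donor"])):
                for ph in itertools.permutations(
                    cands["hydrophobic"], len(slots["hydrophobic"])
                ):
                    assignment = [None] * len(features)
                    for s, v in zip(slots["acceptor"], pa):
                        assignment[s] = v
                    for s, v in zip(slots["donor"], pd):
                        assignment[s] = v
                    for s, v in zip(slots["hydrophobic"], ph):
                        assignment[s] = v
                    expected.add(tuple(assignment))
        assert set(got) == expected

        # and the reported best equals the brute-force argmin
        Q = np.array([f.center for f in features])
        radii = np.array([f.radius for f in features])
        positions = np.array([p.position for p in points])
        best = min(
            _evaluate_assignment(positions[list(a)], Q, radii)[0] for a in expected
        )
        result = match_subset(points, features)
        assert result.max_normalized_deviation == pytest.approx(best, abs=1e-6)


class TestSubsetsAndScreening:
    def test_binomial_subset_counts(self):
        subsets = enumerate_subsets(9, (5, 6))
        assert len(subsets[5]) == 126
        assert len(subsets[6]) == 84

    def test_planted_hit_found_for_its_subset(self, simple_pharmacophore):
        subset = (0, 3, 6, 7, 8)
        hit = Compound(
            "hit",
            "hit",
            "active",
            point_sets=[_points_at(simple_pharmacophore, subset)],
        )
        hits = screen_library([hit], simple_pharmacophore, k_values=(5,))
        assert len(hits) == 126
        row = hits[hits["subset"] == subset]
        assert bool(row["matched"].iloc[0])

    def test_blocker_like_body_avoids_donor_subsets(self, simple_pharmacophore):
        subset = (0, 1, 2, 7, 8)  # acceptors + hydrophobics only
        blocker = Compound(
            "blk",
            "blk",
            "blocker",
            point_sets=[_points_at(simple_pharmacophore, subset)],
        )
        hits = screen_library([blocker], simple_pharmacophore, k_values=(5, 6))
        matched = hits[hits["matched"]]["subset"].tolist()
        assert subset in matched
        donor_features = {3, 4, 5}
        for s in matched:
            assert not (set(s) & donor_features)

    def test_chemical_mode_end_to_end_small(self, simple_pharmacophore, tmp_path):
        """A real molecule passes through conformers and typing into the
        hit table without errors."""
        comp = Compound("phenol", "phenol", "active", mol=_mol("Oc1ccccc1"))
        point_sets = conformer_point_sets(
            comp, params={"conformation_limit": 2}, seed=4
        )
        assert all(len(ps) >= 1 for ps in point_sets)
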