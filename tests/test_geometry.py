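"""Rigid-body operations: translation, rotation, superposition, merging."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

import clickchem as cc
from clickchem.geometry import Tether

from conftest import random_molecule


def _random_rigid(rng):
    return Rotation.random(rng=rng).as_matrix(), rng.normal(size=3) * 5.0


class TestTranslate:
    def test_zero_is_identity(self, panel):
        mol = panel["methane"]
        assert np.array_equal(cc.translate(mol, [0, 0, 0]).coords, mol.coords)

    def test_shift_and_inverse(self, panel):
        mol = panel["methane"]
        moved = cc.translate(mol, [1, 2, 3])
        np.testing.assert_allclose(moved.atoms[0].coord - mol.atoms[0].coord, [1, 2, 3])
        back = cc.translate(moved, [-1, -2, -3])
        assert np.abs(back.coords - mol.coords).max() < 1e-12

    def test_bonds_unchanged(self, panel):
        mol = panel["ethane"]
        assert cc.translate(mol, [3, 0, 0]).bonds == mol.bonds


class TestSetAtomLocation:
    def test_moves_atom_to_target(self, panel):
        mol = cc.set_atom_location(panel["methane"], 0, [0, 0, 0])
        np.testing.assert_allclose(mol.atoms[0].coord, [0, 0, 0], atol=1e-12)

    def test_noop_at_current_position(self, panel):
        mol = panel["methane"]
        same = cc.set_atom_location(mol, 1, mol.atoms[1].coord)
        assert np.abs(same.coords - mol.coords).max() < 1e-12

    def test_pairwise_distances_preserved(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mol = random_molecule(rng, 12)
            before = pdist(mol.coords)
            moved = cc.set_atom_location(mol, int(rng.integers(12)), rng.normal(size=3))
            assert np.abs(pdist(moved.coords) - before).max() < 1e-9

    def test_invalid_index(self, panel):
        with pytest.raises(IndexError):
            cc.set_atom_location(panel["methane"], 99, [0, 0, 0])


class TestRotations:
    def test_zero_and_full_turn_identity(self, panel):
        mol = panel["ethanol"]
        for angle in (0.0, 2 * np.pi):
            out = cc.rotate_about_line(mol, [0, 0, 0], [0, 0, 1], angle)
            assert np.abs(out.coords - mol.coords).max() < 1e-9

    def test_quarter_turn_closed_form(self):
        mol = cc.Molecule(atoms=[cc.Atom("C", [1, 0, 0])])
        out = cc.rotate_about_line(mol, [0, 0, 0], [0, 0, 1], np.pi / 2)
        np.testing.assert_allclose(out.atoms[0].coord, [0, 1, 0], atol=1e-9)

    def test_degenerate_axis(self, panel):
        with pytest.raises(ValueError, match="degenerate"):
            cc.rotate_about_line(panel["methane"], [1, 1, 1], [1, 1, 1], 0.3)

    def test_bond_atoms_fixed(self, panel):
        mol = panel["ethane"]
        out = cc.rotate_about_bond(mol, 0, 1, 1.1)
        assert np.abs(out.coords[[0, 1]] - mol.coords[[0, 1]]).max() < 1e-9

    def test_ethane_c3_symmetry(self, panel):
        # rotating 120 degrees about the C-C bond maps staggered H onto H
        mol = panel["ethane"]
        out = cc.rotate_about_bond(mol, 0, 1, 2 * np.pi / 3)
        d = cdist(out.coords, mol.coords)
        assert max(d.min(axis=0).max(), d.min(axis=1).max()) < 1e-6

    def test_pivot_composition_matches_matrix_product(self):
        rng = np.random.default_rng(11)
        mol = random_molecule(rng, 8)
        pivot, axis = rng.normal(size=3), [0, 1, 0]
        twice = cc.rotate_about_pivot(
            cc.rotate_about_pivot(mol, pivot, axis, np.pi / 2), pivot, axis, np.pi / 2
        )
        once = cc.rotate_about_pivot(mol, pivot, axis, np.pi)
        assert np.abs(twice.coords - once.coords).max() < 1e-9

    def test_pivot_point_fixed(self, panel):
        mol = panel["methane"]
        out = cc.rotate_about_pivot(mol, mol.atoms[0].coord, [1, 1, 0], 0.7)
        assert np.abs(out.atoms[0].coord - mol.atoms[0].coord).max() < 1e-12

    def test_rigidity_of_all_rotations(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            mol = random_molecule(rng, 10)
            before = pdist(mol.coords)
            for out in (
                cc.rotate_about_line(mol, rng.normal(size=3), rng.normal(size=3) + 5, 1.0),
                cc.rotate_about_pivot(mol, rng.normal(size=3), rng.normal(size=3), 0.5),
            ):
                assert np.abs(pdist(out.coords) - before).max() < 1e-9


class TestAlignByTethers:
    def test_self_alignment_is_identity(self, panel):
        mol = panel["benzene"]
        res = cc.align_by_tethers(mol, mol, [Tether(i, i) for i in range(4)])
        assert res.residual < 1e-20
        assert np.abs(res.molecule.coords - mol.coords).max() < 1e-9

    def test_single_tether_zeroes_length(self):
        rng = np.random.default_rng(2)
        a, b = random_molecule(rng, 6), random_molecule(rng, 6)
        res = cc.align_by_tethers(a, b, [Tether(2, 4)])
        assert np.linalg.norm(res.molecule.atoms[2].coord - b.atoms[4].coord) < 1e-12

    def test_recovery_of_known_transform(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mol = random_molecule(rng, 5)
            R, t = _random_rigid(rng)
            moved = mol.copy()
            moved.set_coords(mol.coords @ R.T + t)
            res = cc.align_by_tethers(moved, mol, [Tether(i, i) for i in range(5)])
            assert np.abs(res.molecule.coords - mol.coords).max() < 1e-6
            assert res.residual < 1e-10

    def test_local_optimality_probe(self):
        # no random rigid perturbation of the returned pose does better
        rng = np.random.default_rng(23)
        for _ in range(500):
            mobile = random_molecule(rng, 6)
            reference = random_molecule(rng, 6)
            tethers = [Tether(i, i) for i in range(4)]
            res = cc.align_by_tethers(mobile, reference, tethers)
            P = np.array([res.molecule.atoms[t.mobile_index].coord for t in tethers])
            Q = np.array([reference.atoms[t.target_index].coord for t in tethers])
            base = float(np.sum((P - Q) ** 2))
            center = P.mean(axis=0)
            for _ in range(100):
                R = Rotation.from_rotvec(rng.normal(size=3) * 0.05).as_matrix()
                t = rng.normal(size=3) * 0.02
                trial = (P - center) @ R.T + center + t
                assert np.sum((trial - Q) ** 2) >= base - 1e-9

    def test_requires_a_tether(self, panel):
        with pytest.raises(ValueError):
            cc.align_by_tethers(panel["methane"], panel["methane"], [])


class TestMergeAndDistance:
    def test_merge_counts_and_coordinates(self, panel):
        a, b = panel["methane"], panel["ethanol"]
        m = cc.merge(a, b)
        assert len(m) == len(a) + len(b)
        assert len(m.bonds) == len(a.bonds) + len(b.bonds)
        assert np.array_equal(m.coords[: len(a)], a.coords)
        assert np.array_equal(m.coords[len(a):], b.coords)

    def test_merge_with_empty_is_identity(self, panel):
        a = panel["methane"]
        m = cc.merge(a, cc.Molecule())
        assert len(m) == len(a) and m.bonds == a.bonds

    def test_two_atoms_three_angstrom(self):
        a = cc.Molecule(atoms=[cc.Atom("C", [0, 0, 0])])
        b = cc.Molecule(atoms=[cc.Atom("C", [3, 0, 0])])
        assert cc.min_intermolecular_distance(a, b) == pytest.approx(3.0)

    def test_identical_copies_zero(self, panel):
        mol = panel["benzene"]
        assert cc.min_intermolecular_distance(mol, mol.copy()) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        a, b = random_molecule(rng, 50), random_molecule(rng, 50)
        brute = min(
            float(np.linalg.norm(x.coord - y.coord))
            for x in a.atoms
            for y in b.atoms
        )
        assert abs(cc.min_intermolecular_distance(a, b) - brute) < 1e-12

    def test_empty_molecule_error(self, panel):
        with pytest.raises(ValueError):
            cc.min_intermolecular_distance(panel["methane"], cc.Molecule())
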