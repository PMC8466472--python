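"""LNP shell composition and molecular packing objective/minimizer."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from mrnaplant.errors import InvalidInputError
from mrnaplant.lnp import (Molecule, PackingProblem, ShellSpec,
                           area_per_lipid, inside_box, inside_sphere,
                           minimize_packing, packing_objective, read_xyz,
                           shell_counts, write_pdb, write_xyz)

REFERENCE_COUNTS = {"DSPC": 620, "CHOL": 2876, "DDAB": 2280, "PEG": 124,
                    "DOPE": 0}


class TestShellComposition:
    def test_reference_particle_counts(self):
        """A 250 Angstrom particle at the area-per-lipid implied by its
        3024 surface lipids reproduces the reference composition exactly."""
        apl = area_per_lipid(250.0, 3024)
        spec = ShellSpec(apl=apl)
        assert shell_counts(spec) == REFERENCE_COUNTS

    def test_rounded_apl_stays_close(self):
        # at the 2-significant-figure APL of 0.65 nm^2 the surface pool is
        # 3021 rather than 3024, so counts shift by up to a few molecules
        counts = shell_counts(ShellSpec(apl=0.65))
        for species, want in REFERENCE_COUNTS.items():
            assert abs(counts[species] - want) <= 3

    def test_huge_apl_empties_shell(self):
        counts = shell_counts(ShellSpec(apl=1e9))
        assert all(v == 0 for v in counts.values())

    def test_surface_scaling_with_diameter(self):
        small = shell_counts(ShellSpec(particle_diameter=250.0))
        large = shell_counts(ShellSpec(particle_diameter=500.0))
        total = lambda c: sum(v for k, v in c.items() if k != "CHOL")
        assert total(large) == pytest.approx(4 * total(small), abs=2)

    def test_zero_apl_rejected(self):
        with pytest.raises(InvalidInputError):
            shell_counts(ShellSpec(apl=0.0))

    @pytest.mark.parametrize("diameter, count, expected", [
        (250.0, 3024, 0.649),    # surface-species reading
        (250.0, 5900, 0.333),    # all-species alternative reading
    ])
    def test_area_per_lipid(self, diameter, count, expected):
        assert area_per_lipid(diameter, count) == pytest.approx(expected,
                                                                abs=1e-3)

    def test_area_per_lipid_identity(self):
        # count numerically equal to the surface area in nm^2 -> APL = 1
        spec = ShellSpec()
        area = spec.surface_area_nm2()
        assert area_per_lipid(spec.particle_diameter, area) \
            == pytest.approx(1.0)


def single_atoms(positions):
    mols = [Molecule("X", np.zeros((1, 3))) for _ in positions]
    return PackingProblem(mols, np.asarray(positions, dtype=float),
                          np.zeros((len(positions), 3)))


class TestPackingObjective:
    def test_separated_pair_is_feasible(self):
        assert packing_objective(single_atoms([[0, 0, 0], [5, 0, 0]])) == 0.0

    def test_coincident_pair_penalty(self):
        # d_tol^2 - 0 = 4, squared = 16
        assert packing_objective(single_atoms([[1, 1, 1], [1, 1, 1]])) == 16.0

    def test_matches_brute_force_oracle(self):
        """Vectorised objective equals an explicit per-pair double loop with
        hand-built rotation matrices."""
        rng = np.random.default_rng(11)
        mols = [Molecule(f"M{i}", rng.normal(size=(4, 3)))
                for i in range(5)]
        centers = rng.uniform(-4, 4, size=(5, 3))
        angles = rng.uniform(0, 2 * math.pi, size=(5, 3))
        problem = PackingProblem(mols, centers, angles, d_tol=2.0)

        def rot(a, b, c):
            rx = np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)],
                           [0, math.sin(a), math.cos(a)]])
            ry = np.array([[math.cos(b), 0, math.sin(b)], [0, 1, 0],
                           [-math.sin(b), 0, math.cos(b)]])
            rz = np.array([[math.cos(c), -math.sin(c), 0],
                           [math.sin(c), math.cos(c), 0], [0, 0, 1]])
            return rz @ ry @ rx   # extrinsic x-y-z order

        placed = [centers[i] + mols[i].atoms @ rot(*angles[i]).T
                  for i in range(5)]
        expected = 0.0
        for i in range(5):
            for k in range(i + 1, 5):
                for p in placed[i]:
                    for q in placed[k]:
                        arg = 4.0 - np.linalg.norm(p - q)
                        expected += max(0.0, arg) ** 2
        assert packing_objective(problem) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        mols = [Molecule(f"M{i}", rng.normal(size=(3, 3))) for i in range(4)]
        centers = rng.uniform(-3, 3, size=(4, 3))
        angles = np.zeros((4, 3))
        base = PackingProblem(mols, centers, angles)
        f0 = packing_objective(base)
        shift = np.array([10.0, -4.0, 2.5])
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        moved = PackingProblem(
            mols, rot.apply(centers) + shift,
            np.tile(rot.as_euler("xyz"), (4, 1)))
        # rotating every molecule by the same extrinsic rotation and moving
        # the centers rigidly preserves all inter-atomic distances
        assert packing_objective(moved) == pytest.approx(f0, rel=1e-9,
                                                         abs=1e-9)

    def test_rotation_preserves_internal_distances(self):
        rng = np.random.default_rng(1)
        mol = Molecule("M", rng.normal(size=(6, 3)))
        problem = PackingProblem([mol], [[0, 0, 0]], [[0.7, -0.2, 1.9]])
        placed = problem.placed_atoms()[0]
        d_orig = np.linalg.norm(mol.atoms[:, None] - mol.atoms[None], axis=-1)
        d_new = np.linalg.norm(placed[:, None] - placed[None], axis=-1)
        np.testing.assert_allclose(d_new, d_orig, atol=1e-9)

    def test_constraint_penalty(self):
        problem = single_atoms([[3.0, 0, 0]])
        problem.constraints = {None: [inside_sphere(2.0)]}
        assert packing_objective(problem) == pytest.approx(1.0)


class TestMinimizePacking:
    def test_ten_atoms_in_box(self):
        problem = single_atoms([[0, 0, 0]] * 10)
        problem.constraints = {None: [inside_box(20.0)]}
        result = minimize_packing(problem, seed=42, restarts=30,
                                  box_half_extent=20.0)
        assert result.objective <= 1e-6
        assert result.feasible

    def test_unbounded_pair(self):
        problem = single_atoms([[0, 0, 0], [0.5, 0, 0]])
        result = minimize_packing(problem, seed=0, restarts=10)
        assert result.objective == 0.0

    def test_deterministic_for_seed(self):
        problem = single_atoms([[0, 0, 0]] * 4)
        r1 = minimize_packing(problem, seed=9, restarts=5)
        r2 = minimize_packing(problem, seed=9, restarts=5)
        assert r1.objective == r2.objective
        np.testing.assert_array_equal(r1.problem.barycenters,
                                      r2.problem.barycenters)

    def test_infeasible_box_flags(self):
        # 8 atoms forced inside a sphere far too small for 2 A separation
        problem = single_atoms([[0, 0, 0]] * 8)
        problem.constraints = {None: [inside_sphere(0.5)]}
        result = minimize_packing(problem, seed=2, restarts=3,
                                  box_half_extent=0.5)
        assert not result.feasible
        assert result.objective > 0


class TestCoordinateIO:
    def test_xyz_round_trip(self, tmp_path):
        problem = single_atoms([[1.5, -2.0, 3.25], [0.0, 4.0, -1.0]])
        path = tmp_path / "config.xyz"
        write_xyz(path, problem, comment="test")
        atoms = read_xyz(path)
        assert len(atoms) == 2
        np.testing.assert_allclose(atoms[0][1], [1.5, -2.0, 3.25])

    def test_pdb_has_atom_records(self, tmp_path):
        problem = single_atoms([[0, 0, 0], [3, 0, 0]])
        path = tmp_path / "config.pdb"
        write_pdb(path, problem)
        text = path.read_text()
        assert text.count("ATOM") == 2
        assert text.strip().endswith("END")
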