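"""Domain model: cell matrices, symmetry expansion, rigid variables."""

import numpy as np
import pytest

from crystalfit.crystal import (
    Crystal,
    CrystalSystem,
    Lattice,
    RigidMolecule,
    SymmetryOp,
    apply_variables,
    cell_matrix,
    euler_zyz_from_quat,
    expand_symmetry,
    extract_variables,
    n_variables,
    quat_to_matrix,
)
from crystalfit.errors import (
    InvalidLatticeError,
    SpecialPositionError,
)

from conftest import random_lattice


class TestCellMatrix:
    def test_cubic_identity_case(self):
        lat = Lattice(10, 10, 10, 90, 90, 90, CrystalSystem.CUBIC)
        assert np.allclose(cell_matrix(lat), np.diag([10.0, 10.0, 10.0]))

    def test_orthorhombic_diagonal(self):
        lat = Lattice(4, 5, 6, 90, 90, 90, CrystalSystem.ORTHORHOMBIC)
        M = cell_matrix(lat)
        assert np.allclose(M, np.diag([4.0, 5.0, 6.0]))
        assert abs(np.linalg.det(M) - 120.0) < 1e-10

    def test_triclinic_volume_matches_triple_product(self):
        # independent oracle: volume from the scalar triple product of the
        # three cell vectors built directly from lengths and angles
        lat = Lattice(5, 6, 7, 80, 85, 95)
        a, b, c = 5.0, 6.0, 7.0
        al, be, ga = np.radians([80.0, 85.0, 95.0])
        va = np.array([a, 0, 0])
        vb = np.array([b * np.cos(ga), b * np.sin(ga), 0])
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(c**2 - cx**2 - cy**2)
        vc = np.array([cx, cy, cz])
        vol_oracle = float(np.dot(va, np.cross(vb, vc)))
        M = cell_matrix(lat)
        assert abs(abs(np.linalg.det(M)) - vol_oracle) < 1e-10 * vol_oracle
        assert abs(lat.volume - vol_oracle) < 1e-10 * vol_oracle

    def test_volume_equals_det_for_random_lattices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            lat = random_lattice(rng)
            det = abs(np.linalg.det(cell_matrix(lat)))
            assert abs(det - lat.volume) < 1e-10 * lat.volume

    def test_degenerate_cell_rejected(self):
        with pytest.raises(InvalidLatticeError):
            Lattice(5, 5, 5, 1.0, 179.0, 90.0)
        with pytest.raises(InvalidLatticeError):
            Lattice(-1, 5, 5, 90, 90, 90)


def _mol(center, quaternion=None, charges=(0.2, 0.2, -0.4)):
    raw = np.array([[0.9, 0.0, 0.0], [-0.9, 0.0, 0.0], [0.0, 0.7, 0.0]])
    return RigidMolecule.create(
        ["C", "C", "O"], ["T1", "T1", "T2"], raw - raw.mean(axis=0),
        charges, center, quaternion=quaternion,
    )


class TestExpandSymmetry:
    def test_p1_returns_asymmetric_unit(self):
        lat = Lattice(8, 8, 8, 90, 90, 90, CrystalSystem.CUBIC)
        c = Crystal.create(lat, [SymmetryOp.identity()], [_mol([0.2, 0.3, 0.4])])
        sites = expand_symmetry(c)
        assert sites.n == 3
        assert np.allclose(sites.frac.mean(axis=0) % 1.0,
                           [0.2, 0.3, 0.4], atol=1e-12)

    def test_p_1_doubles_sites(self):
        lat = Lattice(9, 9, 9, 90, 90, 90, CrystalSystem.CUBIC)
        inv = SymmetryOp.create(-np.eye(3, dtype=int), np.zeros(3))
        c = Crystal.create(
            lat, [SymmetryOp.identity(), inv], [_mol([0.2, 0.3, 0.4])]
        )
        sites = expand_symmetry(c)
        assert sites.n == 6
        assert c.Z == 2

    def test_p21_screw_maps_site_by_hand(self):
        # op (-x, y+1/2, -z): (0.1, 0.2, 0.3) -> (0.9, 0.7, 0.7)
        op = SymmetryOp.create(
            [[-1, 0, 0], [0, 1, 0], [0, 0, -1]], [0, 0.5, 0]
        )
        out = op.apply(np.array([0.1, 0.2, 0.3])) % 1.0
        assert np.allclose(out, [0.9, 0.7, 0.7], atol=1e-14)

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        ops = [
            SymmetryOp.identity(),
            SymmetryOp.create(-np.eye(3, dtype=int), np.zeros(3)),
        ]
        for _ in range(20):
            lat = random_lattice(rng)
            c = Crystal.create(lat, ops, [_mol(rng.uniform(0.1, 0.4, 3))])
            sites = expand_symmetry(c)
            assert sites.n == len(ops) * c.n_atoms_asym

    def test_special_position_rejected(self):
        # an atom sitting exactly on the inversion center coincides with
        # its own image
        lat = Lattice(9, 9, 9, 90, 90, 90, CrystalSystem.CUBIC)
        inv = SymmetryOp.create(-np.eye(3, dtype=int), np.zeros(3))
        atom = RigidMolecule.create(
            ["C"], ["T1"], [[0.0, 0.0, 0.0]], [0.0], [0.0, 0.0, 0.0]
        )
        c = Crystal.create(lat, [SymmetryOp.identity(), inv], [atom])
        with pytest.raises(SpecialPositionError):
            expand_symmetry(c)


class TestRigidVariables:
    def test_length(self):
        lat = Lattice(6, 6.5, 7, 85, 95, 92)
        c = Crystal.create(lat, [SymmetryOp.identity()], [_mol([0.2, 0.3, 0.4])])
        assert n_variables(c) == 6 + 6  # triclinic n_x=6 + 6 per molecule

    def test_apply_extract_round_trip_many_draws(self):
        """apply -> extract reproduces omega to 1e-12 (1000 random draws)."""
        rng = np.random.default_rng(7)
        lat = Lattice(6, 6.5, 7, 85, 95, 92)
        base = Crystal.create(
            lat, [SymmetryOp.identity()],
            [_mol([0.2, 0.3, 0.4], quaternion=[0.9, 0.1, 0.3, 0.2])],
        )
        nx = base.lattice.n_free
        for _ in range(1000):
            om = np.concatenate(
                [
                    rng.uniform(4.0, 9.0, size=3),
                    np.radians(rng.uniform(75.0, 105.0, size=3)),
                    rng.uniform(0.0, 1.0, size=3),
                    rng.uniform(-2.5, 2.5, size=3),  # |w| < pi
                ]
            )
            if np.linalg.norm(om[nx + 3:]) >= np.pi:
                om[nx + 3:] *= 0.5
            try:
                applied = apply_variables(base, om)
            except InvalidLatticeError:
                continue
            back = extract_variables(applied, base=base)
            assert np.abs(back - om).max() < 1e-12

    def test_zero_increment_is_identity(self):
        lat = Lattice(6, 6.5, 7, 85, 95, 92)
        c = Crystal.create(lat, [SymmetryOp.identity()], [_mol([0.2, 0.3, 0.4])])
        c2 = apply_variables(c, extract_variables(c))
        assert np.allclose(c2.lattice.parameters, c.lattice.parameters)
        assert np.allclose(c2.asym_unit[0].center, c.asym_unit[0].center)
        assert np.allclose(c2.asym_unit[0].quaternion, c.asym_unit[0].quaternion)

    def test_single_cell_length_perturbation_is_local(self):
        lat = Lattice(6, 6.5, 7, 85, 95, 92)
        c = Crystal.create(lat, [SymmetryOp.identity()], [_mol([0.2, 0.3, 0.4])])
        om = extract_variables(c)
        om[1] += 0.25  # cell length b
        c2 = apply_variables(c, om)
        assert abs(c2.lattice.b - (lat.b + 0.25)) < 1e-12
        for name in ("a", "c", "alpha", "beta", "gamma"):
            assert abs(getattr(c2.lattice, name) - getattr(lat, name)) < 1e-12

    def test_axis_angle_rotates_local_axis(self):
        # increment (0, 0, pi/2) turns a molecule's local x axis into y
        lat = Lattice(10, 10, 10, 90, 90, 90, CrystalSystem.CUBIC)
        local = np.array([[0.55, 0, 0], [-0.55, 0, 0]])
        mol = RigidMolecule.create(
            ["C", "O"], ["T1", "T2"], local, [0.1, -0.1], [0.5, 0.5, 0.5]
        )
        c = Crystal.create(lat, [SymmetryOp.identity()], [mol])
        om = extract_variables(c)
        om[-1] = np.pi / 2  # w_z
        c2 = apply_variables(c, om)
        rotated = c2.asym_unit[0].rotated_local()
        assert np.allclose(rotated[0], [0.0, 0.55, 0.0], atol=1e-12)

    def test_monoclinic_constrained_angles_regenerated(self):
        lat = Lattice(6, 7, 8, 90, 101, 90, CrystalSystem.MONOCLINIC)
        c = Crystal.create(lat, [SymmetryOp.identity()], [_mol([0.2, 0.3, 0.4])])
        om = extract_variables(c)
        assert om.shape == (4 + 6,)
        c2 = apply_variables(c, om + 1e-3)
        assert c2.lattice.alpha == 90.0 and c2.lattice.gamma == 90.0


class TestOrientation:
    def test_euler_zyz_reconstructs_rotation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            a, b, g = euler_zyz_from_quat(q)
            Rz = lambda t: np.array(
                [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
            )
            Ry = lambda t: np.array(
                [[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]]
            )
            assert np.allclose(Rz(a) @ Ry(b) @ Rz(g), quat_to_matrix(q), atol=1e-10)
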