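"""Energy engine: Buckingham sums, Ewald electrostatics, derivatives."""

import numpy as np
import pytest

from crystalfit.crystal import (
    Crystal,
    CrystalSystem,
    Lattice,
    RigidMolecule,
    SymmetryOp,
    extract_variables,
    n_variables,
    so3_left_jacobian,
)
from crystalfit.energy import (
    COULOMB_KJ_MOL_A,
    TAPER_WIDTH,
    PairPotential,
    PotentialSet,
    buckingham_pair,
    combine_chain_factors,
    combine_cross,
    ewald_point_charge,
    inter_energy,
    repdisp_energy,
)
from crystalfit.errors import DomainError, NeutralityError, OverlapError

from conftest import toy_dimer_crystal


def fit_like_pots(free=False):
    fl = (free, False, free)
    return PotentialSet(
        ("T1", "T2"),
        {
            ("T1", "T1"): PairPotential(369743.0, 3.60, 2439.8, free=fl),
            ("T1", "T2"): PairPotential(66530.0, 3.67, 577.0, free=fl),
            ("T2", "T2"): PairPotential(11971.0, 3.74, 136.4, free=fl),
        },
    )


class TestBuckinghamPair:
    def test_zero_parameters_give_zero(self):
        pot = PairPotential(0.0, 3.6, 0.0)
        assert buckingham_pair(1.7, pot) == 0.0

    def test_long_range_approaches_zero_from_below(self):
        pot = PairPotential(1e5, 3.6, 2e3)
        assert -1e-3 < buckingham_pair(12.0, pot) < 0.0

    def test_reference_value(self):
        # A exp(-3.6*3.5) - 2000/3.5^6, confirmed by scalar arithmetic
        pot = PairPotential(1e5, 3.6, 2e3)
        assert buckingham_pair(3.5, pot) == pytest.approx(-0.750783, abs=1e-5)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(DomainError):
            buckingham_pair(0.0, PairPotential(1.0, 1.0, 1.0))


class TestCombiningRules:
    def test_identical_types_unchanged(self):
        p = PairPotential(100.0, 3.0, 50.0)
        c = combine_cross(p, p)
        assert (c.A, c.B, c.C) == (100.0, 3.0, 50.0)

    def test_geometric_mean_for_A(self):
        c = combine_cross(
            PairPotential(100.0, 3.0, 1.0), PairPotential(400.0, 3.0, 4.0)
        )
        assert c.A == pytest.approx(200.0) and c.C == pytest.approx(2.0)

    def test_harmonic_mean_for_B(self):
        c = combine_cross(
            PairPotential(1.0, 3.0, 0.0), PairPotential(1.0, 6.0, 0.0)
        )
        assert c.B == pytest.approx(4.0)

    def test_chain_factor_closed_form(self):
        # dA_ij/dA_ii = 0.5 sqrt(A_jj/A_ii) = 1 for 100 vs 400
        pi = PairPotential(100.0, 3.0, 1.0)
        pj = PairPotential(400.0, 3.0, 4.0)
        dA, dB, dC = combine_chain_factors(pi, pj)
        assert dA == pytest.approx(1.0)
        assert dC == pytest.approx(1.0)
        assert combine_chain_factors(pi, pi) == (1.0, 1.0, 1.0)

    def test_chain_singularity(self):
        with pytest.raises(DomainError):
            combine_chain_factors(
                PairPotential(0.0, 3.0, 1.0), PairPotential(4.0, 3.0, 1.0)
            )


def one_atom_cubic(a=4.0, charge=0.0):
    mol = RigidMolecule.create(["C"], ["T1"], [[0, 0, 0]], [charge], [0, 0, 0])
    lat = Lattice(a, a, a, 90, 90, 90, CrystalSystem.CUBIC)
    return Crystal.create(lat, [SymmetryOp.identity()], [mol], "one")


class TestRepDisp:
    def test_zero_potential_zero_everything(self):
        pots = PotentialSet(
            ("T1",), {("T1", "T1"): PairPotential(0.0, 3.6, 0.0)}
        )
        rep = repdisp_energy(one_atom_cubic(), pots, cutoff=10.0, order=2,
                             with_params=False)
        assert rep.U_rd == 0.0
        assert np.all(rep.grad == 0.0) and np.all(rep.hessian == 0.0)

    def test_pure_dispersion_matches_shell_oracle(self):
        """Brute-force shell-by-shell direct sum over cubic images (with the
        same taper weights) reproduces U_rd to 1e-6 relative."""
        a, C, cutoff = 4.0, 2000.0, 12.0
        pots = PotentialSet(
            ("T1",), {("T1", "T1"): PairPotential(0.0, 3.6, C)}
        )
        rep = repdisp_energy(one_atom_cubic(a), pots, cutoff=cutoff, order=0)
        # independent oracle: loop over integer shells
        nmax = int(np.ceil(cutoff / a)) + 1
        w = TAPER_WIDTH
        r_on = cutoff - w
        total = 0.0
        for i in range(-nmax, nmax + 1):
            for j in range(-nmax, nmax + 1):
                for k in range(-nmax, nmax + 1):
                    if i == j == k == 0:
                        continue
                    r = a * np.sqrt(i * i + j * j + k * k)
                    if r >= cutoff:
                        continue
                    s = min(max((r - r_on) / w, 0.0), 1.0)
                    taper = 1.0 - s**3 * (10 - 15 * s + 6 * s**2)
                    total += -C / r**6 * taper
        oracle = 0.5 * total
        assert rep.U_rd == pytest.approx(oracle, rel=1e-6)

    def test_exponential_decay_cutoff_insensitive(self):
        pots = PotentialSet(
            ("T1",), {("T1", "T1"): PairPotential(1e5, 3.6, 0.0)}
        )
        u12 = repdisp_energy(one_atom_cubic(), pots, cutoff=12.0).U_rd
        u24 = repdisp_energy(one_atom_cubic(), pots, cutoff=24.0).U_rd
        assert abs(u12 - u24) < 1e-10

    def test_overlap_detected(self):
        lat = Lattice(5, 5, 5, 90, 90, 90, CrystalSystem.CUBIC)
        m1 = RigidMolecule.create(["C"], ["T1"], [[0, 0, 0]], [0.0], [0, 0, 0])
        m2 = RigidMolecule.create(
            ["C"], ["T1"], [[0, 0, 0]], [0.0], [0.04, 0, 0]
        )
        c = Crystal.create(lat, [SymmetryOp.identity()], [m1, m2])
        pots = PotentialSet(
            ("T1",), {("T1", "T1"): PairPotential(1e5, 3.6, 100.0)}
        )
        with pytest.raises(OverlapError):
            repdisp_energy(c, pots, cutoff=10.0)


def rock_salt(a=5.64):
    """Conventional NaCl cell as eight single-ion rigid units."""
    na = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    cl = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    mols = [
        RigidMolecule.create(["Na"], ["Na"], [[0, 0, 0]], [1.0], c) for c in na
    ] + [
        RigidMolecule.create(["Cl"], ["Cl"], [[0, 0, 0]], [-1.0], c) for c in cl
    ]
    lat = Lattice(a, a, a, 90, 90, 90, CrystalSystem.CUBIC)
    return Crystal.create(lat, [SymmetryOp.identity()], mols, "NaCl")


def evjen_madelung(n=10):
    """Evjen's expanding-neutral-cube estimate of the NaCl Madelung
    constant: boundary charges weighted by the fraction of the cube that
    contains them."""
    total = 0.0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for t in (i, j, k):
                    if abs(t) == n:
                        w *= 0.5
                r = np.sqrt(i * i + j * j + k * k)
                total += ((-1) ** ((i + j + k) % 2)) * w / r
    return -total  # positive Madelung constant


class TestEwald:
    def test_zero_charges_zero_energy(self):
        rep = ewald_point_charge(one_atom_cubic(charge=0.0), order=1)
        assert rep.U_elec == 0.0 and np.all(rep.grad == 0.0)

    def test_rock_salt_matches_evjen_oracle(self):
        a = 5.64
        r0 = a / 2.0
        rep = ewald_point_charge(rock_salt(a))
        # engine energy is per mole of "molecules" = per ion; per ion pair:
        u_pair = 2.0 * rep.U_elec
        madelung = evjen_madelung(10)
        expected = -madelung * COULOMB_KJ_MOL_A / r0
        assert u_pair == pytest.approx(expected, rel=1e-4)

    def test_splitting_parameter_invariance(self):
        c = rock_salt()
        u1 = ewald_point_charge(c, alpha=0.35, accuracy=1e-6).U_elec
        u2 = ewald_point_charge(c, alpha=0.70, accuracy=1e-6).U_elec
        assert abs(u1 - u2) < 1e-6

    def test_non_neutral_cell_rejected(self):
        with pytest.raises(NeutralityError):
            ewald_point_charge(one_atom_cubic(charge=0.5))


class TestDerivatives:
    """Analytic derivative blocks against finite differences."""

    def setup_method(self):
        self.crystal = toy_dimer_crystal()
        self.pots = fit_like_pots(free=True)
        self.om0 = extract_variables(self.crystal)
        self.n = n_variables(self.crystal)

    def _f(self, om):
        return inter_energy(
            self.crystal, self.pots, omega=om, order=0, cutoff=10.0
        ).U_inter

    def _g_fixed(self, om):
        """Gradient mapped into the fixed chart at self.om0."""
        g = inter_energy(
            self.crystal, self.pots, omega=om, order=1, cutoff=10.0
        ).grad.copy()
        nx, zp = 6, 2
        for m in range(zp):
            sl = slice(nx + 3 * zp + 3 * m, nx + 3 * zp + 3 * m + 3)
            g[sl] = so3_left_jacobian(om[sl] - self.om0[sl]).T @ g[sl]
        return g

    def test_gradient_matches_fd(self):
        rep = inter_energy(self.crystal, self.pots, order=1, cutoff=10.0)
        h = 1e-5
        fd = np.empty(self.n)
        for k in range(self.n):
            e = np.zeros(self.n)
            e[k] = h
            fd[k] = (self._f(self.om0 + e) - self._f(self.om0 - e)) / (2 * h)
        assert np.abs(rep.grad - fd).max() < 1e-6 * max(1.0, np.abs(fd).max())

    def test_hessian_symmetric_and_matches_fd(self):
        rep = inter_energy(self.crystal, self.pots, order=2, cutoff=10.0)
        assert np.abs(rep.hessian - rep.hessian.T).max() < 1e-8 * max(
            1.0, np.abs(rep.hessian).max()
        )
        h = 1e-5
        fd = np.empty((self.n, self.n))
        for k in range(self.n):
            e = np.zeros(self.n)
            e[k] = h
            fd[:, k] = (
                self._g_fixed(self.om0 + e) - self._g_fixed(self.om0 - e)
            ) / (2 * h)
        assert np.abs(rep.hessian - fd).max() < 1e-5 * np.abs(fd).max()

    def test_param_derivatives_match_fd(self):
        rep = inter_energy(
            self.crystal, self.pots, order=1, with_params=True, cutoff=10.0
        )
        p0 = self.pots.get_vector()
        for k in range(len(p0)):
            d = 1e-6 * p0[k]
            e = np.zeros(len(p0))
            e[k] = d
            up = inter_energy(
                self.crystal, self.pots.with_vector(p0 + e), order=1,
                cutoff=10.0,
            )
            um = inter_energy(
                self.crystal, self.pots.with_vector(p0 - e), order=1,
                cutoff=10.0,
            )
            fd_u = (up.U_rd - um.U_rd) / (2 * d)
            fd_cross = (up.grad - um.grad) / (2 * d)
            assert rep.dU_rd_dp[k] == pytest.approx(fd_u, rel=1e-6)
            assert np.abs(rep.cross[:, k] - fd_cross).max() < 1e-6 * max(
                1.0, np.abs(fd_cross).max()
            )

    def test_absent_type_parameter_derivative_is_zero(self):
        pots3 = PotentialSet(
            ("T1", "T2", "T9"),
            {
                **fit_like_pots(free=True).pairs,
                ("T1", "T9"): PairPotential(1e4, 3.5, 100.0, free=(True, False, True)),
                ("T2", "T9"): PairPotential(1e4, 3.5, 100.0),
                ("T9", "T9"): PairPotential(1e4, 3.5, 100.0, free=(True, False, True)),
            },
        )
        rep = inter_energy(
            self.crystal, pots3, order=1, with_params=True, cutoff=10.0
        )
        labels = pots3.free_labels()
        for i, (key, comp) in enumerate(labels):
            if "T9" in key:
                assert rep.dU_rd_dp[i] == 0.0
                assert np.all(rep.cross[:, i] == 0.0)


class TestCombiningModeChain:
    def test_chained_derivative_matches_fd(self):
        """dU/dA_T1T1 under combining rules (cross pairs derived from the
        homoatomic entries) agrees with finite differences."""
        crystal = toy_dimer_crystal()
        pots = PotentialSet(
            ("T1", "T2"),
            {
                ("T1", "T1"): PairPotential(
                    369743.0, 3.60, 2439.8, free=(True, False, True)
                ),
                ("T2", "T2"): PairPotential(
                    11971.0, 3.74, 136.4, free=(True, False, True)
                ),
            },
            mode="combine",
        )
        rep = inter_energy(crystal, pots, order=0, with_params=True, cutoff=10.0)
        p0 = pots.get_vector()
        for k in range(len(p0)):
            d = 1e-6 * p0[k]
            e = np.zeros(len(p0))
            e[k] = d
            up = inter_energy(
                crystal, pots.with_vector(p0 + e), order=0, cutoff=10.0
            ).U_rd
            um = inter_energy(
                crystal, pots.with_vector(p0 - e), order=0, cutoff=10.0
            ).U_rd
            assert rep.dU_rd_dp[k] == pytest.approx(
                (up - um) / (2 * d), rel=1e-6
            )


class TestInvariances:
    def test_translation_invariance(self):
        crystal = toy_dimer_crystal()
        pots = fit_like_pots()
        om = extract_variables(crystal)
        u0 = inter_energy(crystal, pots, omega=om, cutoff=10.0).U_inter
        om2 = om.copy()
        om2[6:9] += 0.137
        om2[9:12] += 0.137
        u1 = inter_energy(crystal, pots, omega=om2, cutoff=10.0).U_inter
        assert abs(u1 - u0) < 1e-10 * max(1.0, abs(u0))

    def test_supercell_extensivity(self):
        """A 2x1x1 P1 supercell reproduces the per-molecule energy."""
        lat = Lattice(6.0, 6.5, 7.0, 85.0, 95.0, 92.0)
        raw = np.array([[0.9, 0, 0], [-0.9, 0, 0], [0, 0.7, 0]])
        local = raw - raw.mean(axis=0)
        q = [0.2, 0.2, -0.4]
        mol = RigidMolecule.create(
            ["C", "C", "O"], ["T1", "T1", "T2"], local, q, [0.3, 0.4, 0.5],
            quaternion=[0.9, 0.1, 0.3, 0.2],
        )
        c1 = Crystal.create(lat, [SymmetryOp.identity()], [mol])
        lat2 = Lattice(12.0, 6.5, 7.0, 85.0, 95.0, 92.0)
        molA = RigidMolecule.create(
            ["C", "C", "O"], ["T1", "T1", "T2"], local, q, [0.15, 0.4, 0.5],
            quaternion=[0.9, 0.1, 0.3, 0.2],
        )
        molB = RigidMolecule.create(
            ["C", "C", "O"], ["T1", "T1", "T2"], local, q, [0.65, 0.4, 0.5],
            quaternion=[0.9, 0.1, 0.3, 0.2],
        )
        c2 = Crystal.create(lat2, [SymmetryOp.identity()], [molA, molB])
        pots = fit_like_pots()
        u1 = inter_energy(c1, pots, cutoff=10.0).U_inter
        u2 = inter_energy(c2, pots, cutoff=10.0).U_inter
        assert u2 == pytest.approx(u1, rel=1e-8)
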