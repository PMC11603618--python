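"""Domain model for rigid-molecule molecular crystals.

A crystal is described by a :class:`Lattice` (six cell parameters, with the
crystal system fixing which of them are free), a list of space-group
operators acting in the fractional basis, and the asymmetric unit: one or
more rigid molecules, each carrying element symbols, force-field atom-type
labels, point charges (e) and local Cartesian coordinates relative to the
molecular centroid.

The free geometric degrees of freedom form the rigid-variable vector
``omega``: the independent cell parameters (lengths in A, angles in rad),
the fractional centroid of every asymmetric molecule, and a 3-vector
incremental axis-angle rotation about each molecule's stored orientation.
Orientations are stored as unit quaternions; an incremental axis-angle
(exponential map) chart about the current orientation is exposed to
optimizers, re-baselined whenever a new geometry is applied, which keeps
the chart singularity-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache

import numpy as np

from .errors import (
    ConsistencyError,
    InvalidLatticeError,
    NeutralityError,
    SpecialPositionError,
)

__all__ = [
    "CrystalSystem",
    "Lattice",
    "SymmetryOp",
    "RigidMolecule",
    "Crystal",
    "cell_matrix",
    "cell_matrix_derivs",
    "cell_volume",
    "expand_symmetry",
    "SiteSet",
    "n_variables",
    "extract_variables",
    "apply_variables",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_multiply",
    "rotvec_to_quat",
    "quat_to_rotvec",
    "euler_zyz_from_quat",
    "so3_left_jacobian",
]

DEG = np.pi / 180.0


def _wrap01(x: np.ndarray) -> np.ndarray:
    """Wrap to [0, 1), robust to np.mod returning exactly 1.0."""
    out = np.mod(np.asarray(x, dtype=float), 1.0)
    out = np.where(out >= 1.0, 0.0, out)
    return out


class CrystalSystem(str, Enum):
    TRICLINIC = "triclinic"
    MONOCLINIC = "monoclinic"
    ORTHORHOMBIC = "orthorhombic"
    TETRAGONAL = "tetragonal"
    HEXAGONAL = "hexagonal"  # covers trigonal settings with hexagonal axes
    CUBIC = "cubic"


# mask over (a, b, c, alpha, beta, gamma): which parameters are free
_FREE_MASKS = {
    CrystalSystem.TRICLINIC: (True, True, True, True, True, True),
    CrystalSystem.MONOCLINIC: (True, True, True, False, True, False),
    CrystalSystem.ORTHORHOMBIC: (True, True, True, False, False, False),
    CrystalSystem.TETRAGONAL: (True, False, True, False, False, False),
    CrystalSystem.HEXAGONAL: (True, False, True, False, False, False),
    CrystalSystem.CUBIC: (True, False, False, False, False, False),
}

_PARAM_NAMES = ("a", "b", "c", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class Lattice:
    """Unit-cell parameters. Lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    crystal_system: CrystalSystem = CrystalSystem.TRICLINIC

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise InvalidLatticeError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidLatticeError(f"cell angle {name} out of (0, 180)")
        if self.volume <= 1e-6:
            raise InvalidLatticeError("degenerate cell (volume <= 1e-6 A^3)")

    @property
    def free_mask(self) -> tuple[bool, ...]:
        return _FREE_MASKS[self.crystal_system]

    @property
    def n_free(self) -> int:
        return sum(self.free_mask)

    @property
    def parameters(self) -> np.ndarray:
        """The six parameters (a, b, c, alpha, beta, gamma), degrees."""
        return np.array(
            [self.a, self.b, self.c, self.alpha, self.beta, self.gamma],
            dtype=float,
        )

    def free_parameters(self) -> np.ndarray:
        """Free parameters only: lengths in A, angles in *radians*."""
        p = self.parameters
        p[3:] *= DEG
        return p[list(self.free_mask)]

    def with_free_parameters(self, values: np.ndarray) -> "Lattice":
        """Rebuild the lattice from free parameters (angles in radians).

        Constrained parameters are regenerated from the crystal system,
        never read from the input vector.
        """
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_free,):
            raise ConsistencyError(
                f"expected {self.n_free} free cell parameters, got {values.shape}"
            )
        sys = self.crystal_system
        full = dict(zip(_PARAM_NAMES, self.parameters))
        it = iter(values)
        for name, free in zip(_PARAM_NAMES, self.free_mask):
            if free:
                v = float(next(it))
                if name in ("alpha", "beta", "gamma"):
                    v /= DEG
                full[name] = v
        # regenerate constrained parameters
        if sys is CrystalSystem.MONOCLINIC:
            full["alpha"] = full["gamma"] = 90.0
        elif sys is CrystalSystem.ORTHORHOMBIC:
            full["alpha"] = full["beta"] = full["gamma"] = 90.0
        elif sys is CrystalSystem.TETRAGONAL:
            full["b"] = full["a"]
            full["alpha"] = full["beta"] = full["gamma"] = 90.0
        elif sys is CrystalSystem.HEXAGONAL:
            full["b"] = full["a"]
            full["alpha"] = full["beta"] = 90.0
            full["gamma"] = 120.0
        elif sys is CrystalSystem.CUBIC:
            full["b"] = full["c"] = full["a"]
            full["alpha"] = full["beta"] = full["gamma"] = 90.0
        return Lattice(crystal_system=sys, **full)

    @property
    def volume(self) -> float:
        ca, cb, cg = np.cos(np.array([self.alpha, self.beta, self.gamma]) * DEG)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * float(np.sqrt(arg))


def cell_volume(lattice: Lattice) -> float:
    return lattice.volume


def free_param_map(lattice: Lattice) -> np.ndarray:
    """Matrix T (6 x n_free) mapping free-parameter perturbations onto the
    six raw cell parameters, including system constraints (tetragonal and
    hexagonal b = a, cubic b = c = a)."""
    mask = np.array(lattice.free_mask)
    T = np.zeros((6, lattice.n_free))
    col = 0
    for i, f in enumerate(mask):
        if f:
            T[i, col] = 1.0
            col += 1
    sys = lattice.crystal_system
    if sys in (CrystalSystem.TETRAGONAL, CrystalSystem.HEXAGONAL):
        T[1, 0] = 1.0
    elif sys is CrystalSystem.CUBIC:
        T[1, 0] = 1.0
        T[2, 0] = 1.0
    return T


def cell_matrix(lattice: Lattice) -> np.ndarray:
    """3x3 matrix mapping fractional -> Cartesian coordinates (A).

    Convention: **a** along x, **b** in the x-y plane; lattice vectors are
    the matrix *columns*, so |det| equals the cell volume.
    """
    if lattice.volume <= 1e-6:
        raise InvalidLatticeError("degenerate cell (volume <= 1e-6 A^3)")
    fn, _, _ = _cell_matrix_functions()
    ang = np.array([lattice.alpha, lattice.beta, lattice.gamma]) * DEG
    return np.array(fn(lattice.a, lattice.b, lattice.c, *ang), dtype=float)


def cell_matrix_derivs(lattice: Lattice):
    """Return (L, dL, d2L): the cell matrix and its first and second
    derivatives with respect to the six parameters (a, b, c in A; alpha,
    beta, gamma in *radians*), as arrays of shape (3,3), (6,3,3), (6,6,3,3).
    """
    fn, dfn, d2fn = _cell_matrix_functions()
    args = (
        lattice.a,
        lattice.b,
        lattice.c,
        lattice.alpha * DEG,
        lattice.beta * DEG,
        lattice.gamma * DEG,
    )
    L = np.array(fn(*args), dtype=float)
    dL = np.array(dfn(*args), dtype=float)
    d2L = np.array(d2fn(*args), dtype=float)
    return L, dL, d2L


@lru_cache(maxsize=1)
def _cell_matrix_functions():
    """Symbolically generate and cache the cell matrix and its derivatives."""
    import sympy as sp

    a, b, c, al, be, ga = sp.symbols("a b c alpha beta gamma", positive=True)
    ca, cb, cg = sp.cos(al), sp.cos(be), sp.cos(ga)
    sg = sp.sin(ga)
    v = sp.sqrt(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
    M = sp.Matrix(
        [
            [a, b * cg, c * cb],
            [0, b * sg, c * (ca - cb * cg) / sg],
            [0, 0, c * v / sg],
        ]
    )
    params = (a, b, c, al, be, ga)
    dM = sp.Array([M.diff(p).tolist() for p in params])
    d2M = sp.Array(
        [[M.diff(p).diff(q).tolist() for q in params] for p in params]
    )
    fn = sp.lambdify(params, M, "numpy")
    dfn = sp.lambdify(params, dM, "numpy")
    d2fn = sp.lambdify(params, d2M, "numpy")
    return fn, dfn, d2fn


# ---------------------------------------------------------------------------
# quaternion / rotation utilities (scalar-first convention, unit norm)
# ---------------------------------------------------------------------------


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Rotation matrix -> unit quaternion (scalar part non-negative)."""
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s,
             (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


def rotvec_to_quat(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        q = np.array([1.0, 0.5 * w[0], 0.5 * w[1], 0.5 * w[2]])
        return q / np.linalg.norm(q)
    axis = w / theta
    return np.concatenate([[np.cos(theta / 2)], np.sin(theta / 2) * axis])


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    q = q / np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    s = np.linalg.norm(q[1:])
    if s < 1e-12:
        return 2.0 * q[1:]
    theta = 2.0 * np.arctan2(s, q[0])
    return theta * q[1:] / s


def euler_zyz_from_quat(q: np.ndarray) -> tuple[float, float, float]:
    """ZYZ Euler angles (radians) equivalent to the stored quaternion."""
    R = quat_to_matrix(q)
    beta = np.arccos(np.clip(R[2, 2], -1.0, 1.0))
    if abs(np.sin(beta)) < 1e-12:
        # gimbal-degenerate: fold all rotation into alpha
        alpha = np.arctan2(R[1, 0], R[0, 0])
        gamma = 0.0
    else:
        alpha = np.arctan2(R[1, 2], R[0, 2])
        gamma = np.arctan2(R[2, 1], -R[2, 0])
    return float(alpha), float(beta), float(gamma)


def so3_left_jacobian(w: np.ndarray) -> np.ndarray:
    """Left Jacobian J_l of SO(3): exp((w+dw)^) = exp((J_l(w) dw)^) exp(w^)."""
    w = np.asarray(w, dtype=float)
    theta = np.linalg.norm(w)
    W = _skew(w)
    if theta < 1e-8:
        return np.eye(3) + 0.5 * W + W @ W / 6.0
    return (
        np.eye(3)
        + (1 - np.cos(theta)) / theta**2 * W
        + (theta - np.sin(theta)) / theta**3 * (W @ W)
    )


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


# ---------------------------------------------------------------------------
# symmetry operators and molecules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operator in the fractional basis: x -> R x + t."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # length-3 tuple of floats in [0, 1)

    @staticmethod
    def create(rotation, translation) -> "SymmetryOp":
        R = np.asarray(rotation, dtype=int)
        det = int(round(np.linalg.det(R)))
        if det not in (1, -1):
            raise ConsistencyError(f"symmetry rotation determinant {det}")
        t = _wrap01(np.asarray(translation, dtype=float))
        t[np.isclose(t, 1.0, atol=1e-12)] = 0.0
        return SymmetryOp(
            tuple(tuple(int(x) for x in row) for row in R), tuple(float(x) for x in t)
        )

    @staticmethod
    def identity() -> "SymmetryOp":
        return SymmetryOp.create(np.eye(3, dtype=int), np.zeros(3))

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.R, np.eye(3)) and np.allclose(self.t, 0.0)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.R.T + self.t


@dataclass(frozen=True)
class RigidMolecule:
    """A rigid molecule of the asymmetric unit.

    ``local`` holds Cartesian coordinates (A) in the molecular frame,
    relative to the (mass-unweighted) centroid; ``center`` is the centroid
    in fractional coordinates; ``quaternion`` the orientation.
    """

    elements: tuple[str, ...]
    atom_types: tuple[str, ...]
    local: np.ndarray  # (n, 3)
    charges: np.ndarray  # (n,)
    center: np.ndarray  # (3,)
    quaternion: np.ndarray  # (4,)

    @staticmethod
    def create(elements, atom_types, local, charges, center, quaternion=None):
        local = np.array(local, dtype=float)
        charges = np.array(charges, dtype=float)
        center = _wrap01(np.array(center, dtype=float))
        n = len(elements)
        if not (local.shape == (n, 3) and charges.shape == (n,) and len(atom_types) == n):
            raise ConsistencyError("molecule field lengths disagree")
        centroid = local.mean(axis=0)
        if np.linalg.norm(centroid) > 1e-10:
            raise ConsistencyError(
                f"local coordinates are not centroid-centered (|mean| = "
                f"{np.linalg.norm(centroid):.2e} A)"
            )
        if quaternion is None:
            quaternion = np.array([1.0, 0.0, 0.0, 0.0])
        quaternion = np.array(quaternion, dtype=float)
        if abs(np.linalg.norm(quaternion) - 1.0) > 1e-12:
            quaternion = quaternion / np.linalg.norm(quaternion)
        return RigidMolecule(
            tuple(elements), tuple(atom_types), local, charges, center, quaternion
        )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def rotation(self) -> np.ndarray:
        return quat_to_matrix(self.quaternion)

    @property
    def euler_zyz(self) -> tuple[float, float, float]:
        return euler_zyz_from_quat(self.quaternion)

    def rotated_local(self) -> np.ndarray:
        """Local coordinates rotated into the crystal Cartesian frame."""
        return self.local @ self.rotation.T


@dataclass(frozen=True)
class Crystal:
    """Lattice + space-group operators + rigid asymmetric unit."""

    lattice: Lattice
    ops: tuple[SymmetryOp, ...]
    asym_unit: tuple[RigidMolecule, ...]
    label: str = ""

    @staticmethod
    def create(lattice, ops, asym_unit, label="") -> "Crystal":
        ops = tuple(ops)
        if not ops or not ops[0].is_identity:
            raise ConsistencyError("first symmetry operator must be the identity")
        return Crystal(lattice, ops, tuple(asym_unit), label)

    @property
    def z_prime(self) -> int:
        return len(self.asym_unit)

    @property
    def Z(self) -> int:
        return len(self.ops) * len(self.asym_unit)

    @property
    def n_atoms_asym(self) -> int:
        return sum(m.n_atoms for m in self.asym_unit)

    def validate(self, min_distance: float = 0.5) -> None:
        """Check unit-cell neutrality and the hard contact sanity bound."""
        total_q = sum(float(m.charges.sum()) for m in self.asym_unit) * len(self.ops)
        if abs(total_q) > 1e-8:
            raise NeutralityError(f"net unit-cell charge {total_q:.3e} e")
        sites = expand_symmetry(self)
        if sites.n > 1:
            d = _min_periodic_distance(sites, self.lattice)
            if d < min_distance:
                raise ConsistencyError(
                    f"expanded atoms closer than {min_distance} A (d = {d:.3f})"
                )


@dataclass
class SiteSet:
    """All atom sites of the unit cell with provenance.

    Arrays are aligned: entry ``i`` belongs to asymmetric molecule
    ``mol_index[i]`` under operator ``op_index[i]``; ``mol_id`` numbers the
    molecule *instances* (Z of them) so intramolecular pairs can be excluded.
    """

    frac: np.ndarray  # (N, 3), wrapped to [0, 1) per atom
    frac_mol: np.ndarray  # (N, 3), molecule-coherent: only the molecule
    # *instance center* is wrapped, so intramolecular pairs always sit in
    # the same image cell (atoms may fall slightly outside [0, 1))
    cart: np.ndarray  # (N, 3), consistent with frac_mol
    charges: np.ndarray  # (N,)
    elements: list
    atom_types: list
    mol_index: np.ndarray  # (N,) index into asym_unit
    op_index: np.ndarray  # (N,) index into ops
    atom_index: np.ndarray  # (N,) atom index within its molecule
    mol_id: np.ndarray  # (N,) molecule-instance id, 0..Z-1
    local_rot: np.ndarray  # (N, 3) R_m l_a in the crystal Cartesian frame

    @property
    def n(self) -> int:
        return len(self.charges)


def expand_symmetry(crystal: Crystal, check_special: bool = True) -> SiteSet:
    """Expand the asymmetric unit by all space-group operators.

    Raises :class:`SpecialPositionError` when two images coincide (the rigid
    whole-molecule model cannot represent special positions).
    """
    lat = crystal.lattice
    L = cell_matrix(lat)
    Linv = np.linalg.inv(L)
    frac_all, rows = [], []
    local_rot_all = []
    mol_id = 0
    for k, op in enumerate(crystal.ops):
        for m, mol in enumerate(crystal.asym_unit):
            d = mol.rotated_local()  # (n, 3) Cartesian
            f_local = d @ Linv.T  # fractional offsets
            # wrap the *image center* only; atoms stay rigid around it so
            # intramolecular pairs always share the same image cell
            c_img = _wrap01(op.R @ mol.center + op.t)
            f = c_img + (f_local @ op.R.T)
            frac_all.append(f)
            local_rot_all.append(d)
            for a in range(mol.n_atoms):
                rows.append((m, k, a, mol_id))
            mol_id += 1
    frac_mol = np.vstack(frac_all)
    frac = _wrap01(frac_mol)
    rows = np.array(rows, dtype=int)
    elements, atom_types, charges = [], [], []
    for m, k, a, _ in rows:
        mol = crystal.asym_unit[m]
        elements.append(mol.elements[a])
        atom_types.append(mol.atom_types[a])
        charges.append(mol.charges[a])
    sites = SiteSet(
        frac=frac,
        frac_mol=frac_mol,
        cart=frac_mol @ L.T,
        charges=np.array(charges),
        elements=elements,
        atom_types=atom_types,
        mol_index=rows[:, 0],
        op_index=rows[:, 1],
        atom_index=rows[:, 2],
        mol_id=rows[:, 3],
        local_rot=np.vstack(local_rot_all),
    )
    if check_special and sites.n > 1:
        df = frac[:, None, :] - frac[None, :, :]
        df -= np.round(df)
        dist = np.linalg.norm(df, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1e-4:
            i, j = np.unravel_index(int(np.argmin(dist)), dist.shape)
            raise SpecialPositionError(
                f"symmetry images coincide (sites {i} and {j}): special "
                "position not representable with rigid whole molecules"
            )
    return sites


def _min_periodic_distance(sites: SiteSet, lattice: Lattice) -> float:
    L = cell_matrix(lattice)
    best = np.inf
    shifts = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    for s in shifts:
        d = sites.frac[:, None, :] - sites.frac[None, :, :] + s
        r = np.linalg.norm(d @ L.T, axis=-1)
        if np.all(s == 0):
            np.fill_diagonal(r, np.inf)
        best = min(best, float(r.min()))
    return best


# ---------------------------------------------------------------------------
# rigid-variable vector (omega)
# ---------------------------------------------------------------------------


def n_variables(crystal: Crystal) -> int:
    """Length of omega: n_x free cell parameters + 6 per asymmetric molecule."""
    return crystal.lattice.n_free + 6 * crystal.z_prime


def extract_variables(crystal: Crystal, base: Crystal | None = None) -> np.ndarray:
    """Extract omega. Orientation increments are measured about ``base``
    (zero when ``base`` is None or is the crystal itself)."""
    parts = [crystal.lattice.free_parameters()]
    for m, mol in enumerate(crystal.asym_unit):
        parts.append(np.asarray(mol.center, dtype=float))
    for m, mol in enumerate(crystal.asym_unit):
        if base is None:
            parts.append(np.zeros(3))
        else:
            q_base = base.asym_unit[m].quaternion
            q_rel = quat_multiply(
                mol.quaternion, np.array([q_base[0], *(-q_base[1:])])
            )
            parts.append(quat_to_rotvec(q_rel))
    return np.concatenate(parts)


def apply_variables(crystal: Crystal, omega: np.ndarray) -> Crystal:
    """Return a new crystal with geometry set from omega.

    Constrained cell parameters are regenerated from the crystal system.
    Orientation increments are composed onto the stored quaternions, so the
    returned crystal is itself a zero-increment baseline.
    """
    omega = np.asarray(omega, dtype=float)
    nx = crystal.lattice.n_free
    zp = crystal.z_prime
    if omega.shape != (nx + 6 * zp,):
        raise ConsistencyError(
            f"omega length {omega.shape} != {nx + 6 * zp} for this crystal"
        )
    lattice = crystal.lattice.with_free_parameters(omega[:nx])
    mols = []
    for m, mol in enumerate(crystal.asym_unit):
        center = _wrap01(omega[nx + 3 * m : nx + 3 * m + 3])
        w = omega[nx + 3 * zp + 3 * m : nx + 3 * zp + 3 * m + 3]
        q = quat_multiply(rotvec_to_quat(w), mol.quaternion)
        q = q / np.linalg.norm(q)
        if q[0] < 0:
            q = -q
        mols.append(replace(mol, center=center, quaternion=q))
    return Crystal(lattice, crystal.ops, tuple(mols), crystal.label)
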