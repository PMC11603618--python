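"""Self-contained synthetic fixtures: toy rigid molecules packed into
low-symmetry cells and relaxed to force-field minima under known "true"
parameters, standing in for reference training data.

The generator follows an inverse-crime design on purpose: reference
geometries and intermolecular energies come from the *same* force-field
family that is later fitted, so the global optimum of the parameter
estimation is known exactly (the true parameters, with zero merit
function).  That is the right construction for testing the estimation
machinery; it says nothing about the accuracy of any force field against
quantum-chemical data.

Templates are nonlinear molecules (a linear molecule's rigid-body Hessian
has an exact zero mode - rotation about its own axis - which the
implicit-function sensitivity cannot invert; a diatomic template is kept
for energy-oracle tests only).  Charges default to a magnitude that puts
the electrostatic share of the lattice energy roughly between 20 and 60%,
so fitting always exercises the Ewald path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import (
    Crystal,
    CrystalSystem,
    Lattice,
    RigidMolecule,
    SymmetryOp,
    expand_symmetry,
)
from .energy import PairPotential, PotentialSet, _Geometry, _enumerate_pairs
from .errors import ConfigError, GenerationError
from .latmin import LMOptions, LMStatus, minimize_lattice
from .residuals import ReferenceEntry

__all__ = [
    "ToySpec",
    "TEMPLATES",
    "default_true_potentials",
    "make_toy_molecule",
    "make_toy_crystal",
    "min_intermolecular_distance",
    "generate_reference_set",
    "perturb_parameters",
]


def _centered(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    return coords - coords.mean(axis=0)


#: template name -> (elements, type slots, local coordinates, charge slots)
#: type/charge slots index into the ToySpec's atom_types / charge magnitude
TEMPLATES = {
    # bent triatomic, ~ an SO2/ozone-shaped polar unit
    "bent3": (
        ("C", "C", "O"),
        (0, 0, 1),
        _centered([[0.95, 0.0, 0.0], [-0.95, 0.0, 0.0], [0.0, 0.75, 0.0]]),
        (1.0, 1.0, -2.0),
    ),
    # planar 4-atom quadrupolar unit
    "quad4": (
        ("C", "O", "C", "O"),
        (0, 1, 0, 1),
        _centered(
            [[0.95, 0.55, 0.0], [-0.95, 0.55, 0.0],
             [-0.95, -0.55, 0.0], [0.95, -0.55, 0.0]]
        ),
        (1.0, -1.0, 1.0, -1.0),
    ),
    # six-membered ring with alternating charges
    "ring6": (
        ("C", "N", "C", "N", "C", "N"),
        (0, 1, 0, 1, 0, 1),
        _centered(
            [
                [1.39 * np.cos(k * np.pi / 3), 1.39 * np.sin(k * np.pi / 3), 0.0]
                for k in range(6)
            ]
        ),
        (1.0, -1.0, 1.0, -1.0, 1.0, -1.0),
    ),
    # charged diatomic: energy/latmin tests only (rigid-body Hessian is
    # singular for linear molecules)
    "diatomic": (
        ("C", "O"),
        (0, 1),
        _centered([[0.55, 0.0, 0.0], [-0.55, 0.0, 0.0]]),
        (1.0, -1.0),
    ),
}

_SPACE_GROUPS = {
    "P1": [SymmetryOp.identity()],
    "P-1": [
        SymmetryOp.identity(),
        SymmetryOp.create(-np.eye(3, dtype=int), np.zeros(3)),
    ],
    "P21": [
        SymmetryOp.identity(),
        SymmetryOp.create(
            [[-1, 0, 0], [0, 1, 0], [0, 0, -1]], [0.0, 0.5, 0.0]
        ),
    ],
}


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one toy crystal."""

    template: str = "bent3"
    atom_types: tuple[str, str] = ("T1", "T2")
    charge: float = 0.25  # e; slot scale factor
    space_group: str = "P1"
    cell_range: tuple[float, float] = (5.5, 7.5)  # initial lengths, A
    min_contact: float = 2.0  # initial packing bound, A

    def __post_init__(self):
        if self.template not in TEMPLATES:
            raise ConfigError(f"unknown template {self.template!r}")
        if self.space_group not in _SPACE_GROUPS:
            raise ConfigError(f"unsupported space group {self.space_group!r}")


def default_true_potentials(
    types: tuple[str, str] = ("T1", "T2"), free: bool = True
) -> PotentialSet:
    """A transferable-magnitude (FIT-like) explicit Buckingham set for two
    atom types: T1 carbon-like, T2 hydrogen-like; B fixed, A and C free."""
    t1, t2 = types
    fl = (free, False, free)
    key = lambda a, b: (a, b) if a <= b else (b, a)
    return PotentialSet(
        (t1, t2),
        {
            key(t1, t1): PairPotential(369743.0, 3.60, 2439.8, free=fl),
            key(t1, t2): PairPotential(66530.0, 3.67, 577.0, free=fl),
            key(t2, t2): PairPotential(11971.0, 3.74, 136.4, free=fl),
        },
    )


def make_toy_molecule(spec: ToySpec) -> RigidMolecule:
    elements, type_slots, local, charge_slots = TEMPLATES[spec.template]
    types = tuple(spec.atom_types[s] for s in type_slots)
    charges = spec.charge * np.asarray(charge_slots, dtype=float)
    return RigidMolecule.create(
        elements, types, local, charges, center=np.zeros(3)
    )


def min_intermolecular_distance(crystal: Crystal, search: float = 8.0) -> float:
    """Shortest intermolecular atom-atom distance over periodic images."""
    geom = _Geometry(crystal, order=0)
    _, _, _, rvec = _enumerate_pairs(geom, search)
    if len(rvec) == 0:
        return np.inf
    return float(np.linalg.norm(rvec, axis=-1).min())


def _random_quaternion(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return q if q[0] >= 0 else -q


def make_toy_crystal(spec: ToySpec, seed, max_tries: int = 200) -> Crystal:
    """Deterministic random packing with no initial contact below 2 A."""
    rng = np.random.default_rng(seed)
    ops = _SPACE_GROUPS[spec.space_group]
    mol0 = make_toy_molecule(spec)
    lo, hi = spec.cell_range
    # roomier cells for multi-molecule cells
    scale = 1.0 if spec.space_group == "P1" else 1.3
    for _ in range(max_tries):
        if spec.space_group == "P21":
            lat = Lattice(
                rng.uniform(lo, hi) * scale,
                rng.uniform(lo, hi) * scale,
                rng.uniform(lo, hi) * scale,
                90.0,
                rng.uniform(95.0, 115.0),
                90.0,
                CrystalSystem.MONOCLINIC,
            )
        else:
            lat = Lattice(
                rng.uniform(lo, hi) * scale,
                rng.uniform(lo, hi) * scale,
                rng.uniform(lo, hi) * scale,
                rng.uniform(78.0, 102.0),
                rng.uniform(78.0, 102.0),
                rng.uniform(78.0, 102.0),
                CrystalSystem.TRICLINIC,
            )
        if spec.space_group == "P1":
            center = rng.uniform(0.0, 1.0, size=3)
        else:
            center = rng.uniform(0.12, 0.38, size=3)  # clear of 0 and 1/2
        mol = RigidMolecule.create(
            mol0.elements, mol0.atom_types, mol0.local, mol0.charges,
            center=center, quaternion=_random_quaternion(rng),
        )
        crystal = Crystal.create(lat, ops, [mol], label=spec.template)
        try:
            expand_symmetry(crystal)  # special-position check
        except Exception:
            continue
        if min_intermolecular_distance(crystal) >= spec.min_contact:
            crystal.validate()
            return crystal
    raise GenerationError(
        f"could not pack {spec.template} in {spec.space_group} after "
        f"{max_tries} tries"
    )


def generate_reference_set(
    specs: list[ToySpec],
    p_true: PotentialSet,
    seed: int,
    lm_opts: LMOptions = LMOptions(cutoff=10.0),
    max_regen: int = 12,
) -> list[ReferenceEntry]:
    """Relax each toy crystal under the true parameters; the relaxed
    geometry and its intermolecular energy become the reference data.

    Entries whose lattice minimization fails (or relaxes into an unphysical
    contact) are regenerated with a fresh sub-seed.  The same ``lm_opts``
    must be used when fitting against the returned entries.
    """
    entries = []
    for s_idx, spec in enumerate(specs):
        ok = False
        for attempt in range(max_regen):
            crystal = make_toy_crystal(spec, seed=[seed, s_idx, attempt])
            lm = minimize_lattice(crystal, p_true, opts=lm_opts)
            if lm.status is not LMStatus.CONVERGED:
                continue
            if min_intermolecular_distance(lm.crystal_star) < 1.5:
                continue
            has_hp = "Hp" in lm.crystal_star.asym_unit[0].atom_types
            entries.append(
                ReferenceEntry(
                    crystal_ref=lm.crystal_star,
                    u_inter_ref=lm.U_star,
                    w_G=1.0,
                    w_E=0.0 if has_hp else 1.0,
                    label=f"{spec.template}-{spec.space_group}-{s_idx}",
                )
            )
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"persistent lattice-minimization failure for spec "
                f"{s_idx} ({spec.template}, {spec.space_group})"
            )
    return entries


def perturb_parameters(
    p_true: np.ndarray, scale: float, seed, bounds=None
) -> np.ndarray:
    """Multiplicative log-uniform perturbation of a parameter vector.

    Factors are drawn uniformly in log space from [ln(1-scale), ln(1+scale)];
    scale 0 returns the input unchanged.
    """
    p_true = np.asarray(p_true, dtype=float)
    if not 0.0 <= scale < 1.0:
        raise ConfigError("perturbation scale must be in [0, 1)")
    if scale == 0.0:
        return p_true.copy()
    rng = np.random.default_rng(seed)
    f = np.exp(
        rng.uniform(np.log(1.0 - scale), np.log(1.0 + scale), size=p_true.shape)
    )
    out = p_true * f
    if bounds is not None:
        out = np.clip(out, bounds[0], bounds[1])
    return out
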