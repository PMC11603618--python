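"""Geometry and energy residuals, per-structure merit function, and the
Total Merit Function over a training set.

For each structure the residuals compare the relaxed (force-field) geometry
and energy with the reference data:

* cell residuals ``X``: relative deviations of the free cell parameters,
  normalized by sqrt(n_x);
* coordinate residuals: deviations of fractional coordinates measured
  *relative to the first atom* of the asymmetric unit (which removes the
  global-translation degeneracy), each component mapped to the periodic
  image nearest its reference value, normalized by sqrt(3 N_at - 3);
* one energy residual: the relative deviation from the reference
  intermolecular energy.

``MF_s = 1/2 (w_G (|X|^2 + |Y|^2) + w_E E^2)`` and the TMF is the sum over
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import Crystal, Lattice, cell_matrix
from .energy import PotentialSet, inter_energy
from .errors import ConsistencyError, DomainError
from .latmin import LMOptions, LMResult, LMStatus, minimize_lattice

__all__ = [
    "ReferenceEntry",
    "ResidualSet",
    "lattice_residuals",
    "coord_residuals",
    "asym_fractional_coords",
    "energy_residual",
    "merit_function",
    "structure_residuals",
    "count_residuals",
    "total_merit",
    "TMFReport",
]


@dataclass(frozen=True)
class ReferenceEntry:
    """One training structure: reference geometry, reference intermolecular
    energy (kJ/mol) and merit-function weights."""

    crystal_ref: Crystal
    u_inter_ref: float
    w_G: float = 1.0
    w_E: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.w_G < 0 or self.w_E < 0:
            raise ConsistencyError("weights must be non-negative")


@dataclass
class ResidualSet:
    """Residual blocks and the merit function for one structure."""

    X: np.ndarray  # (n_x,)
    Y: np.ndarray  # (3 N_at - 3,)
    E: float
    MF: float

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.X, self.Y, [self.E]])


def lattice_residuals(
    lattice: Lattice, ref_lattice: Lattice
) -> np.ndarray:
    """Relative free-cell-parameter deviations over sqrt(n_x)."""
    if lattice.crystal_system is not ref_lattice.crystal_system:
        raise ConsistencyError("crystal systems differ")
    x = lattice.free_parameters()
    x_ref = ref_lattice.free_parameters()
    return (x - x_ref) / x_ref / np.sqrt(len(x))


def asym_fractional_coords(crystal: Crystal) -> np.ndarray:
    """Fractional coordinates of every asymmetric-unit atom (identity
    operator), unwrapped, in manifest atom order."""
    L = cell_matrix(crystal.lattice)
    Linv = np.linalg.inv(L)
    rows = []
    for mol in crystal.asym_unit:
        rows.append(mol.center + mol.rotated_local() @ Linv.T)
    return np.vstack(rows)


def coord_residuals(
    coords: np.ndarray, ref_coords: np.ndarray
) -> np.ndarray:
    """Relative-to-first-atom fractional coordinate residuals.

    ``coords`` and ``ref_coords`` are (N_at, 3) fractional positions in
    identical atom order; the first atom is the reference atom.
    """
    coords = np.asarray(coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    if coords.shape != ref_coords.shape or coords.ndim != 2:
        raise ConsistencyError("coordinate arrays must have identical shape")
    n_at = coords.shape[0]
    if n_at < 2:
        raise DomainError("need at least two atoms for relative coordinates")
    Y = coords[1:] - coords[0]
    Y_ref = ref_coords[1:] - ref_coords[0]
    d = Y - Y_ref
    d -= np.round(d)  # nearest periodic image of the reference value
    return d.ravel() / np.sqrt(3 * n_at - 3)


def energy_residual(
    U_star: float, U_ref: float, denominator: str = "abs"
) -> float:
    """Relative, sign-preserving energy deviation.

    ``denominator="abs"`` (default) divides by ``|U_ref|`` so underbinding
    (a less negative lattice energy) is always positive regardless of the
    sign convention of the reference energies; ``"signed"`` divides by
    ``U_ref`` itself.  The merit function squares the residual, so the fit
    is identical either way.
    """
    if U_ref == 0:
        raise DomainError("reference energy must be non-zero")
    if denominator == "signed":
        return (U_star - U_ref) / U_ref
    if denominator != "abs":
        raise ConsistencyError(f"unknown denominator convention {denominator!r}")
    return (U_star - U_ref) / abs(U_ref)


def merit_function(res: ResidualSet, w_G: float, w_E: float) -> float:
    if w_G < 0 or w_E < 0:
        raise ConsistencyError("weights must be non-negative")
    return 0.5 * (
        w_G * (float(res.X @ res.X) + float(res.Y @ res.Y)) + w_E * res.E**2
    )


def structure_residuals(
    crystal_star: Crystal, U_star: float, entry: ReferenceEntry
) -> ResidualSet:
    """Assemble the residual set of one relaxed structure against its
    reference entry and attach MF."""
    X = lattice_residuals(crystal_star.lattice, entry.crystal_ref.lattice)
    Y = coord_residuals(
        asym_fractional_coords(crystal_star),
        asym_fractional_coords(entry.crystal_ref),
    )
    E = energy_residual(U_star, entry.u_inter_ref)
    rs = ResidualSet(X=X, Y=Y, E=E, MF=0.0)
    rs.MF = merit_function(rs, entry.w_G, entry.w_E)
    return rs


def count_residuals(crystal: Crystal) -> int:
    """n_x + (3 N_at - 3) + 1 residuals for one structure."""
    n_at = crystal.n_atoms_asym
    return crystal.lattice.n_free + (3 * n_at - 3) + 1


@dataclass
class TMFReport:
    """Total merit function with per-structure diagnostics."""

    TMF: float
    valid: bool
    per_structure: list  # list of (label, ResidualSet | None, LMResult)
    failed_labels: list

    @property
    def lm_results(self) -> list:
        return [r for _, _, r in self.per_structure]


def total_merit(
    entries: list[ReferenceEntry],
    pots: PotentialSet,
    starts: list[Crystal] | None = None,
    lm_opts: LMOptions = LMOptions(),
) -> TMFReport:
    """Sum of MF_s over the training set; LM failures are reported, not
    raised (the estimator decides what to do with them)."""
    starts = starts or [e.crystal_ref for e in entries]
    per, failed, tmf = [], [], 0.0
    for entry, start in zip(entries, starts):
        lm = minimize_lattice(start, pots, opts=lm_opts)
        if not lm.converged:
            per.append((entry.label, None, lm))
            failed.append(entry.label)
            continue
        rs = structure_residuals(lm.crystal_star, lm.U_star, entry)
        per.append((entry.label, rs, lm))
        tmf += rs.MF
    return TMFReport(
        TMF=tmf, valid=not failed, per_structure=per, failed_labels=failed
    )
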