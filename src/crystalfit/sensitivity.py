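"""Analytic derivatives of residuals and merit functions with respect to
the free potential parameters.

The lattice minimization makes the relaxed geometry ``omega*`` and energy
``U*`` implicit functions of the Buckingham parameters ``p``.  Both are
differentiated without any additional lattice minimizations:

* the envelope result: ``dU*/dp`` equals the *partial* derivative of the
  repulsion/dispersion energy with respect to ``p`` evaluated at
  ``omega*`` - stationarity of the inner minimization kills the indirect
  dependence through the geometry;
* the implicit-function linear system: differentiating the stationarity
  condition ``grad_omega U = 0`` in ``p`` gives
  ``H . (d omega*/d p_j) = - d^2 U_rd / (d omega d p_j)``,
  solved with a symmetric (Cholesky) factorization of the converged
  Hessian, which is reused for every parameter column.

Geometry-residual derivatives then chain ``d omega*/dp`` through the
residual definitions analytically (cell rows through the free-parameter
map, coordinate rows through the fractional-position dependence on omega);
combining-rule dependence is already folded into the parameter-derivative
blocks by the energy engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal import (
    Crystal,
    cell_matrix_derivs,
    free_param_map,
    n_variables,
    _skew,
)
from .energy import EnergyReport, PotentialSet, inter_energy
from .errors import ConsistencyError, SensitivityUnavailableError
from .latmin import LMOptions, LMResult, LMStatus
from .residuals import ReferenceEntry, ResidualSet, structure_residuals

__all__ = [
    "SensitivityBlock",
    "d_uinter_dp",
    "d_omega_dp",
    "asym_frac_jacobian",
    "residual_jacobian",
    "structure_sensitivity",
]


@dataclass
class SensitivityBlock:
    """Per-structure parameter sensitivities."""

    dU_dp: np.ndarray  # (NP,)
    dOmega_dp: np.ndarray  # (n_omega, NP)
    dResiduals_dp: np.ndarray  # (n_x + 3N-3 + 1, NP)
    dMF_dp: np.ndarray  # (NP,)
    residuals: ResidualSet
    solve_residual: float  # relative residual of the linear solve


def d_uinter_dp(lm: LMResult, report: EnergyReport) -> np.ndarray:
    """Envelope theorem: dU*/dp = dU_rd/dp evaluated at omega*."""
    if lm.status is not LMStatus.CONVERGED:
        raise SensitivityUnavailableError(
            f"stale derivative: lattice minimization status {lm.status.value}"
        )
    return report.dU_rd_dp


def d_omega_dp(hessian: np.ndarray, cross: np.ndarray, null_tol: float = 1e-8):
    """Solve H . dOmega/dp_j = -cross[:, j] for all parameter columns.

    Space groups with a free origin leave exact zero modes in H (global
    translations the energy cannot see).  The solve is performed in the
    orthogonal complement of those modes; the component of dOmega*/dp along
    a flat direction is a pure gauge choice (the residuals are invariant
    there by the reference-atom construction) and is set to zero.

    Returns (dOmega_dp, relative solve residual).  Raises
    :class:`SensitivityUnavailableError` when H has a negative eigenvalue
    beyond the null tolerance (not a minimum).
    """
    lam, V = np.linalg.eigh(hessian)
    scale = float(np.abs(lam).max())
    if scale == 0.0 or lam.min() < -null_tol * scale:
        raise SensitivityUnavailableError(
            "Hessian not positive semi-definite at the reported minimum"
        )
    keep = lam > null_tol * scale
    inv = np.where(keep, 1.0 / np.where(keep, lam, 1.0), 0.0)
    X = -V @ (inv[:, None] * (V.T @ cross))
    # residual measured in the range of H (null components of the
    # right-hand side vanish identically for exact invariances)
    P_cross = V @ (np.where(keep, 1.0, 0.0)[:, None] * (V.T @ cross))
    bnorm = np.linalg.norm(cross)
    resid = np.linalg.norm(hessian @ X + P_cross) / bnorm if bnorm > 0 else 0.0
    return X, float(resid)


def asym_frac_jacobian(crystal: Crystal) -> np.ndarray:
    """d(asymmetric-unit fractional coordinates)/d(omega) at the crystal's
    zero-increment baseline; shape (N_at, 3, n_omega)."""
    lat = crystal.lattice
    L, dL6, _ = cell_matrix_derivs(lat)
    T = free_param_map(lat)
    dL = np.einsum("pij,pu->uij", dL6, T)
    Linv = np.linalg.inv(L)
    dLinv = -np.einsum("ij,ujk,kl->uil", Linv, dL, Linv)
    nx, zp = lat.n_free, crystal.z_prime
    nO = n_variables(crystal)
    E = [_skew(e) for e in np.eye(3)]
    out = []
    for m, mol in enumerate(crystal.asym_unit):
        d = mol.rotated_local()  # (n, 3)
        J = np.zeros((mol.n_atoms, 3, nO))
        J[:, :, nx + 3 * m : nx + 3 * m + 3] = np.eye(3)
        crossd = np.stack(
            [d @ Ei.T for Ei in E], axis=-1
        )  # (n, 3, 3): [:, :, j] = e_j x d
        J[:, :, nx + 3 * zp + 3 * m : nx + 3 * zp + 3 * m + 3] = np.einsum(
            "ik,nkj->nij", Linv, crossd
        )
        if nx:
            J[:, :, :nx] = np.einsum("uik,nk->niu", dLinv, d)
        out.append(J)
    return np.concatenate(out, axis=0)


def residual_jacobian(
    lm: LMResult,
    entry: ReferenceEntry,
    dOmega_dp: np.ndarray,
    dU_dp: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, ResidualSet]:
    """Chain dOmega*/dp and dU*/dp through the residual definitions.

    Returns (dResiduals_dp, dMF_dp, residual set), with rows ordered as the
    residual vector: cell, coordinates, energy.
    """
    star = lm.crystal_star
    res = structure_residuals(star, lm.U_star, entry)
    nx = star.lattice.n_free
    NP = dOmega_dp.shape[1]

    # cell rows: X_i = (omega_i - omega_ref_i) / omega_ref_i / sqrt(n_x)
    omega_ref = entry.crystal_ref.lattice.free_parameters()
    JX = dOmega_dp[:nx, :] / omega_ref[:, None] / np.sqrt(nx)

    # coordinate rows: Y components chain through the fractional positions
    Jf = asym_frac_jacobian(star)  # (N_at, 3, nO)
    n_at = Jf.shape[0]
    dY_dOmega = (Jf[1:] - Jf[0]).reshape(3 * (n_at - 1), -1)
    JY = (dY_dOmega @ dOmega_dp) / np.sqrt(3 * n_at - 3)

    # energy row (envelope derivative scaled by the residual normalization)
    JE = dU_dp[None, :] / abs(entry.u_inter_ref)

    J = np.vstack([JX, JY, JE])
    dMF = (
        entry.w_G * (res.X @ JX + res.Y @ JY)
        + entry.w_E * res.E * JE[0]
    )
    return J, dMF, res


def structure_sensitivity(
    lm: LMResult,
    entry: ReferenceEntry,
    pots: PotentialSet,
    lm_opts: LMOptions = LMOptions(),
) -> SensitivityBlock:
    """Full sensitivity block for one converged structure.

    Costs one energy/derivative evaluation at the already-relaxed geometry;
    no lattice minimizations.
    """
    rep = inter_energy(
        lm.crystal_star, pots, order=2, with_params=True,
        cutoff=lm_opts.cutoff, ewald_accuracy=lm_opts.ewald_accuracy,
    )
    dU = d_uinter_dp(lm, rep)
    dOm, solve_res = d_omega_dp(rep.hessian, rep.cross)
    J, dMF, res = residual_jacobian(lm, entry, dOm, dU)
    return SensitivityBlock(
        dU_dp=dU,
        dOmega_dp=dOm,
        dResiduals_dp=J,
        dMF_dp=dMF,
        residuals=res,
        solve_residual=solve_res,
    )
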