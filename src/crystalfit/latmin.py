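"""Two-stage rigid-body lattice-energy minimization.

The intermolecular energy is minimized over the rigid variables ``omega``
at fixed molecular conformation and fixed potential parameters:

* **Stage 1** - a quasi-Newton line-search descent (L-BFGS) working in a
  fixed chart anchored at the starting geometry.  Orientation gradients are
  mapped from the evaluated geometry's own zero-increment chart into the
  fixed chart through the SO(3) left Jacobian, so the objective and its
  gradient are mutually consistent.  Runs to a loose tolerance.
* **Stage 2** - a modified-Newton refinement using the analytic Hessian,
  re-baselined at every iteration (each iterate becomes the new chart
  origin).  Indefinite Hessians are eigenvalue-shifted; steps are
  backtracked so the energy never increases.  Runs to an infinity-norm
  gradient below ``stage2_tol`` (default 1e-9), the precision needed when
  the estimator iterates around the minimization.

Saddle points (indefinite Hessian at the terminal stationary point) and
atomic overlaps (interatomic distance below 0.3 A, the unphysical
short-range Buckingham regime) are reported as failure statuses, never
silently accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .crystal import (
    Crystal,
    apply_variables,
    extract_variables,
    n_variables,
    so3_left_jacobian,
)
from .energy import SOFT_CORE_R0, PotentialSet, inter_energy
from .errors import ConsistencyError, InvalidLatticeError, OverlapError

__all__ = ["LMStatus", "LMOptions", "LMResult", "minimize_lattice"]


class LMStatus(str, Enum):
    CONVERGED = "converged"
    SADDLE = "saddle"
    NOT_CONVERGED = "not_converged"
    OVERLAP_FAILURE = "overlap_failure"


@dataclass(frozen=True)
class LMOptions:
    cutoff: float = 15.0
    ewald_accuracy: float = 1e-6
    stage1_tol: float = 1e-5
    stage1_ftol: float = 1e-10  # stage 1 is a warm start; stage 2 refines
    stage2_tol: float = 1e-9
    max_iter_stage1: int = 300
    max_iter_stage2: int = 100
    saddle_eig_tol: float = 1e-8
    max_step: float = 0.25  # trust bound on a single Newton step component


@dataclass
class LMResult:
    """Outcome of one lattice minimization.

    ``omega_star`` applies to the *input* crystal; ``crystal_star`` is the
    relaxed geometry itself (its own zero-increment baseline, at which
    ``grad``, ``hessian`` and all sensitivity blocks are expressed).
    """

    status: LMStatus
    omega_star: np.ndarray
    crystal_star: Crystal
    U_star: float
    grad: np.ndarray
    grad_norm: float
    hessian: np.ndarray | None
    n_iter_stage1: int
    n_iter_stage2: int
    U_trace: list = None  # accepted stage-2 energies, non-increasing

    @property
    def converged(self) -> bool:
        return self.status is LMStatus.CONVERGED


def _orientation_slices(crystal: Crystal):
    nx = crystal.lattice.n_free
    zp = crystal.z_prime
    return [
        slice(nx + 3 * zp + 3 * m, nx + 3 * zp + 3 * m + 3) for m in range(zp)
    ]


def minimize_lattice(
    crystal: Crystal,
    pots: PotentialSet,
    omega0: np.ndarray | None = None,
    opts: LMOptions = LMOptions(),
) -> LMResult:
    """Problem LM: locally minimize U_inter over omega (deterministic)."""
    if omega0 is not None:
        crystal = apply_variables(crystal, omega0)
    base = crystal
    n = n_variables(crystal)
    osl = _orientation_slices(crystal)

    def fun(om):
        # energy and fixed-chart gradient at base + om on the soft-core
        # surface: short contacts cost a smooth, steep penalty instead of
        # raising, so line searches backtrack out of collapsed trials
        try:
            rep = inter_energy(
                base, pots, omega=om, order=1, soft_core=True,
                cutoff=opts.cutoff, ewald_accuracy=opts.ewald_accuracy,
            )
        except InvalidLatticeError:
            return 1e12, np.zeros(n)
        g = rep.grad.copy()
        for sl in osl:
            g[sl] = so3_left_jacobian(om[sl]).T @ g[sl]
        return rep.U_inter, g

    om = extract_variables(base)  # zero orientation increments at the base
    nx = crystal.lattice.n_free
    lengths = np.array(crystal.lattice.free_mask[:3]).sum()
    bounds = (
        [(1.0, None)] * int(lengths)
        + [(np.radians(20.0), np.radians(160.0))] * (nx - int(lengths))
        + [(None, None)] * (6 * crystal.z_prime)
    )
    res = _scipy_minimize(
        fun, om, jac=True, method="L-BFGS-B", bounds=bounds,
        options={
            "maxiter": opts.max_iter_stage1,
            "gtol": opts.stage1_tol,
            "ftol": opts.stage1_ftol,
        },
    )
    om = res.x
    it1 = int(res.nit)
    try:
        # stage 2 evaluates the true (hard-overlap) surface; a collapsed
        # stage-1 terminal state surfaces here as an overlap failure
        cur = apply_variables(base, om)
    except InvalidLatticeError:
        return _failure(base, LMStatus.OVERLAP_FAILURE)

    # ---- stage 2: re-baselined modified Newton (soft-core surface; the
    # penalty is inert at any physical geometry and the terminal point is
    # re-checked on the true surface below) ----
    it2 = 0

    def ev(cr, order):
        return inter_energy(
            cr, pots, order=order, soft_core=True,
            cutoff=opts.cutoff, ewald_accuracy=opts.ewald_accuracy,
        )

    U_trace = []
    try:
        rep = ev(cur, 2)
        U_trace.append(rep.U_inter)
        while np.abs(rep.grad).max() > opts.stage2_tol and it2 < opts.max_iter_stage2:
            it2 += 1
            lam, V = np.linalg.eigh(rep.hessian)
            floor = max(1e-6 * np.abs(lam).max(), 1e-10)
            lam_mod = np.maximum(np.abs(lam), floor)
            step = -V @ ((V.T @ rep.grad) / lam_mod)
            smax = np.abs(step).max()
            if smax > opts.max_step:
                step *= opts.max_step / smax
            # backtracking: energy must not increase
            t = 1.0
            g_dot_s = float(rep.grad @ step)
            om_cur = extract_variables(cur)  # orientation block is zero
            trial = None
            for _ in range(40):
                try:
                    cand = apply_variables(cur, om_cur + t * step)
                    U_t = ev(cand, 0).U_inter
                except InvalidLatticeError:
                    t *= 0.5
                    continue
                if U_t <= rep.U_inter + 1e-4 * t * g_dot_s + 1e-13 * abs(rep.U_inter):
                    trial = cand
                    break
                t *= 0.5
            if trial is None:
                break  # no acceptable step; report at current point
            cur = trial
            rep = ev(cur, 2)
            U_trace.append(rep.U_inter)
    except InvalidLatticeError:
        return _failure(base, LMStatus.OVERLAP_FAILURE)

    # terminal evaluation on the true surface (hard overlap detection); a
    # terminal state held up by the soft-core penalty is a collapse, not a
    # minimum of the physical surface
    try:
        rep = inter_energy(
            cur, pots, order=2, cutoff=opts.cutoff,
            ewald_accuracy=opts.ewald_accuracy,
        )
        if _min_contact(cur) < SOFT_CORE_R0:
            return _failure(base, LMStatus.OVERLAP_FAILURE)
    except (OverlapError, InvalidLatticeError):
        return _failure(base, LMStatus.OVERLAP_FAILURE)

    gnorm = float(np.abs(rep.grad).max())
    lam = np.linalg.eigvalsh(rep.hessian)
    scale = max(np.abs(lam).max(), 1.0)
    if gnorm > opts.stage2_tol:
        status = LMStatus.NOT_CONVERGED
    elif lam.min() < -opts.saddle_eig_tol * scale:
        status = LMStatus.SADDLE
    else:
        status = LMStatus.CONVERGED
    return LMResult(
        status=status,
        omega_star=extract_variables(cur, base=base),
        crystal_star=cur,
        U_star=rep.U_inter,
        grad=rep.grad,
        grad_norm=gnorm,
        hessian=rep.hessian,
        n_iter_stage1=it1,
        n_iter_stage2=it2,
        U_trace=U_trace,
    )


def _min_contact(crystal: Crystal) -> float:
    """Shortest intermolecular contact (A) over periodic images."""
    from .energy import SOFT_CORE_R0, _Geometry, _enumerate_pairs

    geom = _Geometry(crystal, order=0)
    _, _, _, rvec = _enumerate_pairs(geom, max(8.0, 2.0 * SOFT_CORE_R0))
    if len(rvec) == 0:
        return np.inf
    return float(np.linalg.norm(rvec, axis=-1).min())


def _failure(base: Crystal, status: LMStatus) -> LMResult:
    n = n_variables(base)
    return LMResult(
        status=status,
        omega_star=np.zeros(n),
        crystal_star=base,
        U_star=np.nan,
        grad=np.full(n, np.nan),
        grad_norm=np.nan,
        hessian=None,
        n_iter_stage1=0,
        n_iter_stage2=0,
    )
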