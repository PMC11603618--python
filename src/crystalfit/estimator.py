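"""Outer parameter estimation: robust bound-constrained least squares over
the Buckingham parameters with dynamic starting points, reinitialization
criteria, structure removal, and Sobol multistart.

The total merit function is a sum of squared weighted residuals whose inner
quantities come from lattice minimizations, which makes the objective
piecewise smooth: as the parameters move, an inner minimization can hop
between energy basins and the TMF jumps.  The machinery here manages that:

* **dynamic starting points** - each structure's lattice minimization is
  warm-started from the optimum found in the previous TMF evaluation, which
  keeps successive evaluations in the same basin and suppresses jumps; the
  very first evaluation starts from the reference geometries;
* **re-evaluation** - after the inner solver terminates, the TMF is
  re-evaluated from the *original reference geometries*; agreement means
  starting-point drift was immaterial and the result is accepted (B3);
* **reinitialization criteria** - otherwise the optimization is restarted
  from the current estimates until the re-evaluated TMF stalls (B4,
  insufficient decrease), worsens (B5, keep the previous estimates), or a
  reinitialization limit is reached (B6);
* **structure removal** - a failed lattice minimization (overlap, saddle,
  no convergence) aborts the current solve; the offending structure is
  removed and the solve restarts from the last successful iterate (D3).
  After termination all removed structures are reintroduced for one final
  optimization and re-evaluation, with no further iterations;
* **Sobol multistart** - independent runs from unscrambled Sobol' points
  mapped into user-specified parameter bounds, clustered afterwards into
  distinct minima by re-evaluated TMF and scaled parameter distance.

Gradients of the residual vector are the analytic implicit-function
Jacobians: a TMF evaluation costs exactly one lattice minimization per
structure and its gradient costs none.
"""

from __future__ import annotations

import itertools
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .crystal import Crystal
from .energy import PotentialSet
from .errors import ConfigError, ConsistencyError, SensitivityUnavailableError
from .latmin import LMOptions, minimize_lattice
from .residuals import ReferenceEntry
from .sensitivity import structure_sensitivity

__all__ = [
    "EstimationOptions",
    "EstimationStatus",
    "EstimationResult",
    "MultistartResult",
    "TMFEvaluator",
    "StructureFailure",
    "sobol_starts",
    "schedule_structures",
    "run_local",
    "run_multistart",
    "cluster_minima",
    "count_free_parameters",
]


class EstimationStatus(str, Enum):
    B3_CONVERGED = "B3_converged"
    B4_SLOW_DECREASE = "B4_slow_decrease"
    B5_INCREASE = "B5_increase"
    B6_REINIT_LIMIT = "B6_reinit_limit"
    FAILED = "failed"


@dataclass(frozen=True)
class EstimationOptions:
    """Knobs of the outer estimation loop."""

    reinit_limit: int = 10
    b4_rel_decrease: float = 1e-3  # "insufficient decrease" threshold
    b3_rel_tol: float = 1e-8  # re-evaluated TMF unchanged (relative)
    b3_abs_tol: float = 1e-12  # ... and absolute floor for tiny TMFs
    cluster_tmf_rtol: float = 1e-3
    cluster_param_tol: float = 1e-2  # infinity-norm on scaled parameters
    workers: int = 1
    lm: LMOptions = field(default_factory=LMOptions)
    inner_max_nfev: int = 200
    inner_ftol: float = 1e-12
    inner_xtol: float = 1e-12
    inner_gtol: float = 1e-12

    def __post_init__(self):
        if self.reinit_limit < 1:
            raise ConfigError("reinit_limit must be >= 1")
        for name in ("b4_rel_decrease", "b3_rel_tol", "cluster_tmf_rtol",
                     "cluster_param_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass
class EstimationResult:
    p_hat: np.ndarray
    TMF_final: float  # re-evaluated from the reference geometries
    status: EstimationStatus
    removed_history: list  # (event, label, attempt index)
    trace: list  # (attempt, TMF at solver optimum, re-evaluated TMF)
    lm_calls: int
    n_attempts: int
    message: str = ""


@dataclass
class MultistartResult:
    results: list  # EstimationResult per start (order of the Sobol points)
    clusters: list  # list of lists of result indices
    best: EstimationResult | None


class StructureFailure(Exception):
    """A lattice minimization failed during a TMF evaluation."""

    def __init__(self, index: int, label: str, status: str):
        super().__init__(f"structure {label!r} failed ({status})")
        self.index = index
        self.label = label
        self.status = status


# ---------------------------------------------------------------------------
# TMF evaluation with dynamic starting points
# ---------------------------------------------------------------------------


class TMFEvaluator:
    """Weighted residual vector and Jacobian over the active training set.

    ``__call__(p)`` returns (f, J) with ``TMF = 0.5 f.f``; results are
    cached per parameter vector so the solver's separate fun/jac calls cost
    one pass.  Lattice minimizations are warm-started from the previous
    evaluation's optima; ``reset_starts`` reverts to the reference
    geometries.  Structures are dispatched to a worker pool in order of
    decreasing estimated cost, and results are assembled in training-set
    order, so parallel and serial runs are identical.
    """

    def __init__(
        self,
        entries: list[ReferenceEntry],
        pots: PotentialSet,
        opts: EstimationOptions = EstimationOptions(),
    ):
        if not entries:
            raise ConsistencyError("empty training set")
        self.entries = list(entries)
        self.pots = pots
        self.opts = opts
        self.active = list(range(len(entries)))
        self.lm_calls = 0
        self.n_evaluations = 0
        self.costs = np.zeros(len(entries))
        self.last_good_p: np.ndarray | None = None
        self.trace: list[tuple[np.ndarray, float]] = []
        self._cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}
        self.reset_starts()

    # -- training-set management -------------------------------------------

    def reset_starts(self) -> None:
        self.starts: dict[int, Crystal] = {
            i: self.entries[i].crystal_ref for i in range(len(self.entries))
        }
        self._cache.clear()

    def remove(self, index: int) -> None:
        self.active = [i for i in self.active if i != index]
        self._cache.clear()

    def reintroduce_all(self) -> None:
        self.active = list(range(len(self.entries)))
        self._cache.clear()

    # -- evaluation ---------------------------------------------------------

    def _one(self, i: int, pots_p: PotentialSet):
        t0 = time.perf_counter()
        entry = self.entries[i]
        lm = minimize_lattice(self.starts[i], pots_p, opts=self.opts.lm)
        if not lm.converged:
            return i, None, None, None, time.perf_counter() - t0
        try:
            sens = structure_sensitivity(lm, entry, pots_p, self.opts.lm)
        except SensitivityUnavailableError:
            return i, None, None, None, time.perf_counter() - t0
        sw = np.concatenate(
            [
                np.full(sens.residuals.X.size + sens.residuals.Y.size,
                        np.sqrt(entry.w_G)),
                [np.sqrt(entry.w_E)],
            ]
        )
        f_i = sw * sens.residuals.vector
        J_i = sw[:, None] * sens.dResiduals_dp
        return i, lm, f_i, J_i, time.perf_counter() - t0

    def __call__(self, p: np.ndarray):
        key = np.asarray(p, dtype=float).tobytes()
        if key in self._cache:
            return self._cache[key]
        pots_p = self.pots.with_vector(p)
        order = [self.active[k] for k in schedule_structures(self.costs[self.active])]
        if self.opts.workers > 1:
            with ThreadPoolExecutor(max_workers=self.opts.workers) as pool:
                results = list(pool.map(lambda i: self._one(i, pots_p), order))
        else:
            results = [self._one(i, pots_p) for i in order]
        self.lm_calls += len(order)
        self.n_evaluations += 1
        by_index = {r[0]: r for r in results}
        fs, Js = [], []
        for i in self.active:  # deterministic training-set order
            _, lm, f_i, J_i, dt = by_index[i]
            self.costs[i] = dt
            if lm is None:
                raise StructureFailure(i, self.entries[i].label, "lm_failure")
            self.starts[i] = lm.crystal_star  # dynamic starting point
            fs.append(f_i)
            Js.append(J_i)
        f = np.concatenate(fs)
        J = np.vstack(Js)
        self.last_good_p = np.asarray(p, dtype=float).copy()
        self.trace.append((self.last_good_p, 0.5 * float(f @ f)))
        if len(self._cache) > 4:
            self._cache.clear()
        self._cache[key] = (f, J)
        return f, J

    def tmf(self, p: np.ndarray) -> float:
        f, _ = self(p)
        return 0.5 * float(f @ f)


# ---------------------------------------------------------------------------
# scheduling and Sobol starts
# ---------------------------------------------------------------------------


def schedule_structures(cost_estimates) -> np.ndarray:
    """Indices in stable order of decreasing estimated cost."""
    costs = np.asarray(cost_estimates, dtype=float)
    return np.argsort(-costs, kind="stable")


def sobol_starts(n: int, bounds, skip: int = 0) -> np.ndarray:
    """``n`` unscrambled Sobol' points mapped into per-parameter bounds.

    Deterministic: identical (n, bounds, skip) give identical points, and
    later points extend the sequence without reshuffling earlier ones.
    """
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    if lo.shape != hi.shape or lo.ndim != 1:
        raise ConfigError("bounds must be two equal-length vectors")
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ConfigError("Sobol sampling bounds must be finite")
    if np.any(hi <= lo):
        raise ConfigError("upper bounds must exceed lower bounds")
    eng = qmc.Sobol(d=len(lo), scramble=False)
    if skip:
        eng.fast_forward(skip)
    u = eng.random(n)
    return lo + u * (hi - lo)


# ---------------------------------------------------------------------------
# the reinitialization (B-criteria) loop, mockable for unit tests
# ---------------------------------------------------------------------------


def b_criteria_loop(attempt, reevaluate, p0, opts: EstimationOptions):
    """Drive repeated inner optimizations until a termination criterion.

    ``attempt(p_start, m) -> (p_hat, tmf_opt)`` runs one inner optimization
    (attempt index ``m``); ``reevaluate(p) -> float`` computes the TMF from
    the original reference geometries.  Returns
    (p_final, tmf_final, status, n_attempts, trace).
    """
    trace = []
    prev_p, prev_tmf = None, None
    p_start = np.asarray(p0, dtype=float)
    m = 0
    while True:
        p_m, tmf_opt = attempt(p_start, m)
        tmf_re = reevaluate(p_m)
        trace.append((m, float(tmf_opt), float(tmf_re)))
        # B3: drift-free optimum — re-evaluation reproduces the solver TMF
        if abs(tmf_re - tmf_opt) <= max(
            opts.b3_abs_tol, opts.b3_rel_tol * max(abs(tmf_opt), abs(tmf_re))
        ):
            return p_m, tmf_re, EstimationStatus.B3_CONVERGED, m + 1, trace
        if prev_tmf is not None:
            if tmf_re > prev_tmf:  # B5: got worse, keep the previous result
                return prev_p, prev_tmf, EstimationStatus.B5_INCREASE, m + 1, trace
            if prev_tmf - tmf_re < opts.b4_rel_decrease * prev_tmf:  # B4
                return p_m, tmf_re, EstimationStatus.B4_SLOW_DECREASE, m + 1, trace
        if m >= opts.reinit_limit:  # B6
            if prev_tmf is not None and prev_tmf < tmf_re:
                return prev_p, prev_tmf, EstimationStatus.B6_REINIT_LIMIT, m + 1, trace
            return p_m, tmf_re, EstimationStatus.B6_REINIT_LIMIT, m + 1, trace
        prev_p, prev_tmf = p_m, tmf_re
        p_start = p_m
        m += 1


# ---------------------------------------------------------------------------
# local estimation (one starting vector)
# ---------------------------------------------------------------------------


def _solve_inner(ev: TMFEvaluator, p0, bounds, opts: EstimationOptions):
    """One bound-constrained least-squares solve with analytic Jacobian."""
    scale = np.maximum(np.abs(p0), 1.0)

    def fun(p):
        return ev(p)[0]

    def jac(p):
        return ev(p)[1]

    res = least_squares(
        fun,
        p0,
        jac=jac,
        bounds=bounds,
        method="trf",
        x_scale=scale,
        ftol=opts.inner_ftol,
        xtol=opts.inner_xtol,
        gtol=opts.inner_gtol,
        max_nfev=opts.inner_max_nfev,
    )
    return res.x, float(res.cost)


def run_local(
    p0: np.ndarray,
    entries: list[ReferenceEntry],
    pots: PotentialSet,
    opts: EstimationOptions = EstimationOptions(),
) -> EstimationResult:
    """Full single-start estimation with the control flow described above."""
    p0 = np.asarray(p0, dtype=float)
    lo, hi = pots.bounds()
    if np.any(p0 < lo) or np.any(p0 > hi):
        raise ConfigError("starting parameters violate the bounds")
    ev = TMFEvaluator(entries, pots, opts)
    removed_history: list = []
    attempt_idx = [0]

    def attempt(p_start, m):
        attempt_idx[0] = m
        ev.reset_starts()  # first evaluation of each attempt uses omega_ref
        p_cur = p_start
        while True:
            try:
                return _solve_inner(ev, p_cur, (lo, hi), opts)
            except StructureFailure as sf:  # D3: remove and restart
                ev.remove(sf.index)
                removed_history.append(("removed", sf.label, m))
                if not ev.active:
                    raise
                if ev.last_good_p is not None:
                    p_cur = ev.last_good_p

    def reevaluate(p):
        ev.reset_starts()
        return ev.tmf(p)

    try:
        p_hat, tmf_final, status, n_attempts, trace = b_criteria_loop(
            attempt, reevaluate, p0, opts
        )
    except StructureFailure as sf:
        return EstimationResult(
            p_hat=p0, TMF_final=np.inf, status=EstimationStatus.FAILED,
            removed_history=removed_history, trace=[], lm_calls=ev.lm_calls,
            n_attempts=attempt_idx[0] + 1,
            message=f"all structures removed (last: {sf.label})",
        )

    if removed_history:
        # A3-A5: reintroduce removed structures, one final optimization and
        # re-evaluation; reported without further iterations
        ev.reintroduce_all()
        removed_history.append(("reintroduced_all", None, n_attempts))
        try:
            ev.reset_starts()
            p_fin, tmf_opt = _solve_inner(ev, p_hat, (lo, hi), opts)
            tmf_fin = reevaluate(p_fin)
            trace.append(("final", float(tmf_opt), float(tmf_fin)))
            p_hat, tmf_final = p_fin, tmf_fin
        except StructureFailure as sf:
            removed_history.append(("final_pass_failed", sf.label, n_attempts))

    return EstimationResult(
        p_hat=np.asarray(p_hat, dtype=float),
        TMF_final=float(tmf_final),
        status=status,
        removed_history=removed_history,
        trace=trace,
        lm_calls=ev.lm_calls,
        n_attempts=n_attempts,
    )


# ---------------------------------------------------------------------------
# multistart and clustering
# ---------------------------------------------------------------------------


def run_multistart(
    n_points: int,
    entries: list[ReferenceEntry],
    pots: PotentialSet,
    sobol_bounds,
    opts: EstimationOptions = EstimationOptions(),
    skip: int = 0,
) -> MultistartResult:
    """Independent local estimations from Sobol' starting vectors."""
    if n_points < 1:
        raise ConfigError("need at least one starting point")
    starts = sobol_starts(n_points, sobol_bounds, skip=skip)
    lo, hi = pots.bounds()
    results = []
    for p0 in starts:
        p0c = np.clip(p0, lo, hi)
        results.append(run_local(p0c, entries, pots, opts))
    clusters = cluster_minima(results, opts)
    ok = [r for r in results if r.status is not EstimationStatus.FAILED]
    best = min(ok, key=lambda r: r.TMF_final) if ok else None
    return MultistartResult(results=results, clusters=clusters, best=best)


def cluster_minima(results: list[EstimationResult], opts: EstimationOptions):
    """Greedy clustering of non-failed results: same minimum when the
    re-evaluated TMFs agree (relative) AND the scaled parameters agree in
    infinity norm."""
    idx = [
        i for i, r in enumerate(results)
        if r.status is not EstimationStatus.FAILED
    ]
    idx.sort(key=lambda i: results[i].TMF_final)
    clusters: list[list[int]] = []
    for i in idx:
        r = results[i]
        for cl in clusters:
            rep = results[cl[0]]
            scale = np.maximum(np.abs(rep.p_hat), 1e-30)
            same_tmf = abs(r.TMF_final - rep.TMF_final) <= (
                opts.cluster_tmf_rtol * max(abs(rep.TMF_final), 1e-300)
                + opts.b3_abs_tol
            )
            same_p = np.max(np.abs(r.p_hat - rep.p_hat) / scale) <= (
                opts.cluster_param_tol
            )
            if same_tmf and same_p:
                cl.append(i)
                break
        else:
            clusters.append([i])
    return clusters


# ---------------------------------------------------------------------------
# bookkeeping: free-parameter counting under the fitting conventions
# ---------------------------------------------------------------------------


def count_free_parameters(
    atom_types,
    fixed_C_types: tuple = ("Hp",),
    absent_pairs: tuple = (("Cl", "S"),),
) -> int:
    """Number of free Buckingham parameters for a training problem.

    Conventions: every distinct type pair is fitted explicitly; B is held
    fixed at transferable (FIT) values; A and C are free, except that C is
    fixed to zero for any pair involving a polarized hydrogen (Hp), and
    pairs absent from the data (by default S-Cl) are not parametrized.
    """
    absent = {tuple(sorted(p)) for p in absent_pairs}
    n = 0
    for t1, t2 in itertools.combinations_with_replacement(sorted(atom_types), 2):
        if (t1, t2) in absent:
            continue
        n += 1  # A
        if t1 not in fixed_C_types and t2 not in fixed_C_types:
            n += 1  # C
    return n
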