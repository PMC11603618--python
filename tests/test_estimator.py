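"""Outer estimation: Sobol starts, termination criteria, scheduling,
clustering, and the worker-pool determinism contract."""

import numpy as np
import pytest

from crystalfit.errors import ConfigError
from crystalfit.estimator import (
    EstimationOptions,
    EstimationStatus,
    TMFEvaluator,
    b_criteria_loop,
    cluster_minima,
    count_free_parameters,
    run_local,
    schedule_structures,
    sobol_starts,
)
from crystalfit.synthetic import default_true_potentials, perturb_parameters


def _sobol_oracle_2d(n):
    """Gray-code Sobol' generator from textbook direction numbers: the
    first dimension is the van der Corput sequence (m = 1,1,1,...), the
    second uses the primitive polynomial x + 1 with m = 1,3,5,15,...

    Independent of scipy: direct bitwise construction.
    """
    bits = 30
    # direction integers scaled to 2^bits
    v1 = [1 << (bits - j - 1) for j in range(bits)]
    m2 = [1]
    for j in range(1, bits):
        # recurrence for poly x + 1 (degree 1, a = 1): m_j = m_{j-1} XOR 2 m_{j-1}
        m2.append(m2[j - 1] ^ (2 * m2[j - 1]))
    v2 = [m2[j] << (bits - j - 1) for j in range(bits)]
    pts = np.empty((n, 2))
    x = [0, 0]
    pts[0] = 0.0
    for i in range(1, n):
        c = (~(i - 1) & i).bit_length() - 1  # rightmost zero bit of i-1
        x[0] ^= v1[c]
        x[1] ^= v2[c]
        pts[i] = [x[0] / 2.0**bits, x[1] / 2.0**bits]
    return pts


class TestSobolStarts:
    def test_within_bounds(self):
        lo = np.array([1.0, 10.0, 100.0])
        hi = np.array([2.0, 20.0, 400.0])
        pts = sobol_starts(16, (lo, hi))
        assert np.all(pts >= lo) and np.all(pts <= hi)

    def test_deterministic(self):
        b = (np.zeros(4), np.ones(4))
        assert np.array_equal(sobol_starts(8, b, skip=3), sobol_starts(8, b, skip=3))

    def test_first_points_match_direction_number_oracle(self):
        pts = sobol_starts(8, (np.zeros(2), np.ones(2)))
        oracle = _sobol_oracle_2d(8)
        assert np.allclose(pts, oracle, atol=1e-12)

    def test_extension_not_reshuffle(self):
        b = (np.zeros(3), np.ones(3))
        a8 = sobol_starts(8, b)
        a4 = sobol_starts(4, b)
        assert np.array_equal(a8[:4], a4)

    def test_unbounded_range_rejected(self):
        with pytest.raises(ConfigError):
            sobol_starts(4, (np.zeros(2), np.array([1.0, np.inf])))


class TestBCriteria:
    """Every termination branch of the reinitialization loop, driven by
    mocked TMF sequences."""

    def _opts(self, **kw):
        return EstimationOptions(**kw)

    def test_b3_reevaluation_unchanged(self):
        attempt = lambda p, m: (p + 1.0, 5.0)
        reeval = lambda p: 5.0
        p, tmf, status, n, _ = b_criteria_loop(
            attempt, reeval, np.zeros(2), self._opts()
        )
        assert status is EstimationStatus.B3_CONVERGED
        assert n == 1 and tmf == 5.0

    def test_b4_insufficient_decrease(self):
        seq = iter([10.0, 9.9999])  # re-evaluated TMFs: tiny improvement
        attempt = lambda p, m: (p, 1.0)
        reeval = lambda p: next(seq)
        p, tmf, status, n, _ = b_criteria_loop(
            attempt, reeval, np.zeros(2), self._opts()
        )
        assert status is EstimationStatus.B4_SLOW_DECREASE
        assert n == 2 and tmf == 9.9999

    def test_b5_increase_keeps_previous(self):
        seq = iter([10.0, 12.0])
        attempts = iter([np.array([1.0]), np.array([2.0])])
        attempt = lambda p, m: (next(attempts), 1.0)
        reeval = lambda p: next(seq)
        p, tmf, status, n, _ = b_criteria_loop(
            attempt, reeval, np.zeros(1), self._opts()
        )
        assert status is EstimationStatus.B5_INCREASE
        assert tmf == 10.0 and p[0] == 1.0  # previous attempt's estimates

    def test_b6_reinit_limit_exact(self):
        """With reinit_limit=1 and a persistently drifting objective the
        loop stops after exactly one reinitialization."""
        calls = []

        def attempt(p, m):
            calls.append(m)
            return p, 1.0

        seq = iter([10.0, 4.0, 2.0, 1.0])  # large decreases: never B4/B5
        reeval = lambda p: next(seq)
        _, tmf, status, n, _ = b_criteria_loop(
            attempt, reeval, np.zeros(2), self._opts(reinit_limit=1)
        )
        assert status is EstimationStatus.B6_REINIT_LIMIT
        assert calls == [0, 1]  # initial attempt + one reinitialization
        assert n == 2 and tmf == 4.0

    def test_invalid_options(self):
        with pytest.raises(ConfigError):
            EstimationOptions(reinit_limit=0)


class TestScheduling:
    def test_descending_costs(self):
        assert list(schedule_structures([3.0, 1.0, 2.0])) == [0, 2, 1]

    def test_stable_ties(self):
        assert list(schedule_structures([2.0, 2.0, 1.0, 2.0])) == [0, 1, 3, 2]

    def test_parallel_equals_serial(self, refset2, fit_pots, lm_opts):
        p = fit_pots.get_vector() * 1.04
        f1, J1 = TMFEvaluator(
            refset2, fit_pots, EstimationOptions(lm=lm_opts, workers=1)
        )(p)
        f2, J2 = TMFEvaluator(
            refset2, fit_pots, EstimationOptions(lm=lm_opts, workers=2)
        )(p)
        assert np.array_equal(f1, f2)
        assert np.array_equal(J1, J2)


class TestClustering:
    def _result(self, p, tmf, status=EstimationStatus.B3_CONVERGED):
        from crystalfit.estimator import EstimationResult

        return EstimationResult(
            p_hat=np.asarray(p, dtype=float), TMF_final=tmf, status=status,
            removed_history=[], trace=[], lm_calls=0, n_attempts=1,
        )

    def test_partition_property(self):
        results = [
            self._result([1.0, 2.0], 1.0),
            self._result([1.0001, 2.0002], 1.0001),
            self._result([5.0, 6.0], 3.0),
            self._result([0.0, 0.0], np.inf, EstimationStatus.FAILED),
        ]
        clusters = cluster_minima(results, EstimationOptions())
        flat = sorted(i for cl in clusters for i in cl)
        assert flat == [0, 1, 2]  # disjoint cover of non-failed results
        assert sorted(map(len, clusters)) == [1, 2]

    def test_distinct_minima_not_merged(self):
        results = [self._result([1.0], 1.0), self._result([1.5], 1.0)]
        clusters = cluster_minima(results, EstimationOptions())
        assert len(clusters) == 2


class TestRunLocal:
    def test_duplicate_start_bitwise_identical(self, refset2, fit_pots, lm_opts):
        p0 = perturb_parameters(fit_pots.get_vector(), 0.1, seed=3)
        opts = EstimationOptions(lm=lm_opts)
        r1 = run_local(p0, refset2, fit_pots, opts)
        r2 = run_local(p0, refset2, fit_pots, opts)
        assert np.array_equal(r1.p_hat, r2.p_hat)
        assert r1.TMF_final == r2.TMF_final
        assert r1.status == r2.status

    def test_small_recovery(self, refset2, fit_pots, lm_opts):
        p_true = fit_pots.get_vector()
        p0 = perturb_parameters(p_true, 0.15, seed=5)
        res = run_local(p0, refset2, fit_pots, EstimationOptions(lm=lm_opts))
        assert res.status is EstimationStatus.B3_CONVERGED
        assert res.TMF_final < 1e-10
        assert np.abs(res.p_hat - p_true).max() / p_true.min() < 1e-2

    def test_gradient_adds_no_lm_calls(self, refset2, fit_pots, lm_opts):
        """One lattice minimization per structure per TMF evaluation; the
        Jacobian is free."""
        opts = EstimationOptions(lm=lm_opts)
        ev = TMFEvaluator(refset2, fit_pots, opts)
        p = fit_pots.get_vector() * 1.02
        ev(p)  # fun + jac in one pass
        assert ev.lm_calls == len(refset2)
        ev(p)  # cached: no further calls
        assert ev.lm_calls == len(refset2)


class TestParameterCounting:
    @pytest.mark.parametrize(
        "types,expected",
        [
            (("C", "H"), 6),
            (("C", "H", "N"), 12),
            (("C", "H", "N", "O"), 20),
            (("C", "H", "N", "O", "F"), 30),
            (("C", "H", "N", "O", "F", "Cl"), 42),
            (("C", "H", "N", "O", "F", "Cl", "S"), 54),
            (("C", "H", "N", "O", "F", "Cl", "S", "Hp"), 62),
        ],
    )
    def test_training_problem_sizes(self, types, expected):
        """A and C per explicit pair, B fixed, no C for polarized-hydrogen
        pairs, no S-Cl data: reproduces the published problem sizes."""
        assert count_free_parameters(types) == expected
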