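"""Likelihood closed forms, derivative cross-checks, and multi-start fitting.

The slow full-scale convergence behavior lives in the acceptance suite;
here the pinned single-label model keeps every check fast.
"""

import numpy as np
import pytest

from lipidpulse.inference import (
    EstimationProblem,
    FitResult,
    convergence_fraction,
    fit_multistart,
    forward_sensitivities,
    negative_log_likelihood,
    objective_gradient,
)
from lipidpulse.inference import objective_value_and_grad
from lipidpulse.population import MeasurementSet
from lipidpulse.simulate import LabelSchedule


def make_problem(model, ms, **kw):
    return EstimationProblem.from_measurement_set(
        model, LabelSchedule.default(model.n_labels), ms, **kw
    )


class TestNegativeLogLikelihood:
    def test_perfect_fit_closed_form(self, problem_1label, cohort_1label):
        """At ȳ = y the NLL reduces to Σ ½ log(2π σ²)."""
        ms = cohort_1label.measurements[0]
        perfect = EstimationProblem(
            problem_1label.model, problem_1label.schedule,
            ms.truth[[list(ms.observable_ids).index(o)
                      for o in problem_1label.model.observable_ids]],
            problem_1label.sigma,
        )
        theta_log10 = np.log10(cohort_1label.parameters[0])
        J = negative_log_likelihood(theta_log10, perfect)
        assert J == pytest.approx(perfect.constant_term, abs=1e-6)

    def test_single_datum_constant(self):
        # one observable, sigma 0.1: J = 1/2 log(2*pi*0.01) at zero residual
        expected = 0.5 * np.log(2 * np.pi * 0.01)
        assert expected == pytest.approx(-1.38364, abs=1e-5)

    def test_one_sigma_residual_adds_half(self, problem_1label):
        theta_log10 = np.full(40, -1.0)
        J0 = negative_log_likelihood(theta_log10, problem_1label)
        shifted = EstimationProblem(
            problem_1label.model, problem_1label.schedule,
            problem_1label.y_meas.copy(), problem_1label.sigma,
        )
        # shift one measurement by exactly 1 sigma relative to the same fit
        y_model = problem_1label.y_meas - _residuals(problem_1label, theta_log10)
        shifted.y_meas = y_model.copy()
        shifted.y_meas[0] += shifted.sigma[0]
        J_shift = negative_log_likelihood(theta_log10, shifted)
        assert J_shift - shifted.constant_term == pytest.approx(0.5, abs=1e-9)

    def test_objective_additive_over_observables(self, problem_1label):
        theta_log10 = np.full(40, -1.0)
        full = negative_log_likelihood(theta_log10, problem_1label)
        parts = []
        for i in range(problem_1label.y_meas.size):
            sub = EstimationProblem(
                problem_1label.model, problem_1label.schedule,
                problem_1label.y_meas, problem_1label.sigma,
            )
            parts.append(
                0.5 * (np.log(2 * np.pi * sub.sigma[i] ** 2)
                       + (_residuals(sub, theta_log10)[i] / sub.sigma[i]) ** 2)
            )
        assert full == pytest.approx(sum(parts), rel=1e-12)

    def test_failure_returns_finite_penalty(self, problem_1label):
        bad = EstimationProblem(
            problem_1label.model, problem_1label.schedule,
            problem_1label.y_meas, problem_1label.sigma, ss_t_max=1e-6,
        )
        bad.ss_tol = 0.0  # unreachable -> steady-state failure
        J = negative_log_likelihood(np.full(40, -1.0), bad)
        assert np.isfinite(J) and J >= 1e10
        assert bad.n_failures == 1


def _residuals(problem, theta_log10):
    y, _ = forward_sensitivities(problem, theta_log10)
    return problem.y_meas - y


class TestGradients:
    def test_forward_matches_finite_differences(self, problem_1label):
        rng = np.random.default_rng(0)
        theta_log10 = np.log10(
            10 ** rng.uniform(-1.5, -0.5, 40)
        )
        g = objective_gradient(theta_log10, problem_1label)
        h = 1e-5
        g_fd = np.empty(40)
        for j in range(40):
            e = np.zeros(40)
            e[j] = h
            g_fd[j] = (
                negative_log_likelihood(theta_log10 + e, problem_1label)
                - negative_log_likelihood(theta_log10 - e, problem_1label)
            ) / (2 * h)
        scale = np.max(np.abs(g_fd))
        assert np.max(np.abs(g - g_fd)) <= 1e-4 * scale

    def test_adjoint_matches_forward(self, problem_1label):
        """Two independent derivative routes agree."""
        theta_log10 = np.full(40, -1.0)
        g_fwd = objective_gradient(theta_log10, problem_1label)
        J, g_adj = objective_value_and_grad(theta_log10, problem_1label)
        assert J == pytest.approx(
            negative_log_likelihood(theta_log10, problem_1label), rel=1e-9
        )
        scale = np.max(np.abs(g_fwd))
        assert np.max(np.abs(g_adj - g_fwd)) <= 1e-4 * scale

    def test_trapezoid_matches_bdf_reference(self, problem_1label):
        theta_log10 = np.full(40, -1.0)
        y1, S1 = forward_sensitivities(problem_1label, theta_log10, method="bdf")
        y2, S2 = forward_sensitivities(problem_1label, theta_log10, method="trapezoid")
        assert np.allclose(y1, y2)
        assert np.max(np.abs(S1 - S2)) <= 1e-4 * np.max(np.abs(S1))

    def test_gradient_near_zero_at_noise_free_optimum(self, models, cohort_1label):
        ms = cohort_1label.measurements[0]
        model = models[1]
        order = [list(ms.observable_ids).index(o) for o in model.observable_ids]
        problem = EstimationProblem(
            model, LabelSchedule.default(1), ms.truth[order], ms.sigma[order],
        )
        theta_log10 = np.log10(cohort_1label.parameters[0])
        J = negative_log_likelihood(theta_log10, problem)
        g = objective_gradient(theta_log10, problem)
        assert np.linalg.norm(g) <= 1e-4 * (1 + abs(J))

    def test_log10_chain_rule(self, problem_1label):
        """∂J/∂log10 θ = ln(10)·θ·∂J/∂θ, checked via two FD scales."""
        theta_log10 = np.full(40, -1.0)
        theta = 10.0 ** theta_log10
        j = 4
        h = 1e-6
        e = np.zeros(40)
        e[j] = h
        dJ_dlog = (
            negative_log_likelihood(theta_log10 + e, problem_1label)
            - negative_log_likelihood(theta_log10 - e, problem_1label)
        ) / (2 * h)
        # finite difference on the linear scale
        th_hi, th_lo = theta.copy(), theta.copy()
        th_hi[j] += h * theta[j]
        th_lo[j] -= h * theta[j]
        dJ_dlin = (
            negative_log_likelihood(np.log10(th_hi), problem_1label)
            - negative_log_likelihood(np.log10(th_lo), problem_1label)
        ) / (2 * h * theta[j])
        assert dJ_dlog == pytest.approx(np.log(10) * theta[j] * dJ_dlin, rel=1e-3)


class TestMultistart:
    def test_start_points_respect_bounds(self, problem_1label):
        lb, ub = problem_1label.bounds_log10
        rng_starts = fit_multistart(
            problem_1label, n_starts=3, seed=1, gn_max_nfev=1, lbfgs_maxiter=1,
            max_rounds=1,
        ).start_points
        assert np.all(rng_starts >= lb) and np.all(rng_starts <= ub)

    def test_noise_free_start_at_truth_recovers_perfect_fit(
        self, models, cohort_1label
    ):
        ms = cohort_1label.measurements[0]
        model = models[1]
        order = [list(ms.observable_ids).index(o) for o in model.observable_ids]
        problem = EstimationProblem(
            model, LabelSchedule.default(1), ms.truth[order], ms.sigma[order],
        )
        theta_log10 = np.log10(cohort_1label.parameters[0])
        res = fit_multistart(problem, start_points=theta_log10[None, :])
        assert res.best_fval == pytest.approx(problem.constant_term, abs=1e-6)

    def test_deterministic_under_fixed_seed(self, problem_1label):
        a = fit_multistart(problem_1label, n_starts=2, seed=3, gn_max_nfev=30,
                           lbfgs_maxiter=10, max_rounds=1)
        b = fit_multistart(problem_1label, n_starts=2, seed=3, gn_max_nfev=30,
                           lbfgs_maxiter=10, max_rounds=1)
        assert np.array_equal(a.fvals, b.fvals)
        assert np.array_equal(a.thetas, b.thetas)

    def test_best_index_is_minimum(self, problem_1label):
        res = fit_multistart(problem_1label, n_starts=3, seed=2, gn_max_nfev=30,
                             lbfgs_maxiter=10, max_rounds=1)
        assert res.best_fval == res.fvals.min()
        assert np.all(np.diff(res.waterfall()) >= 0)


class TestConvergenceFraction:
    def _result(self, fvals):
        n = len(fvals)
        dummy = np.zeros((n, 2))
        problem = None
        return FitResult(problem, dummy, dummy, np.array(fvals, dtype=float),
                         np.ones(n, bool), np.zeros(n, int))

    def test_single_start(self):
        assert convergence_fraction(self._result([5.0])) == 1.0

    def test_both_within_delta(self):
        assert convergence_fraction(self._result([5.0, 5.05]), 0.1) == 1.0

    def test_half_within_delta(self):
        assert convergence_fraction(self._result([5.0, 7.0]), 0.1) == 0.5

    def test_penalty_starts_excluded(self):
        # the fraction is over successful starts; penalties don't count
        assert convergence_fraction(self._result([5.0, 1e10]), 0.1) == 1.0
        assert convergence_fraction(self._result([5.0, 7.0, 1e10]), 0.1) == 0.5

    def test_all_failed_raises(self):
        with pytest.raises(ValueError):
            convergence_fraction(self._result([1e10]))


class TestProblemValidation:
    def test_bad_bounds_rejected(self, models, cohort_1label):
        with pytest.raises(ValueError, match="bound"):
            make_problem(models[1], cohort_1label.measurements[0],
                         bounds_log10=(2.0, -4.0))

    def test_wrong_observable_count_rejected(self, models):
        ms = MeasurementSet(("FA__u",), np.ones(1), np.ones(1), 10.0)
        with pytest.raises(ValueError, match="lacks observables"):
            make_problem(models[1], ms)
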