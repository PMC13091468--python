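"""Steady state, schedule simulation, observation, and label moments."""

import numpy as np
import pytest

from lipidpulse.expansion import aggregate
from lipidpulse.simulate import (
    LabelSchedule,
    SteadyStateError,
    embed_initial_state,
    find_steady_state,
    label_moment,
    moment_weights,
    observe,
    simulate_schedule,
)


class TestLabelSchedule:
    def test_default_is_equidistant(self):
        s = LabelSchedule.default(3, t_meas=10.0)
        assert s.switch_times == (0.0, 10.0 / 3.0, 20.0 / 3.0)
        assert s.phases() == [
            (0.0, 10.0 / 3.0, 1),
            (10.0 / 3.0, 20.0 / 3.0, 2),
            (20.0 / 3.0, 10.0, 3),
        ]

    def test_zero_labels_single_unlabeled_phase(self):
        s = LabelSchedule.default(0, t_meas=10.0)
        assert s.phases() == [(0.0, 10.0, 0)]

    def test_active_label(self):
        s = LabelSchedule.default(2, t_meas=10.0)
        assert s.active_label(0.0) == 1
        assert s.active_label(5.0) == 2
        assert s.active_label(9.999) == 2

    @pytest.mark.parametrize(
        "times,t_meas", [((1.0, 0.5), 10.0), ((0.0, 5.0), 5.0), ((0.0,), 0.0)]
    )
    def test_non_increasing_times_rejected(self, times, t_meas):
        with pytest.raises(ValueError):
            LabelSchedule(len(times), times, t_meas)


class TestSteadyState:
    def test_linear_birth_death_closed_form(self, base):
        """With Cho phosphorylation switched off, Cho settles at k6/k7."""
        theta = np.full(40, 0.1)
        theta[7] = 1e-12  # R8: Cho -> ChoP effectively off
        x0 = find_steady_state(base, theta)
        names = [s.name for s in base.species]
        cho = x0[names.index("Cho")]
        assert np.isclose(cho, theta[5] / theta[6], rtol=1e-6)

    def test_residual_postcondition(self, base, theta_typical):
        from lipidpulse.simulate import kinetics_for
        from lipidpulse.expansion import expand_network

        x0 = find_steady_state(base, theta_typical, tol=1e-10)
        model = expand_network(base, 0)
        kin = kinetics_for(model)
        f = kin.rhs(x0, kin.rate_coeff(theta_typical, 0))
        assert np.max(np.abs(f)) <= 1e-10 * (1 + np.max(np.abs(x0)))

    def test_all_aggregates_positive(self, base, theta_typical):
        x0 = find_steady_state(base, theta_typical)
        assert np.all(x0 > 0)

    def test_nonpositive_theta_rejected(self, base):
        with pytest.raises(ValueError):
            find_steady_state(base, np.zeros(40))

    def test_failure_names_worst_species(self, base, theta_typical):
        with pytest.raises(SteadyStateError, match="species"):
            find_steady_state(base, theta_typical, tol=0.0, t_init=1e-3, t_max=2e-3)


class TestScheduleSimulation:
    def test_zero_label_trajectory_constant(self, models, theta_typical):
        traj = simulate_schedule(models[0], theta_typical, LabelSchedule.default(0))
        assert np.allclose(traj.states, traj.states[0], rtol=1e-7, atol=1e-12)

    def test_state_continuous_across_switches(self, models, theta_typical):
        sched = LabelSchedule.default(2)
        traj = simulate_schedule(models[2], theta_typical, sched)
        t_switch = sched.switch_times[1]
        end_phase1 = traj.phase_solutions[0](t_switch)
        start_phase2 = traj.phase_solutions[1](t_switch)
        assert np.allclose(end_phase1, start_phase2, rtol=1e-12, atol=1e-15)

    def test_aggregates_stay_at_steady_state(self, base, models, theta_typical):
        x0 = find_steady_state(base, theta_typical)
        traj = simulate_schedule(
            models[3], theta_typical, LabelSchedule.default(3), x0_base=x0
        )
        agg = traj.aggregates()
        rel = np.abs(agg - x0[None, :]) / x0[None, :]
        assert rel.max() < 1e-6

    def test_label_mismatch_rejected(self, models, theta_typical):
        with pytest.raises(ValueError, match="labels"):
            simulate_schedule(models[2], theta_typical, LabelSchedule.default(3))

    def test_initial_mass_all_unlabeled(self, models, base, theta_typical):
        x0b = find_steady_state(base, theta_typical)
        x0 = embed_initial_state(models[3], x0b)
        model = models[3]
        labeled = [
            i for i, s in enumerate(model.species) if any(v > 0 for v in s.state)
        ]
        assert np.all(x0[labeled] == 0)
        assert np.allclose(aggregate(model, x0), x0b)

    def test_solver_tolerance_convergence(self, models, theta_typical):
        """Halving tolerances moves the measurement by far less than 1e-6."""
        sched = LabelSchedule.default(1)
        y1 = observe(simulate_schedule(models[1], theta_typical, sched,
                                       rtol=1e-8, atol=1e-12))
        y2 = observe(simulate_schedule(models[1], theta_typical, sched,
                                       rtol=5e-9, atol=5e-13))
        assert np.max(np.abs(y1 - y2)) <= 1e-6 * np.max(np.abs(y1))


class TestObservation:
    def test_observable_count_by_label(self, models, theta_typical):
        traj = simulate_schedule(models[0], theta_typical, LabelSchedule.default(0))
        assert observe(traj).size == 11
        traj3 = simulate_schedule(models[3], theta_typical, LabelSchedule.default(3))
        assert observe(traj3).size == 90

    def test_all_zero_state_measures_zero(self, models):
        x = np.zeros(models[3].n_x)
        assert np.all(x[models[3].observable_indices] == 0)


class TestLabelMoments:
    @pytest.fixture(scope="class")
    def traj3(self, models, theta_typical):
        return simulate_schedule(
            models[3], theta_typical, LabelSchedule.default(3),
            t_eval=np.linspace(0, 10, 121),
        )

    def test_zero_before_label_applied(self, traj3):
        sched = traj3.schedule
        for label in (2, 3):
            t_on = sched.switch_times[label - 1]
            ts = np.linspace(0, t_on - 1e-6, 20)
            for sp in ("FA", "DAG", "TAG"):
                _, m = label_moment(traj3, sp, label, ts)
                assert np.max(np.abs(m)) < 1e-9

    def test_chain_bookkeeping_identity(self, traj3):
        """Unlabeled + labeled chain moments equal chains-weighted totals."""
        model = traj3.model
        for sp in ("FA", "PA", "TAG"):
            c = model.base.species_by_name(sp).n_chains
            block = model.variant_indices(sp)
            total = traj3.states[:, block].sum(axis=1) * c
            labeled = sum(
                label_moment(traj3, sp, l)[1] for l in (1, 2, 3)
            )
            w_unlab = np.zeros(model.n_x)
            for i in block:
                w_unlab[i] = model.species[i].state.count(0)
            unlabeled = traj3.states @ w_unlab
            assert np.allclose(labeled + unlabeled, total, rtol=1e-9, atol=1e-12)

    def test_time_shift_between_labels(self, traj3):
        """Equidistant phases: label-2 moments are label-1 moments shifted."""
        sched = traj3.schedule
        dt = sched.switch_times[1] - sched.switch_times[0]
        ts = np.linspace(sched.switch_times[1], sched.t_meas, 60)
        for sp in ("FA", "LPA", "DAG", "PC", "TAG"):
            _, m2 = label_moment(traj3, sp, 2, ts)
            _, m1s = label_moment(traj3, sp, 1, ts - dt)
            _, m1 = label_moment(traj3, sp, 1)
            scale = max(m1.max(), 1e-300)
            assert np.max(np.abs(m2 - m1s)) <= 1e-5 * scale

    def test_unknown_species_or_label_rejected(self, traj3):
        with pytest.raises(ValueError):
            moment_weights(traj3.model, "NOPE", 1)
        with pytest.raises(ValueError):
            moment_weights(traj3.model, "FA", 4)


class TestLabelPermutationDynamics:
    def test_swapping_labels_and_times_permutes_states(self, base, models, theta_typical):
        """Applying media in order (2, 1) instead of (1, 2) swaps variants."""
        from lipidpulse.simulate import kinetics_for
        from lipidpulse.expansion import permute_labels
        from scipy.integrate import solve_ivp

        model = models[2]
        kin = kinetics_for(model)
        x0b = find_steady_state(base, theta_typical)
        x0 = embed_initial_state(model, x0b)

        def run(label_order):
            x = x0.copy()
            bounds = [(0.0, 5.0), (5.0, 10.0)]
            for (lo, hi), lbl in zip(bounds, label_order):
                coeff = kin.rate_coeff(theta_typical, lbl)
                sol = solve_ivp(
                    lambda t, y: kin.rhs(y, coeff), (lo, hi), x,
                    method="LSODA", jac=lambda t, y: kin.jac(y, coeff),
                    rtol=1e-10, atol=1e-13,
                )
                x = sol.y[:, -1]
            return x

        forward = run((1, 2))
        swapped_media = run((2, 1))
        perm = {1: 2, 2: 1}
        for i, s in enumerate(model.species):
            j = model.index_of(s.base_name, permute_labels(s.state, perm))
            assert np.isclose(
                forward[i], swapped_media[j], rtol=1e-7, atol=1e-12
            ), s.id
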