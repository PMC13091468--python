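"""Simulation of the sequential-labeling protocol.

The protocol starts from the label-free metabolic steady state (all mass in
all-unlabeled variants), then switches the fatty-acid influx through a
sequence of label phases: during phase ``l`` only label-``l`` FA enters the
medium.  Washing changes only the influx label, so the state is continuous
across switches and the label-blind aggregates stay at the steady state for
the whole experiment.  A single terminal measurement at ``t_meas`` reads out
every chain-carrying variant.

Numerics: the stiff LSODA integrator with an analytic Jacobian, restarted at
every switch time so the discontinuous input is handled exactly; the steady
state is found by damped Newton iteration on the 22-state label-free system
with a long-time-integration fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .expansion import ExpandedModel, aggregate, expand_network
from .network import BaseNetwork

__all__ = [
    "LabelSchedule",
    "Trajectory",
    "SteadyStateError",
    "IntegrationError",
    "Kinetics",
    "find_steady_state",
    "simulate_schedule",
    "observe",
    "label_moment",
]

LN10 = np.log(10.0)


class SteadyStateError(RuntimeError):
    """Pre-equilibration did not reach the requested residual tolerance."""


class IntegrationError(RuntimeError):
    """ODE integration failed inside a labeling phase."""


#: Default cap on right-hand-side evaluations per ODE solve.  Healthy solves
#: use a few thousand; the cap aborts pathological parameter regions (e.g.
#: near-zero effluxes with huge pools) deterministically, so multi-start
#: optimization stays both alive and reproducible.
MAX_RHS_EVALS = 30_000


class _EvalBudgetExceeded(Exception):
    pass


def _budgeted(fun, budget: int):
    """Wrap an ODE right-hand side with a deterministic evaluation budget."""
    count = 0

    def wrapped(t, y):
        nonlocal count
        count += 1
        if count > budget:
            raise _EvalBudgetExceeded(f"RHS evaluation budget {budget} exhausted")
        return fun(t, y)

    return wrapped


# ---------------------------------------------------------------------------
# Label schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelSchedule:
    """Switch times of the sequential-labeling protocol.

    ``switch_times[l-1]`` is the time at which label ``l``'s medium is
    applied; phase ``l`` spans ``[T_l, T_{l+1})`` and the last phase ends at
    the measurement time ``t_meas``.  Before ``T_1`` the medium is unlabeled
    (label symbol 0); the default schedule starts at ``T_1 = 0`` with phases
    of equal length.
    """

    n_labels: int
    switch_times: tuple[float, ...]
    t_meas: float

    def __post_init__(self) -> None:
        if len(self.switch_times) != self.n_labels:
            raise ValueError(
                f"need {self.n_labels} switch times, got {len(self.switch_times)}"
            )
        times = (*self.switch_times, self.t_meas)
        if any(a >= b for a, b in zip(times, times[1:])):
            raise ValueError(f"times must be strictly increasing and end at t_meas: {times}")

    @classmethod
    def default(cls, n_labels: int, t_meas: float = 10.0, t_start: float = 0.0) -> "LabelSchedule":
        """Uniformly spaced labels: ``T_l = t_start + (l-1)·(t_meas-t_start)/N_L``."""
        if n_labels == 0:
            return cls(0, (), t_meas)
        dt = (t_meas - t_start) / n_labels
        return cls(n_labels, tuple(t_start + i * dt for i in range(n_labels)), t_meas)

    @property
    def t_start(self) -> float:
        return self.switch_times[0] if self.n_labels else 0.0

    def phases(self) -> list[tuple[float, float, int]]:
        """``(t_lo, t_hi, active_label)`` per phase; label 0 for no labels."""
        if self.n_labels == 0:
            return [(0.0, self.t_meas, 0)]
        times = (*self.switch_times, self.t_meas)
        return [(times[i], times[i + 1], i + 1) for i in range(self.n_labels)]

    def active_label(self, t: float) -> int:
        for lo, hi, lbl in self.phases():
            if lo <= t < hi:
                return lbl
        return self.phases()[-1][2] if t >= self.t_meas else 0


# ---------------------------------------------------------------------------
# Vectorized kinetics
# ---------------------------------------------------------------------------


class Kinetics:
    """Vectorized mass-action right-hand side and Jacobians for a model.

    Reaction rates are ``v_j = k[rule_j] · m_j · x[r1_j] · x[r2_j] · g_j``
    with multiplicity ``m_j`` and influx gate ``g_j`` (1 iff the instance is
    ungated or its influx label is the active one).  The state derivative is
    ``N v`` with stoichiometric matrix ``N``.
    """

    def __init__(self, model: ExpandedModel):
        self.model = model
        n_x, n_r = model.n_x, model.n_instances
        self.n_x, self.n_r = n_x, n_r
        self.n_params = model.n_parameters
        self.ridx = np.array([inst.param_index for inst in model.instances], dtype=np.intp)
        self.mult = np.array([float(inst.multiplicity) for inst in model.instances])
        self.influx_label = np.array(
            [-1 if inst.influx_label is None else inst.influx_label
             for inst in model.instances],
            dtype=np.intp,
        )
        pad = n_x  # index of the virtual constant-1 state
        r1 = np.full(n_r, pad, dtype=np.intp)
        r2 = np.full(n_r, pad, dtype=np.intp)
        s_row, s_col, s_val = [], [], []
        for j, inst in enumerate(model.instances):
            if len(inst.reactants) > 0:
                r1[j] = inst.reactants[0]
            if len(inst.reactants) > 1:
                r2[j] = inst.reactants[1]
            for i in inst.reactants:
                s_row.append(i); s_col.append(j); s_val.append(-1.0)
            for i in inst.products:
                s_row.append(i); s_col.append(j); s_val.append(1.0)
        self.r1, self.r2 = r1, r2
        # stoichiometry triplets: state index, instance index, +/-1
        self._s_row = np.array(s_row, dtype=np.intp)
        self._s_col = np.array(s_col, dtype=np.intp)
        self._s_val = np.array(s_val)
        self.stoich = sp.csr_matrix(
            (self._s_val, (self._s_row, self._s_col)), shape=(n_x, n_r)
        )

        # Jacobian triplets: one per (stoichiometry entry, reactant of that
        # instance) pair; dv_j/dx[c] = coeff_j · x[other partner of c].
        t_row, t_col, t_other, t_inst, t_val = [], [], [], [], []
        for i, j, val in zip(self._s_row, self._s_col, self._s_val):
            for c, other in ((r1[j], r2[j]), (r2[j], r1[j])):
                if c < n_x:
                    t_row.append(i); t_col.append(c); t_other.append(other)
                    t_inst.append(j); t_val.append(val)
        self._t_row = np.array(t_row, dtype=np.intp)
        self._t_col = np.array(t_col, dtype=np.intp)
        self._t_other = np.array(t_other, dtype=np.intp)
        self._t_inst = np.array(t_inst, dtype=np.intp)
        self._t_val = np.array(t_val)
        self._t_flat = self._t_row * n_x + self._t_col

    def gate(self, active_label: int) -> np.ndarray:
        return (self.influx_label < 0) | (self.influx_label == active_label)

    def rate_coeff(self, theta: np.ndarray, active_label: int) -> np.ndarray:
        """Per-instance coefficient ``k·m·g`` for one phase."""
        return theta[self.ridx] * self.mult * self.gate(active_label)

    def _xe(self, x: np.ndarray) -> np.ndarray:
        return np.append(x, 1.0)

    def rates(self, x: np.ndarray, coeff: np.ndarray) -> np.ndarray:
        xe = self._xe(x)
        return coeff * xe[self.r1] * xe[self.r2]

    def rhs(self, x: np.ndarray, coeff: np.ndarray) -> np.ndarray:
        v = self.rates(x, coeff)
        return np.bincount(self._s_row, weights=self._s_val * v[self._s_col],
                           minlength=self.n_x)

    def _jac_entries(self, x: np.ndarray, coeff: np.ndarray) -> np.ndarray:
        xe = self._xe(x)
        return self._t_val * coeff[self._t_inst] * xe[self._t_other]

    def jac(self, x: np.ndarray, coeff: np.ndarray) -> np.ndarray:
        """Dense state Jacobian ``d(rhs)/dx``."""
        flat = np.bincount(self._t_flat, weights=self._jac_entries(x, coeff),
                           minlength=self.n_x * self.n_x)
        return flat.reshape(self.n_x, self.n_x)

    def jac_transpose_vec(self, x: np.ndarray, coeff: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """``Jᵀ λ`` without forming the Jacobian (adjoint right-hand side)."""
        w = self._jac_entries(x, coeff) * lam[self._t_row]
        return np.bincount(self._t_col, weights=w, minlength=self.n_x)

    def param_jac(self, x: np.ndarray, theta: np.ndarray, active_label: int) -> np.ndarray:
        """Dense ``d(rhs)/dθ`` (linear-scale parameters), shape (n_x, n_θ)."""
        xe = self._xe(x)
        v_per_k = self.mult * self.gate(active_label) * xe[self.r1] * xe[self.r2]
        flat = np.bincount(
            self._s_row * self.n_params + self.ridx[self._s_col],
            weights=self._s_val * v_per_k[self._s_col],
            minlength=self.n_x * self.n_params,
        )
        return flat.reshape(self.n_x, self.n_params)

    def param_quadrature(
        self, x: np.ndarray, lam: np.ndarray, theta: np.ndarray, active_label: int
    ) -> np.ndarray:
        """``λᵀ · d(rhs)/dθ`` without forming the dense matrix."""
        xe = self._xe(x)
        w = np.bincount(self._s_col, weights=self._s_val * lam[self._s_row],
                        minlength=self.n_r)
        contrib = w * self.mult * self.gate(active_label) * xe[self.r1] * xe[self.r2]
        return np.bincount(self.ridx, weights=contrib, minlength=self.n_params)


def kinetics_for(model: ExpandedModel) -> Kinetics:
    """Per-model cached :class:`Kinetics` (arrays are built once)."""
    kin = getattr(model, "_kinetics", None)
    if kin is None:
        kin = Kinetics(model)
        object.__setattr__(model, "_kinetics", kin)
    return kin


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------


def _residual_ok(f: np.ndarray, x: np.ndarray, tol: float) -> bool:
    return np.max(np.abs(f)) <= tol * (1.0 + np.max(np.abs(x)))


def find_steady_state(
    system: BaseNetwork | ExpandedModel,
    theta: np.ndarray,
    tol: float = 1e-10,
    t_init: float = 2e2,
    t_max: float = 1e7,
    newton_maxiter: int = 50,
    max_rhs_evals: int = MAX_RHS_EVALS,
    x_init: np.ndarray | None = None,
) -> np.ndarray:
    """Label-free steady state ``x0`` with ``‖f(x0)‖_∞ ≤ tol·(1+‖x0‖_∞)``.

    Works on the zero-label system with the unlabeled FA influx active.
    Strategy: damped Newton directly from ``x_init`` when a warm start is
    available (step halving enforces a residual decrease and
    non-negativity); otherwise, or on Newton failure, integrate towards
    equilibrium and polish, extending the horizon geometrically up to
    ``t_max``.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        raise ValueError("theta must be strictly positive and finite")
    if isinstance(system, ExpandedModel):
        model = system if system.n_labels == 0 else expand_network(system.base, 0)
    else:
        model = expand_network(system, 0)
    kin = kinetics_for(model)
    coeff = kin.rate_coeff(theta, active_label=0)

    if x_init is not None and x_init.shape == (kin.n_x,) and np.all(x_init >= 0):
        xn = _newton_polish(kin, coeff, np.asarray(x_init, dtype=float), tol, newton_maxiter)
        if xn is not None:
            return xn

    x = np.full(kin.n_x, 0.1) if x_init is None else np.maximum(x_init, 1e-6)
    horizon = t_init
    t_done = 0.0
    while True:
        try:
            sol = solve_ivp(
                _budgeted(lambda t, y: kin.rhs(y, coeff), max_rhs_evals),
                (0.0, horizon),
                x,
                method="LSODA",
                jac=lambda t, y: kin.jac(y, coeff),
                rtol=1e-8,
                atol=1e-12,
            )
        except _EvalBudgetExceeded as exc:
            raise SteadyStateError(f"pre-equilibration stalled: {exc}") from None
        if not sol.success:
            raise SteadyStateError(f"pre-equilibration integration failed: {sol.message}")
        x = np.maximum(sol.y[:, -1], 0.0)
        t_done += horizon

        xn = _newton_polish(kin, coeff, x, tol, newton_maxiter)
        if xn is not None:
            return xn
        if t_done >= t_max:
            f = kin.rhs(x, coeff)
            worst = int(np.argmax(np.abs(f)))
            raise SteadyStateError(
                f"no steady state within horizon {t_max:g}; worst residual "
                f"{f[worst]:.3e} on species {model.species[worst].id!r}"
            )
        horizon *= 10.0


def _newton_polish(kin, coeff, x0, tol, maxiter):
    x = x0.copy()
    f = kin.rhs(x, coeff)
    for _ in range(maxiter):
        if _residual_ok(f, x, tol):
            return x
        J = kin.jac(x, coeff)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        norm0 = np.max(np.abs(f))
        lam = 1.0
        while lam > 1e-6:
            xn = x + lam * step
            if np.min(xn) >= -1e-12:
                fn = kin.rhs(np.maximum(xn, 0.0), coeff)
                if np.max(np.abs(fn)) < norm0:
                    x = np.maximum(xn, 0.0)
                    f = fn
                    break
            lam *= 0.5
        else:
            return None
    return x if _residual_ok(f, x, tol) else None


def embed_initial_state(model: ExpandedModel, x0_base: np.ndarray) -> np.ndarray:
    """Place the base steady state on the all-unlabeled variants."""
    x0 = np.zeros(model.n_x)
    for i, s in enumerate(model.base.species):
        x0[model.unlabeled_index(s.name)] = x0_base[i]
    return x0


# ---------------------------------------------------------------------------
# Trajectory & schedule simulation
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Piecewise solution of one labeling experiment."""

    model: ExpandedModel
    schedule: LabelSchedule
    theta: np.ndarray
    t: np.ndarray
    states: np.ndarray  # (len(t), n_x)
    phase_solutions: list = field(repr=False, default_factory=list)

    def states_at(self, times) -> np.ndarray:
        """Evaluate the dense solution at arbitrary times in the experiment."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty((times.size, self.model.n_x))
        phases = self.schedule.phases()
        for k, tv in enumerate(times):
            if not phases[0][0] - 1e-12 <= tv <= phases[-1][1] + 1e-12:
                raise ValueError(f"time {tv} outside simulated range")
            for (lo, hi, _), sol in zip(phases, self.phase_solutions):
                if tv <= hi or sol is self.phase_solutions[-1]:
                    out[k] = sol(min(max(tv, lo), hi))
                    break
        return out

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def aggregates(self) -> np.ndarray:
        return aggregate(self.model, self.states)


def simulate_schedule(
    model: ExpandedModel,
    theta: np.ndarray,
    schedule: LabelSchedule,
    t_eval: np.ndarray | None = None,
    x0_base: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    ss_tol: float = 1e-10,
    max_rhs_evals: int = MAX_RHS_EVALS,
) -> Trajectory:
    """Integrate through the label phases from the pre-equilibrated state.

    The solver restarts at every switch time, so the discontinuous influx is
    exact; only the influx label changes across a switch (the state is
    continuous).  ``t_eval`` defaults to 201 uniform points over the
    experiment and always includes the measurement time.
    """
    if model.n_labels != schedule.n_labels:
        raise ValueError(
            f"model has {model.n_labels} labels but schedule has {schedule.n_labels}"
        )
    theta = np.asarray(theta, dtype=float)
    if x0_base is None:
        x0_base = find_steady_state(model.base, theta, tol=ss_tol)
    x0 = embed_initial_state(model, x0_base)
    kin = kinetics_for(model)

    phases = schedule.phases()
    t0 = phases[0][0]
    if t_eval is None:
        t_eval = np.linspace(t0, schedule.t_meas, 201)
    t_eval = np.asarray(t_eval, dtype=float)

    sols = []
    x = x0
    for pidx, (lo, hi, lbl) in enumerate(phases):
        coeff = kin.rate_coeff(theta, active_label=lbl)
        try:
            sol = solve_ivp(
                _budgeted(lambda t, y: kin.rhs(y, coeff), max_rhs_evals),
                (lo, hi),
                x,
                method="LSODA",
                jac=lambda t, y: kin.jac(y, coeff),
                dense_output=True,
                rtol=rtol,
                atol=atol,
            )
        except _EvalBudgetExceeded as exc:
            raise IntegrationError(f"phase {pidx + 1} stalled: {exc}") from None
        if not sol.success:
            raise IntegrationError(f"integration failed in phase {pidx + 1}: {sol.message}")
        sols.append(sol.sol)
        x = sol.y[:, -1]

    traj = Trajectory(model, schedule, theta, t_eval, np.empty((t_eval.size, model.n_x)), sols)
    traj.states = traj.states_at(t_eval)
    return traj


# ---------------------------------------------------------------------------
# Observation & label moments
# ---------------------------------------------------------------------------


def observe(trajectory: Trajectory, t: float | None = None) -> np.ndarray:
    """Noise-free measurement: every chain-carrying variant at time ``t``.

    ``t`` defaults to the measurement time of the schedule.
    """
    if t is None:
        t = trajectory.schedule.t_meas
    x = trajectory.states_at([t])[0]
    return x[trajectory.model.observable_indices]


def moment_weights(model: ExpandedModel, base_species: str, label: int) -> np.ndarray:
    """Weight vector whose dot with the state gives the label-count moment."""
    if label < 1 or label > model.n_labels:
        raise ValueError(f"label must be in 1..{model.n_labels}, got {label}")
    names = {s.name for s in model.base.species}
    if base_species not in names:
        raise ValueError(f"unknown species {base_species!r}")
    w = np.zeros(model.n_x)
    for i in model.variant_indices(base_species):
        w[i] = model.species[i].label_count(label)
    return w


def label_moment(
    trajectory: Trajectory, base_species: str, label: int, times=None
) -> tuple[np.ndarray, np.ndarray]:
    """Expected number of label-``label`` chains in a species pool over time.

    ``m_l^s(t) = Σ_M (#l in M) · [s_M](t)``.  With equal-length phases these
    curves are time-shifted copies of each other across labels (the tracer
    dynamics are linear and time-invariant at metabolic steady state).
    Returns ``(times, values)``.
    """
    w = moment_weights(trajectory.model, base_species, label)
    if times is None:
        times = trajectory.t
        states = trajectory.states
    else:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        states = trajectory.states_at(times)
    return times, states @ w
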