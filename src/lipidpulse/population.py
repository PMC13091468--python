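"""Synthetic heterogeneous single-cell cohorts.

Cell-to-cell variability is modeled by sampling each cell's rate-parameter
vector from a multivariate log-normal population distribution: parameter j
has median ``b_j`` (the pinned defaults lie between 0.01 and 0.5) and a
log10-scale standard deviation ``s`` (default 0.1, i.e. samples of one
parameter span roughly half to one order of magnitude).  Each cell is then
pre-equilibrated, run through the sequential-labeling schedule, and measured
once: every chain-carrying variant at the measurement time, corrupted with
additive Gaussian noise whose standard deviation is 10% of the noise-free
value (``cv = 0.1``), with a small floor for near-zero observables.

The generative noise scale is stored with each measurement and reused as the
known noise model during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expansion import ExpandedModel, expand_network
from .network import BaseNetwork, build_base_network
from .simulate import LabelSchedule, SteadyStateError, observe, simulate_schedule

__all__ = [
    "PopulationDistribution",
    "MeasurementSet",
    "CellCohort",
    "default_base_values",
    "sample_parameters",
    "add_noise",
    "generate_cohort",
]

#: Documented seed pinning the default per-parameter medians (log-uniform in
#: [0.01, 0.5]); regenerating with this constant reproduces the table.
BASE_VALUE_SEED = 94781

#: Noise floor as a fraction of the largest noise-free observable.
SIGMA_FLOOR_FRACTION = 1e-8


def default_base_values(n_parameters: int = 40) -> np.ndarray:
    """Pinned per-parameter medians ``b_j``, log-uniform in [0.01, 0.5]."""
    rng = np.random.default_rng(BASE_VALUE_SEED)
    return 10.0 ** rng.uniform(np.log10(0.01), np.log10(0.5), n_parameters)


@dataclass(frozen=True)
class PopulationDistribution:
    """Independent log-normal population distribution of rate parameters.

    ``log10 θ_j ~ Normal(log10 b_j, s²)``; a full covariance on the log10
    scale may be supplied via ``covariance`` (default: diagonal ``s²·I``).
    """

    base_values: np.ndarray
    log10_sd: float = 0.1
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.base_values, dtype=float)
        object.__setattr__(self, "base_values", b)
        if np.any(b <= 0):
            raise ValueError("base values must be strictly positive")
        if self.log10_sd < 0:
            raise ValueError("log10 standard deviation must be >= 0")
        if np.any(b < 0.01 - 1e-12) or np.any(b > 0.5 + 1e-12):
            import warnings

            warnings.warn(
                "base values outside the standard range [0.01, 0.5]",
                stacklevel=2,
            )

    @classmethod
    def default(cls, n_parameters: int = 40, log10_sd: float = 0.1) -> "PopulationDistribution":
        return cls(default_base_values(n_parameters), log10_sd)

    @property
    def n_parameters(self) -> int:
        return self.base_values.size


def sample_parameters(
    dist: PopulationDistribution, n_cells: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Draw per-cell parameter vectors, shape ``(n_cells, n_θ)``.

    ``θ_j = b_j · 10^z`` with ``z ~ Normal(0, s²)`` independently per
    parameter and cell (or correlated via the optional covariance).
    Deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n_p = dist.n_parameters
    if dist.covariance is not None:
        z = rng.multivariate_normal(np.zeros(n_p), dist.covariance, size=n_cells)
    else:
        z = rng.normal(0.0, dist.log10_sd, size=(n_cells, n_p))
    return dist.base_values[None, :] * 10.0 ** z


@dataclass
class MeasurementSet:
    """One cell's single-time-point noisy measurement of all observables."""

    observable_ids: tuple[str, ...]
    values: np.ndarray           # noisy measurements ȳ
    sigma: np.ndarray            # per-observable noise SD used to generate
    t_meas: float
    truth: np.ndarray | None = None  # noise-free y, if known

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("all noise standard deviations must be > 0")

    @property
    def n_observables(self) -> int:
        return len(self.observable_ids)


def add_noise(
    y: np.ndarray,
    cv: float,
    seed: int | np.random.SeedSequence,
    observable_ids: tuple[str, ...] | None = None,
    t_meas: float = 10.0,
) -> MeasurementSet:
    """Corrupt a noise-free measurement vector with additive Gaussian noise.

    ``σ_i = max(cv·y_i, σ_floor)`` with ``σ_floor`` a small fraction of the
    largest observable, so zero-valued observables still get a proper noise
    scale.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    floor = SIGMA_FLOOR_FRACTION * max(float(np.max(y)), 1.0e-300)
    sigma = np.maximum(cv * y, floor)
    noisy = y + rng.normal(0.0, sigma)
    if observable_ids is None:
        observable_ids = tuple(f"obs_{i}" for i in range(y.size))
    return MeasurementSet(tuple(observable_ids), noisy, sigma, t_meas, truth=y.copy())


@dataclass
class CellCohort:
    """Sampled ground-truth parameters plus per-cell measurement sets."""

    model: ExpandedModel
    schedule: LabelSchedule
    cell_ids: list[str]
    parameters: np.ndarray           # (n_cells, n_θ) ground truth
    measurements: list[MeasurementSet]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def ground_truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.parameters, columns=self.model.parameter_names)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def measurement_frame(self) -> pd.DataFrame:
        rows = []
        for cid, ms in zip(self.cell_ids, self.measurements):
            for oid, val, sd in zip(ms.observable_ids, ms.values, ms.sigma):
                rows.append((cid, oid, ms.t_meas, val, sd))
        return pd.DataFrame(
            rows, columns=["cell_id", "observable_id", "time", "measurement", "noise_sd"]
        )


def generate_cohort(
    base: BaseNetwork | None = None,
    n_labels: int = 3,
    schedule: LabelSchedule | None = None,
    dist: PopulationDistribution | None = None,
    n_cells: int = 10,
    seed: int = 0,
    cv: float = 0.1,
    parameters: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> CellCohort:
    """Sample a cohort, simulate every cell, and emit noisy measurements.

    Each cell is an independent single-cell problem (parameters and data
    belong to one cell, never pooled).  The parameter sample depends only on
    ``(dist, n_cells, seed)`` — not on the label count — so studies across
    label numbers reuse the identical ground truth by passing the same seed
    (or the same ``parameters`` array).  Noise uses per-cell spawned
    sub-seeds and is reproducible.  Cells whose pre-equilibration fails are
    excluded and recorded in ``cohort.excluded``.
    """
    if base is None:
        base = build_base_network()
    model = expand_network(base, n_labels)
    if schedule is None:
        schedule = LabelSchedule.default(n_labels)
    if dist is None:
        dist = PopulationDistribution.default(base.n_rules)

    root = np.random.SeedSequence(seed)
    param_seed, noise_root = root.spawn(2)
    if parameters is None:
        parameters = sample_parameters(dist, n_cells, param_seed)
    else:
        parameters = np.asarray(parameters, dtype=float)
        if parameters.shape[0] != n_cells:
            raise ValueError("parameters row count must equal n_cells")
    noise_seeds = noise_root.spawn(n_cells)

    cell_ids, thetas, sets, excluded = [], [], [], []
    for j in range(n_cells):
        cid = f"cell_{j:04d}"
        theta = parameters[j]
        try:
            traj = simulate_schedule(model, theta, schedule, t_eval=np.array([schedule.t_meas]),
                                     rtol=rtol, atol=atol)
        except SteadyStateError as exc:
            excluded.append((cid, str(exc)))
            continue
        y = observe(traj)
        ms = add_noise(y, cv, noise_seeds[j], model.observable_ids, schedule.t_meas)
        cell_ids.append(cid)
        thetas.append(theta)
        sets.append(ms)

    return CellCohort(model, schedule, cell_ids, np.array(thetas), sets, excluded)
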