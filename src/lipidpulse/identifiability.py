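"""Practical identifiability via the Fisher information matrix, and the
label-number design study.

At the maximum-likelihood estimate the observed information is approximated
by the Gauss–Newton Fisher information matrix

    FIM = Σ_i (1/σ_i²) · s_i s_iᵀ,     s_i = ∂y_i(T_M) / ∂ log10 θ,

a sum of positive-semidefinite rank-one terms, one per observable.  Large
eigenvalues mark well-determined directions in (log) parameter space; tiny
ones mark practically non-identifiable (sloppy) directions.  Because each
observable adds a PSD term, enlarging the observable set — e.g. by using
more labels — can only grow the information matrix in the Loewner order.

Population-level recovery is quantified per parameter by the Pearson
correlation between estimated and true log10 values across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    EstimationProblem,
    convergence_fraction,
    fit_multistart,
    forward_sensitivities,
)
from .network import BaseNetwork, build_base_network
from .population import PopulationDistribution, generate_cohort
from .simulate import LabelSchedule

__all__ = [
    "FIMSpectrum",
    "RecoverySummary",
    "fisher_information",
    "eigenspectrum",
    "parameter_recovery",
    "label_study",
]

#: Eigenvalues below this floor are reported at the floor (spectra span many
#: orders of magnitude; numerically-zero values are clipped for comparison).
EIGENVALUE_CLIP = 1e-20


@dataclass
class FIMSpectrum:
    """Fisher information matrix with its clipped eigenspectrum."""

    matrix: np.ndarray
    eigenvalues: np.ndarray  # descending, clipped
    clip: float = EIGENVALUE_CLIP

    @property
    def n_parameters(self) -> int:
        return self.matrix.shape[0]

    @property
    def median_eigenvalue(self) -> float:
        return float(np.median(self.eigenvalues))


def fisher_information(
    problem: EstimationProblem,
    theta_log10: np.ndarray,
    observable_subset: np.ndarray | None = None,
    clip: float = EIGENVALUE_CLIP,
) -> FIMSpectrum:
    """Gauss–Newton FIM at ``theta_log10`` in log10-parameter space.

    ``observable_subset`` (indices into the model's observable list)
    restricts the sum to those observables; the full-set FIM minus any
    subset FIM is positive semidefinite by construction.
    """
    _, S = forward_sensitivities(problem, theta_log10)
    W = S / problem.sigma[:, None]
    if observable_subset is not None:
        W = W[np.asarray(observable_subset, dtype=np.intp)]
    fim = W.T @ W
    fim = 0.5 * (fim + fim.T)
    return FIMSpectrum(fim, eigenspectrum(fim, clip), clip)


def eigenspectrum(fim: np.ndarray, clip: float = EIGENVALUE_CLIP) -> np.ndarray:
    """Descending eigenvalues of a symmetric matrix, floored at ``clip``."""
    fim = np.asarray(fim, dtype=float)
    scale = np.max(np.abs(fim)) if fim.size else 0.0
    if scale > 0 and np.max(np.abs(fim - fim.T)) > 1e-12 * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    vals = np.linalg.eigvalsh(0.5 * (fim + fim.T))[::-1]
    return np.maximum(vals, clip)


@dataclass
class RecoverySummary:
    """Per-parameter estimate-vs-truth correlations across a cohort."""

    parameter_names: tuple[str, ...]
    pearson_r: np.ndarray  # NaN where undefined (zero variance)

    @property
    def n_high(self) -> int:
        """Parameters recovered well (r > 0.8)."""
        return int(np.sum(self.pearson_r[np.isfinite(self.pearson_r)] > 0.8))

    @property
    def n_low(self) -> int:
        """Practically non-identifiable parameters (r < 0.2)."""
        return int(np.sum(self.pearson_r[np.isfinite(self.pearson_r)] < 0.2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.parameter_names, "pearson_r": self.pearson_r}
        )


def parameter_recovery(
    estimates: np.ndarray,
    truths: np.ndarray,
    parameter_names: tuple[str, ...] | None = None,
) -> RecoverySummary:
    """Pearson correlation of estimated vs true parameters, per parameter.

    Inputs are linear-scale parameter matrices of shape (n_cells, n_θ);
    correlations are computed on log10 values.  Parameters whose estimates
    have zero variance across cells get ``NaN`` (excluded from the counts).
    """
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must have the same shape")
    if estimates.shape[0] < 3:
        raise ValueError("need at least 3 cells for correlations")
    le, lt = np.log10(estimates), np.log10(truths)
    n_p = le.shape[1]
    r = np.full(n_p, np.nan)
    for j in range(n_p):
        se, st = np.std(le[:, j]), np.std(lt[:, j])
        if se > 0 and st > 0:
            r[j] = float(np.corrcoef(le[:, j], lt[:, j])[0, 1])
    if parameter_names is None:
        parameter_names = tuple(f"k{j + 1}" for j in range(n_p))
    return RecoverySummary(tuple(parameter_names), r)


# ---------------------------------------------------------------------------
# Label-number design study
# ---------------------------------------------------------------------------


def label_study(
    base: BaseNetwork | None = None,
    n_labels_set: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_cells: int = 10,
    seed: int = 0,
    t_meas: float = 10.0,
    dist: PopulationDistribution | None = None,
    n_starts: int = 20,
    fit: bool = True,
    fit_kwargs: dict | None = None,
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-10,
) -> dict[str, pd.DataFrame]:
    """Compare model size, information content, and recovery across label counts.

    The same per-cell parameter sample (fixed by ``seed``) is reused for
    every label count; only the schedule, the expanded model, and the noise
    realizations differ.  For each label count the study reports model
    dimensions, per-cell FIM eigenspectra (at the best fit when ``fit`` is
    on, else at the ground truth), and — when fitting — per-parameter
    recovery correlations and convergence fractions.

    Returns a dict of tidy tables: ``sizes``, ``eigenvalues``, ``recovery``
    (empty when not fitting), ``fits`` (per cell and label: best objective,
    convergence fraction).
    """
    if base is None:
        base = build_base_network()
    if dist is None:
        dist = PopulationDistribution.default(base.n_rules)
    fit_kwargs = dict(fit_kwargs or {})

    size_rows, eig_rows, rec_rows, fit_rows = [], [], [], []
    failed_cells: set[str] = set()
    per_label: dict[int, dict] = {}

    for nl in sorted(n_labels_set):
        schedule = LabelSchedule.default(nl, t_meas=t_meas)
        cohort = generate_cohort(
            base, nl, schedule, dist, n_cells, seed, rtol=sim_rtol, atol=sim_atol
        )
        model = cohort.model
        size_rows.append(
            {
                "n_labels": nl,
                "n_species": model.n_x,
                "n_reactions": model.n_instances,
                "n_observables": model.n_observables,
            }
        )
        failed_cells.update(cid for cid, _ in cohort.excluded)
        per_label[nl] = {"cohort": cohort, "schedule": schedule}

    for nl in sorted(n_labels_set):
        cohort = per_label[nl]["cohort"]
        schedule = per_label[nl]["schedule"]
        model = cohort.model
        estimates, truths = [], []
        for cid, theta, ms in zip(cohort.cell_ids, cohort.parameters, cohort.measurements):
            if cid in failed_cells:
                continue
            problem = EstimationProblem.from_measurement_set(
                model, schedule, ms, sim_rtol=sim_rtol, sim_atol=sim_atol
            )
            if fit:
                cell_seed = np.random.SeedSequence([seed, nl, int(cid.split("_")[1])])
                result = fit_multistart(problem, n_starts=n_starts, seed=cell_seed, **fit_kwargs)
                theta_hat = result.best_theta_log10
                fit_rows.append(
                    {
                        "n_labels": nl,
                        "cell_id": cid,
                        "best_J": result.best_fval,
                        "convergence_fraction": convergence_fraction(result),
                    }
                )
                estimates.append(10.0 ** theta_hat)
                truths.append(theta)
            else:
                theta_hat = np.log10(theta)
            try:
                spectrum = fisher_information(problem, theta_hat)
            except Exception as exc:  # noqa: BLE001 - recorded, cell skipped
                fit_rows.append(
                    {"n_labels": nl, "cell_id": cid, "best_J": np.nan,
                     "convergence_fraction": np.nan, "error": str(exc)}
                )
                continue
            for rank, val in enumerate(spectrum.eigenvalues):
                eig_rows.append(
                    {"n_labels": nl, "cell_id": cid, "eigenvalue_rank": rank,
                     "eigenvalue": val}
                )
        if fit and len(estimates) >= 3:
            summary = parameter_recovery(
                np.array(estimates), np.array(truths), model.parameter_names
            )
            for name, r in zip(summary.parameter_names, summary.pearson_r):
                rec_rows.append({"n_labels": nl, "parameter": name, "pearson_r": r})

    return {
        "sizes": pd.DataFrame(size_rows),
        "eigenvalues": pd.DataFrame(eig_rows),
        "recovery": pd.DataFrame(rec_rows),
        "fits": pd.DataFrame(fit_rows),
    }
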