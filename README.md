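# lipidpulse

Single-cell lipid metabolism kinetics from one destructive measurement.

Lipidomics readouts destroy the cell, so each cell yields exactly one time
point. `lipidpulse` implements a sequential multi-label pulse strategy that
encodes a time course into that single snapshot: a cell equilibrates in
label-free medium, then fatty-acid labels 1, 2, …, N_L — biochemically
identical, analytically distinguishable — are applied one after another at
times T₁ < T₂ < … < T_{N_L}, and the cell is measured once at T_M. Because
each label's influx window is a shifted copy of the others, the labeled
sub-populations trace the same kinetics started at different times; a
label-aware kinetic model decodes the snapshot into per-cell reaction
rates. The package is aimed at modelers designing such labeling
experiments and benchmarking estimators on them.

## What it contains

* **Rule-based model expansion** — a pinned network of 22 metabolite pools
  and 40 mass-action reactions (triacylglycerol synthesis/lipolysis plus
  PC/PE/PS metabolism) expanded over label *multisets*: a species with `c`
  acyl chains becomes `C(N_L + c, c)` variants, every reaction instance
  keeps its rule's single rate constant, and deacylations carry
  multiplicity weights so the label-blind aggregate dynamics are exactly
  the base dynamics. Three labels give 101 species and 263 reactions with
  still only 40 parameters.
* **Protocol simulator** — damped-Newton pre-equilibration
  (x₀ = lim_{t→∞} x(t)), stiff phase-wise integration of the label switch
  schedule, terminal observation of all chain-carrying variants, and
  label-moment curves exhibiting the time-shift property.
* **Synthetic cohorts** — per-cell rates from a log-normal population
  (`log10 θ_j ~ N(log10 b_j, 0.1²)`, medians in [0.01, 0.5]), additive
  Gaussian noise with σ = 10% of the signal, reproducible seeds, TSV/PEtab
  style tables.
* **Per-cell maximum likelihood** — the Gaussian NLL
  `J(θ) = ½ Σ_i [log(2πσ_i²) + ((ȳ_i − y_i(T_M,θ))/σ_i)²]` minimized in
  log10-parameter space over [10⁻⁴, 10²] by multi-start local
  optimization (Gauss–Newton trust region on the residuals with forward
  sensitivities, chained with adjoint-gradient L-BFGS-B), waterfall
  convergence diagnostics.
* **Identifiability** — Gauss–Newton Fisher information
  `FIM = Σ_i σ_i⁻² s_i s_iᵀ` in log10 space, clipped eigenspectra,
  estimate-vs-truth Pearson correlations across cells, and the 0–4-label
  design study on a shared parameter sample.
* **I/O and CLI** — SBML L3 export/import, measurement and ground-truth
  TSVs, YAML run configs, and a `lipidpulse` command with `expand`,
  `simulate`, `cohort`, `fit`, `fim`, `labelstudy`, `report` subcommands.

See `docs/methods.md` for the model, the numerics, and the design
decisions.

## Worked example

```python
import numpy as np
from lipidpulse import (
    build_base_network, expand_network, LabelSchedule,
    PopulationDistribution, sample_parameters,
    find_steady_state, simulate_schedule, observe, label_moment,
)

base = build_base_network()
model = expand_network(base, n_labels=3)
print(f"expanded model: {model.n_x} species, {model.n_instances} reactions, "
      f"{model.n_observables} observables")

dist = PopulationDistribution.default(base.n_rules)   # log-normal, s = 0.1
theta = sample_parameters(dist, n_cells=1, seed=0)[0]

schedule = LabelSchedule.default(3, t_meas=10.0)      # labels at t = 0, 10/3, 20/3
x0 = find_steady_state(base, theta)
traj = simulate_schedule(model, theta, schedule, x0_base=x0)

y = observe(traj)                   # all chain-carrying variants at t = 10
print(f"measurement at t = {schedule.t_meas}: {y.size} values, "
      f"total TAG = {y[[i.startswith('TAG') for i in model.observable_ids]].sum():.4f}")

for label in (1, 2, 3):
    _, m = label_moment(traj, "TAG", label)
    print(f"label-{label} chains in TAG at t = 10: {m[-1]:.5f}")
```

prints

```
expanded model: 101 species, 263 reactions, 90 observables
measurement at t = 10.0: 90 values, total TAG = 0.0037
label-1 chains in TAG at t = 10: 0.00017
label-2 chains in TAG at t = 10: 0.00012
label-3 chains in TAG at t = 10: 0.00005
```

The three label moments are snapshots of one incorporation curve taken at
three effective ages (10, 6.7, and 3.3 time units of exposure): label 1
has been in the system longest and has accumulated the most TAG chains.
That monotone ladder — read from a single terminal measurement — is the
longitudinal information the protocol recovers. Fitting this cell's 90
noisy values with `fit_multistart` returns per-cell estimates of all 40
rate constants, with the Fisher-information eigenspectrum flagging which
directions the data actually constrain.

To generate and fit a small cohort from the shell:

```sh
lipidpulse cohort --labels 3 --cells 10 --seed 1 --out-dir data/
lipidpulse fit --labels 3 --measurements data/measurements.tsv \
    --starts 50 --seed 1 --out-dir fits/
lipidpulse labelstudy --labels 0,1,2,3,4 --cells 10 --no-fit --out-dir study/
```

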