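# Methods

## The measurement problem

Lipidomics measurements are destructive: a cell is lysed once, so a single
cell yields a single time point. The sequential-labeling protocol recovers
kinetic information from that one snapshot by exchanging the growth medium
through a series of fatty-acid labels that are biochemically identical but
analytically distinguishable (e.g. alkyne or isotope tags resolved by mass
spectrometry). Cells equilibrate in label-free medium, then at times
`T_1 < T_2 < … < T_{N_L}` the medium switches to FA carrying label 1, 2, …;
at `T_M` the cell is measured. Because each label's influx window is a
shifted copy of the others, each labeled sub-population traces out the same
kinetics started at a different time — a time course encoded in one
measurement. Decoding it requires a label-aware dynamic model, which this
package builds, simulates, and fits.

## Base network

The label-free model is a pinned network of 22 metabolite pools and 40
irreversible mass-action reactions covering triacylglycerol synthesis and
lipolysis (GLY, G3P, FA, LPA, PA, MAG, DAG, TAG) and glycerophospholipid
metabolism (PC, PE, PS with their lyso- and head-group intermediates:
Cho, ChoP, CDPCho, Etn, EtnP, CDPEtn, Ser, GPC, GPE). Modeling
simplifications:

* ATP and acyl-CoA are assumed constant and folded into rate constants, so
  FA participates directly in acyl-transfer reactions.
* Beta-oxidation and all other FA consumption are lumped into one efflux
  (`R23`); TAG efflux (`R38`) closes the chain balance.
* One rate constant per reaction (`k1..k40`); no reversible or saturable
  kinetics.
* Chain length and unsaturation diversity within a lipid class are not
  resolved; each pool is one species with a fixed number of esterifiable
  acyl positions (0 for head groups, 1 for FA/lyso-species/MAG, 2 for
  diacyl species, 3 for TAG).

Construction audits every rule for acyl-chain conservation (chains enter
only via FA influx and leave only via the efflux rules).

## Label-resolved expansion

A species with `c` chains carrying labels from `{u, 1..N_L}` (u =
unlabeled) is expanded into one state variable per label *multiset* —
positions on the glycerol backbone are treated as equivalent — giving
`C(N_L + c, c)` variants per species and, for the pinned network, 22, 40,
66, 101, 146 states at 0–4 labels. Reaction rules expand by their class:

* acylation merges the acceptor's multiset with the incoming FA label
  (one instance per variant pair);
* deacylation releases each distinct chain label of the parent as FA, with
  multiplicity weight `count(label)/c` so every physical chain is equally
  likely to be released;
* transfers and head-group reactions carry multisets through unchanged;
* the FA influx expands into one gated instance per label symbol, active
  only during that label's medium phase.

All instances of a rule share its single rate constant (40 parameters at
any label count); the pinned network yields 82, 154, 263, 416 reaction
instances at 1–4 labels. Under the multiplicity convention the label-blind
aggregate of the expanded vector field equals the base vector field at the
aggregated state — exactly, at any state, for any parameters. This is the
formal content of "reactions are agnostic to labels", and it is tested both
algebraically at random states and as mass invariance along trajectories.
A corollary tested as the time-shift property: at metabolic steady state
the label-moment curves `m_l(t) = Σ_M count(l in M)·[x_M](t)` obey linear
time-invariant dynamics, so with equal phase lengths the label-l curve is
the label-l′ curve shifted by `T_l − T_l′`.

## Protocol simulation

Pre-equilibration solves the label-free steady state `f(x0, θ) = 0` by
damped Newton iteration (step halving enforcing residual decrease and
non-negativity) seeded by integrating from a uniform positive state for 200
time units, with the horizon escalated tenfold on failure up to `1e7`;
tolerance `‖f‖∞ ≤ 1e-10·(1+‖x0‖∞)`. The expanded experiment starts with all
mass on the all-unlabeled variants and integrates phase by phase with LSODA
(analytic Jacobian, `rtol 1e-8`, `atol 1e-12` for data generation), the
solver restarted at each switch time so the discontinuous influx is exact.
Time units are arbitrary; the default schedule uses `T_1 = 0`, uniform
phases, and `T_M = 10` for every label count. Every ODE solve carries a
deterministic cap of 30 000 right-hand-side evaluations: parameter
combinations that drive the integrator into a grind (near-zero effluxes
with enormous pools) abort reproducibly instead of hanging, and the
estimator treats them as failures.

Observables are all chain-carrying variants at `T_M` — 11, 29, 55, 90, 135
for 0–4 labels with the pinned network.

## Synthetic cohorts

Cell-to-cell variability follows an independent log-normal population law:
`log10 θ_j ~ Normal(log10 b_j, s²)` with `s = 0.1` (samples of one
parameter span roughly half to one order of magnitude) and pinned medians
`b_j` drawn once, log-uniformly from `[0.01, 0.5]`, from a fixed seed
recorded in the source; a covariance hook exists but defaults to diagonal.
Measurements add Gaussian noise with `σ_i = max(0.1·y_i, σ_floor)`,
`σ_floor = 1e-8·max(y)` — the noise scale comes from the noise-free value
and is stored with the data, and fitting reuses it (known-noise
assumption). Parameter sampling depends only on the distribution, cell
count, and seed, never on the label count, so design studies reuse one
ground-truth sample across 0–4 labels; per-cell noise sub-seeds keep every
realization reproducible.

What the generator does *not* emulate: pooled measurements, missing or
censored observables, correlated parameters, extrinsic/intrinsic noise
decomposition, chain-length diversity, and medium depletion. Passing tests
therefore demonstrate internal consistency of estimator and design
analysis under the stated generative assumptions, not performance on real
spectra.

## Maximum-likelihood estimation

With known Gaussian noise the negative log-likelihood is
`J(θ) = ½ Σ_i [log(2π σ_i²) + ((ȳ_i − y_i(T_M, θ))/σ_i)²]`. Estimation is
in `log10 θ` inside the box `[−4, 2]` (log-uniform multi-start, 1000 start
points by default). Each start runs a cascade:

1. a trust-region-reflective Gauss–Newton pass (`scipy.optimize.least_squares`,
   `trf`) on the weighted residuals, with the residual Jacobian from forward
   sensitivities — this exploits the least-squares structure and does most
   of the work;
2. a short bounded L-BFGS-B pass with the adjoint gradient, which either
   confirms the stationary point at negligible cost or pulls the iterate
   out of regions where Gauss–Newton stalled (including simulation-failure
   plateaus, where the objective falls back on a large finite penalty,
   `1e10` plus a distance-to-center term, rather than raising);
3. repeat, up to three rounds, until the objective stops improving by
   more than `1e-3`.

Fitting uses `rtol 1e-6` simulations; gradient noise at looser tolerances
destabilizes line searches. The steady-state solve is a pure function of θ
(no warm starting across iterates) — a memoized cache keyed on θ lets
value, gradient, and Jacobian evaluations at one iterate share the forward
solve without introducing history dependence, which would corrupt line
searches. Convergence is summarized by the waterfall plot and the fraction
of starts within `Δ = 0.1` of the best objective (the plateau height).

## Derivatives

Three routes, used for different jobs and cross-checked against each other
and against finite differences:

* **Forward sensitivities** solve the variational ODE
  `S' = J_x(x(t)) S + J_θ(x(t))` for all 40 directions above the dense
  forward solution, starting from the pre-equilibration sensitivity
  obtained by implicit differentiation of the fixed point
  (`dx0/dθ = −J_x⁻¹ J_θ`). Default propagation is the A-stable implicit
  trapezoidal rule on the forward solver's own accepted-step grid (split
  in two), which inherits the step-size control of the nonlinear solve;
  an adaptive BDF solve of the same linear ODE with its exact Jacobian is
  available as the high-accuracy reference (`method="bdf"`). Used for the
  residual Jacobian in Gauss–Newton and for the Fisher information.
* **Adjoint (costate)** integration backward from `λ(T_M) = ∂J/∂x` with a
  40-dimensional quadrature for `∫ λᵀ f_θ dt` plus the initial-condition
  term `λ(0)ᵀ dx0/dθ`; costs about two simulations independent of the
  parameter count and supplies the optimizer gradient.
* **Finite differences**, test-only.

All derivatives are reported with respect to `log10 θ` (chain rule
`ln 10 · θ_j` applied at the end).

## Identifiability

The Fisher information matrix is the Gauss–Newton form
`FIM = Σ_i σ_i⁻² s_i s_iᵀ` with `s_i = ∂y_i(T_M)/∂log10 θ` at the estimate
— a sum of PSD rank-one terms, one per observable, so enlarging the
observable set can only grow the matrix in the Loewner order (the exact
statement behind "more labels add information"). Eigenvalues below `1e-20`
are clipped for reporting. Population-level recovery is the per-parameter
Pearson correlation between estimated and true `log10` values across
cells, summarized by the counts of parameters above 0.8 and below 0.2.
The label study runs the whole loop for 0–4 labels on a shared parameter
sample and emits tidy tables of model sizes, per-cell eigenspectra, and
recovery correlations.

On synthetic cohorts the recovery pattern is strongly heterogeneous: FA
uptake and turnover (`k22`, `k23`) and the acyl-transfer backbone recover
with r near 1, while parameters touching the observables only through
unobserved head-group pools (e.g. the Cho↔ChoP↔CDPCho cycle `k8`–`k11`,
or the PS branch `k32`) stay uncorrelated — practical non-identifiability
attributable to unobserved states.

## Problem sizes used in the test suite

The automated suite keeps every check desk-scale as a package design
choice: the convergence-plateau check uses 3 three-label cells with 8
starts each (median plateau fraction observed 0.88–1.0); the recovery
check uses 12 cells with 3 starts each (observed: 12 parameters above 0.8
including `k22`/`k23`; 16 below 0.2 including `k8`–`k11` and `k32`);
aggregate invariance uses 20 sampled parameter vectors at 1–3 labels. The
library itself runs arbitrary cohort sizes (the defaults reproduce the
full protocol with 1000-start multi-starts).

## Numerical choices and edge cases

* Multiset states are canonical sorted tuples; species and instances are
  emitted in deterministic lexicographic order, so all serializations are
  byte-stable.
* Deacylation weights are exact `fractions.Fraction`s in the model object
  and only become floats in the kinetics arrays.
* `σ_floor` keeps zero-valued observables from producing infinite weights.
* Failed cells in cohort generation are excluded and recorded, and the
  label study excludes a failed cell consistently across label counts.
* The steady state is assumed unique on the positive orthant for the
  pinned network; the Newton polish always follows an equilibration
  integration, so a pathological second root would have to be reachable
  from the long-time state.
* SBML export writes Level 3 Version 2 core with mass-action kinetic laws
  and a small annotation carrying each influx instance's label (phase
  gating is protocol information outside SBML core); the importer reads
  back exactly that subset and is validated by structural and simulation
  round trips.

## Known limitations

* The expanded model at three labels has 90 chain-carrying observables;
  grouped or derived observables beyond the per-variant readout are not
  modeled.
* No profile likelihoods, Bayesian posteriors, or structural
  identifiability analysis; the FIM is a local, Gauss–Newton quantity.
* No stochastic (master-equation) simulation, cell growth, or medium
  depletion.
* Non-equidistant label timing is supported by the simulator but the
  time-shift property, and hence the pseudo-time reading of the data,
  holds only for equal phase lengths.
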