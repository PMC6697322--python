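# Methods

This note documents the model-selection procedure implemented by
`famos`, the two bundled benchmark systems, the synthetic-data
generators, and the numerical choices behind them.

## The selection procedure

### Model space

A *global model* lists every candidate parameter
θ = (θ₁, …, θₙ); a sub-model is a binary inclusion vector
α ∈ {0,1}ⁿ — αᵢ = 1 means θᵢ is estimated from data, αᵢ = 0 means the
corresponding process is off or pinned to a default.  The space of
non-empty sub-models has 2ⁿ − 1 members, which rules out exhaustive
evaluation beyond small n (n = 25 already gives > 3 × 10⁷ models).

Two kinds of structural pre-knowledge restrict and guide the search:

* **Critical sets** — a model is admissible only if it includes at
  least one member of each critical set (e.g. a compartment that must
  be reachable somehow).  The empty model is never admissible.
* **Swap sets** — groups of structurally similar parameters that can
  compensate each other (e.g. all processes that increase the same
  compartment).  Every critical set is automatically also a swap set.

Excluded parameters resolve through ordered per-parameter fallback
rules: a literal value, a reference to another parameter's resolved
value, or a *guarded* reference that applies only when some member of
a guard set is included.  Guards express conditional inheritance such
as "a suspension rate tracks its collagen counterpart until the model
selects an environment difference at or before this generation".
Reference chains are checked acyclic at load; with no applicable rule
a parameter resolves to 0 (process off).

### Search moves and method switching

From the current best model the engine proposes its full neighbourhood
under one method: **forward** (add one parameter), **backward**
(remove one), or **swap** (exchange an included for an excluded member
of a shared swap set).  All candidates are fitted and the best one is
accepted only on a *strict* criterion improvement; ties (first by
criterion, then by parameter count, then by the canonical 0/1 string)
can never cycle.  Method switching is a fixed automaton: keep the
method after success (swap success switches to forward); after failure
alternate forward/backward; once both directions have failed
consecutively, escalate to swap if any swap set exists, otherwise
stop; a failed swap stops.  Strict improvement on a finite space
guarantees termination.

Every fitted model is memoised; re-proposed models are not refitted
but their stored scores still compete.  Model comparison uses AIC,
AICc, or BIC computed from the cost function's −2 log L with k = |S₁|
fitted parameters and a user-declared number of data points n.  (A
cost function may instead return the criterion directly; then the
engine only compares.)  After a run, per-parameter Akaike support
Σ_{m ∋ θⱼ} w_m with w_m ∝ exp(−Δ_m/2) summarises how much of the
evidence mass includes each parameter.

### Fitting

Each sub-model is fitted by bounded Nelder–Mead run as *restart legs*:
the optimiser is interrupted after `iteration_cap` (default 1000)
simplex iterations and restarted from its endpoint, which re-inflates
the simplex; legs stop when the between-leg decrease of −2 log L falls
below `convergence_tol` (default 10⁻³ — a value the procedure needs
but that is otherwise unconstrained; 10⁻³ is well below any criterion
difference that could change a model comparison).  The whole chain is
repeated `optim_runs` times from uniform random starts inside the
bounds; the first chain instead inherits the current best model's
estimates for shared parameters.  Per-model RNG streams are derived
from (master seed, model identifier), making results independent of
candidate evaluation order and of process-level parallelism.
`optim_runs` defaults to 2; the bundled dye-dilution configuration
uses 5 independent starting conditions per model, matching the
experimental analysis it reproduces.

### Profile-likelihood identifiability

For each fitted parameter the profile walks away from the estimate
with adaptive steps (growing ~1.8× while the profile is flat, halving
on violent overshoot or failed re-optimisation), re-optimising all
other included parameters at each point, until the profiled −2 log L
rises by χ²₁(0.95) = 3.841.  The crossing is bracketed and refined by
bisection.  A profile still below threshold at the box bound flags
that side non-identifiable and reports the bound — the convention used
for rates whose data carry no constraint in one direction.

### Multi-run campaigns

Because single runs are local, a campaign repeats the search, starting
each new run at the admissible model maximising the minimal Hamming
distance to everything previously tested (exhaustive for ≤ 20 free
parameters, else a seeded multi-restart bit-flip hill climb with
plateau walks), then merges histories (best fit per model) and pools
Akaike support.

## Benchmark 1: four-compartment population model

Compartments A–D with multiplication rates ρ_X and transition rates
μ_XY (per unit time, arbitrary units) form a 16-parameter global model
(65 535 sub-models).  The generating truth is the chain
μ_AB = 0.1, ρ_B = 0.1, μ_BC = 0.05, μ_BD = 0.2, ρ_C = 0.1 started from
A₀ = 100.  The system is linear, so deterministic trajectories are
advanced with matrix exponentials (a fixed-series scaling-and-squaring
`expm` agreeing with SciPy's to machine precision); on the equidistant
grid a single propagator is reused, which is what makes ~10⁵ cost
evaluations per model search affordable.

Synthetic data: each of 30 equidistant time points on a horizon of 10
time units receives 10 *fresh, independent* stochastic trajectories
(Gillespie with adaptive tau-leaping; leaps bounded to ~3% expected
relative change per species, exact-SSA fallback when leaps shrink,
negative-count leaps halved and redrawn), and the per-time-point mean
and SD over the 10 replicates form the dataset.  The horizon is a
package choice (the reference experiment's time axis is not
recoverable); 10 units spans B/C growth and near-depletion of A at the
true rates.

Cost: Gaussian −2 log L of the means with empirical SDs floored by a
scale parameter σ̃, Σ((ȳ−m)/(s+σ̃))² + Σ log((s+σ̃)²).  σ̃ is profiled
out exactly at every evaluation (bounded 1-D minimisation over a
precomputed log grid, parabolically refined).  Being common to all
models it cancels from comparisons and is not counted in k.  Its lower
bound is one count — the resolution of integer count data — which also
keeps the likelihood proper on noiseless data (zero SDs with zero
residuals would otherwise diverge) and gives the noiseless landscape
its finite steepness, so structurally compensating sub-models (the
local optima the swap move exists to escape) remain local optima
rather than being annihilated by an effectively infinite precision.
n = 120 mean cells (30 time points × 4 compartments).  The bundled
selection experiments on this benchmark use single-chain fits seeded
by parameter inheritance (optim_runs = 1; the swap-rescue runs, whose
starting model is fitted cold, use 3 chains).

Swap sets: *influx* mode groups, per compartment X, {ρ_X} ∪ {μ_YX} —
everything that increases X; *efflux* mode (the deliberately
mis-specified grouping) uses outflows instead; *all* puts all 16
parameters in one set.

## Benchmark 2: dye-dilution proliferation model

Cells carrying a division-halved membrane dye are binned by flow
cytometry into generations i = 0…9.  Counts follow the linear cascade

    dT₀/dt = −(ρ₀ + δ₀) T₀
    dTᵢ/dt = 2 ρᵢ₋₁ Tᵢ₋₁ − (ρᵢ + δᵢ) Tᵢ,   i = 1…9,

with generation-dependent proliferation (ρᵢ) and death (δᵢ) rates in
h⁻¹, and no proliferation during an environment-specific adaptation
time τ_E after transfer (integration split exactly at τ_E, where the
dynamics reduce to diagonal exponential death).  By default dividing
T₉ cells leave the tracked system, exactly as the cascade above is
written; a flag switches to the variant where both daughters stay in
T₉ (the two readings of "all cells beyond 8 divisions are captured in
T₉" conflict, and the printed equations win by default).  The
observable is the frequency mᵢ = Tᵢ/ΣTⱼ over living modelled cells.

The global space has 43 parameters: {ρᵢ, δᵢ} for both environments
(collagen C, suspension S), τ_C, τ_S, and the SD floor σ̃ of the cost
— 42 selectable (> 10¹² models) plus σ̃, which sits in a singleton
critical set so every model carries it.  Critical set {ρ₀^C, δ₀^C}
anchors generation 0; one swap set contains all 42 rate/time
parameters.  Inheritance rules: ρᵢ^C ← ρᵢ₋₁^C; ρᵢ^S ← ρᵢ₋₁^S *if* some
ρⱼ^S (j ≤ i) is selected, else ρᵢ^S ← ρᵢ^C (and likewise for δ);
τ_S ← τ_C; an unselected τ_C is 0.  Bounds: rates [0, 1] h⁻¹ (the
tabulated cap of 100 × 10⁻² h⁻¹), τ ∈ [0, 48] h, σ̃ ∈ (10⁻⁶, 1].

Cost: the weighted least-squares form above, summed over environments,
with means and SDs over replicates and σ̃ read from the parameter
vector; n = time points × generations × environments = 80 mean cells
(a count the reference analysis never states; day-0 cells are
included, with all mass in generation 0 at transfer).

### Synthetic dye-dilution data

The generator emulates the shape of the real experiment: frequencies
for generations 0–9 at 0/48/96/168 h (days 0–7), three replicates,
two environments.  Model frequencies receive truncated Gaussian noise
(sd 0.005 by default, clipped at 0) and are renormalised per replicate
to sum to 1.  The generating structure (selected parameters:
ρ₀^C = 0.06, ρ₁^C = 0.01, ρ₄^C = 0.10, δ₀^C = 0.005, δ₅^C = 0.05,
ρ₄^S = 0.06, τ_C = 46 h, τ_S = 40 h, σ̃ = 0.008) mirrors the pattern
of activated-T-cell estimates: a fast first division, a slow phase, a
mid-generation peak reduced in suspension after generation 4, death
concentrated late, and a ~40–46 h adaptation.

What the generator does *not* emulate: cytometry gating error and
generation mis-assignment (noise is i.i.d. Gaussian per cell of the
frequency table, not dye-overlap structured), absolute cell counts
(frequencies only — so a uniform shift of all death rates, which
rescales every Tᵢ by e^(−ct), is structurally non-identifiable and is
expected to show up as flat death-rate profiles hitting both bounds;
the real analysis pinned this direction with separate counting-bead
experiments), donor-to-donor variability, and replicate correlation.
Passing recovery tests therefore demonstrates correctness of the
machinery on well-specified data, not robustness to those artefacts.

Two further caveats matter when comparing maximum-likelihood estimates
against the generating values at high precision.  First, truncation
plus renormalisation makes the replicate mean a slightly biased
estimate of the model frequency (a 200-replicate fit shows the
pseudo-truth shifted by ~1–2% on the most affected rates).  Second,
the weighted cost is a pseudo-likelihood: its denominators are sample
SDs from three replicates (heavy-tailed when squared and inverted)
applied to residuals of the mean, so profile intervals are not exactly
χ²-calibrated — empirically the estimator's seed-to-seed spread can
exceed the interval half-widths by ~1.6×.  Both effects are properties
of the cost as defined, not of the optimiser; on occasional data
seeds a sharply identified rate's generating value falls just outside
its 95% profile interval.  The adaptation times are nevertheless
recovered within a few tenths of an hour on every seed examined.

## Numerical choices

* Linear-ODE propagation by matrix exponential with per-gap caching;
  a fixed-length Taylor scaling-and-squaring `expm` for the small
  generators (truncation error ~7 × 10⁻¹⁶ at scaled norm ≤ 0.5).
* Nelder–Mead bounds via SciPy's clipping; default simplex tolerances
  xatol 10⁻⁶ / fatol 10⁻⁸, relaxed to 10⁻⁴/10⁻⁶ in the large benchmark
  searches where criterion gaps are O(1).
* Non-finite cost values are replaced by a large penalty inside the
  simplex; a model whose cost is non-finite at every start yields a
  flagged failed record (criterion +∞) that is logged but can never
  win.
* Degenerate inputs: the empty model is invalid; a dye-dilution state
  whose total population underflows to zero yields NaN frequencies and
  an infinite cost; AICc with n ≤ k + 1 raises instead of silently
  returning infinity.
* Tie-breaks everywhere use the canonical 0/1-string order.

## Problem sizes used in the bundled experiments

The shipped experiments are scaled-down reproductions chosen as desk-
scale study conditions: the stochastic-data selection experiment uses
20 (tests: 12) uniformly sampled admissible starting models on one
simulated dataset rather than all 65 535 starts; swap-rescue runs
start from one identified forward/backward local optimum; parameter
recovery uses 3 data seeds with profile intervals on every included
parameter.  The real-data analysis protocol (5 sequential most-distant
runs per cell type) is implemented in the campaign driver and
exercised at small scale in the test suite.

## Known limitations

* Nelder–Mead multistart gives no global-optimality guarantee per
  model; sloppy fits can re-rank close models (mitigated by
  inheritance and restart legs, and diagnosable via Akaike support).
* The swap move only helps where swap sets encode genuine structural
  similarity; the efflux grouping in benchmark 1 shows how a wrong
  grouping fails to rescue local minima.
* The most-distant heuristic above 20 free parameters is a hill climb;
  it attains the exhaustive optimum on all tested 12-parameter
  instances but carries no guarantee at 42.
* Profile intervals assume the χ²₁ threshold (asymptotic likelihood
  theory); no finite-sample correction is applied.
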