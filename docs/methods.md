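# Methods

## Model

A compound-connection is a birth-death Markov chain on the synapse count
`S ∈ {0..N}`: per discrete time step each vacant site forms a synapse with
probability `b` and each realized synapse is deleted with probability
`d[S]`, where `d` depends on the current count and on the stimulation
condition. Restricting to one change per step (the first-step
approximation) gives a tridiagonal row-stochastic matrix with up-probability
`(N−S)·b`, down-probability `S·d[S]`. The model's central inversion runs
backwards from biology to rates: a target stationary distribution is
prescribed and detailed balance

    p[S] · S·d[S] = p[S−1] · (N−S+1)·b

is solved for `d[S]`. Because the chain is a reversible birth-death chain,
the inversion is exact — the target is the stationary law, not an
approximation to it. Strict positivity of the target is required (the
inversion divides by `p[S]`) and deliberately not patched by
epsilon-flooring: a zero would disconnect the chain.

Assumptions inherited from this construction: sites are homogeneous and
exchangeable (no dendritic geometry, no per-site rates), the formation rate
`b` is activity-independent, and neural activity itself is abstracted into
three conditions (low / working point / high) via their stationary targets.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `N`  | potential synaptic sites | 7 (decay/learning), 5 (calibration, spine protocol) | the experiments' `N` is not uniquely determined by the published initial condition `S=7`; 7 is the smallest consistent choice and reproduces the 10⁹–10¹⁰-step plateau scale. Exposed everywhere. |
| `b`  | formation probability per vacant site per step | 1e−8 | sets the absolute time scale; all reported times scale as `1/b`. |
| `μ, σ` | center/width of the Gaussian upper peak (synapse counts) | 5.0, 1.2 | the exponent is `−(S−μ)²/σ²` (no factor 2); σ = 1.0 in the spine-experiment protocol. |
| `λ` | Poisson parameter of the lower peak | 0.05 | steepness of decay at 0. |
| `C` | upper-peak weight of the wp mixture | 0.1 | ~10% of connections connected at rest. |

These defaults are the study conditions; the sweep module varies the peak
shape one factor at a time.

## Exact propagation

`propagate` evaluates `p₀·Mᵗ` spectrally, so `t = 10¹⁰` costs the same as
`t = 1`. Numerics matter here: the eigenvalues of `M` cluster within ~1e−8
of 1, so the decomposition is performed on the *generator* `Q = M − I`
with its diagonal rebuilt from the exactly-stored off-diagonal rates
(storing `1 − rates` and subtracting 1 back costs eight digits), and `Q` is
symmetrized by the chain's detailed-balance measure before `eigh`.
Eigenvalue powers use `exp(t·log1p(q))`. The same generator feeds the
stationary-distribution solver (`stationary_of`), a bordered linear solve
with one redundant balance row replaced by normalization; this is the
independent oracle for the rate inversion and achieves the 1e−10
round-trip tolerance even for steep random targets. Chains with a vanishing
off-diagonal rate fall back to square-and-multiply matrix powers.
Probability-vector identities are compared in total-variation distance.

## Event-driven simulator

Exact sampling of the same discrete-time chain, needed when site identity
matters (turnover accounting). Each site carries a geometric waiting time
(the discrete-time analog of the exponential law, matching the
Bernoulli-per-step transition matrix); after every realized event, and on
every condition switch, all pending intervals are redrawn because `d[S]`
changed — the geometric law is memoryless, so the redraw is statistically
neutral. Ties between sites at the same step are resolved uniformly at
random and processed one at a time, preserving the one-change-at-a-time
structure. Runtime scales with the event count, not the horizon: a single
working-point connection over 10¹⁰ steps completes in tens of
milliseconds. Populations derive per-connection streams as
`base_seed + index` and are bit-reproducible.

Because the chain's law depends on time only through `b·t` (with `d`
proportional to `b`), simulator-versus-master-equation checks run at
`b = 1e−3` with proportionally short horizons; this is a pure time
rescaling, not a changed regime.

## Information measures

`MI(S(0); S(t))` and `MI(S(t); condition)` are computed from conditional
distribution trajectories by total probability, so stored conditionals can
be re-weighted under any initial law or condition mix without
recomputation. The default pipelines use exact propagation — the plug-in
entropy has no estimator bias there and results are deterministic; a
population mode (plug-in estimator on empirical frequencies of 500–1500
simulated connections, no bias correction) mirrors the finite-population
procedure and is used for cross-validation only.

Time-scale extraction (`tau_fraction`) finds threshold crossings on the
exponential recording grid (`t_k = round(1.2^k)`, deduplicated) with linear
interpolation in log-time; a never-crossed threshold returns a
"beyond horizon" sentinel (`inf`) rather than raising. For the plateau
decay time τ₀.₉₅ the plateau height is taken analytically as the t=0
mutual information of the matched two-state model, H₂(q) — this avoids
fragile numerical plateau detection on log grids. "Decayed to zero" is
operationalized as MI < 1e−3 bits.

## Two-state reduction

Lumping the two peaks into states with stationary masses `(1−C₂, C₂)`
(where `C₂` is the upper-peak mass `Σ_{S>S̃} p_wp[S]`, not the mixture
weight; they agree to ~1e−3 at the defaults) gives a 2×2 chain with
eigenvalues `{1, 1 − R/(C₂(1−C₂))}`. The rate is matched by equating the
stationary probability flow through the barrier state `S̃` (the interpeak
minimum; ties resolve to the smallest count):

    R = (N−S̃)·b·p_wp[S̃]  ≈ 5.8e−11 at the defaults.

The closed-form exponential evolution is the continuous-time envelope of
the discrete chain; at per-step rates of order 1e−10 the discretization
error is far below every tolerance used.

**Known limitation (computed by the test suite).** Flux matching counts
every barrier crossing as a peak switch, but from `S̃+1` the committor to
the upper peak is only ≈ 0.65 at the defaults, so `R/(C₂(1−C₂))`
(6.45e−10) overestimates the exact spectral gap of the working-point chain
(4.18e−10) by ~1.5×. The lumped MI curve therefore decays somewhat early;
its worst-case deviation from the exact curve after the first decay is
≈ 0.07 bits. The matched rate is retained as the model's definition — it
is what the slowdown factor and the sweep intuition are built on — and the
deviation is asserted at its measured size in the unit tests, while the
stricter 0.05-bit agreement check is kept (and currently fails) in the
acceptance suite.

The slowdown factor `((N−S̃)·p_wp[S̃] / Σ_{S≤S̃} p_wp[S])⁻¹ ≈ 155`
quantifies the multi- versus mono-synaptic storage advantage: the ratio of
lower-peak mass to its barrier exit flux per unit `b`; `b` cancels, so it
is a pure shape property of the stationary distribution.

## Calibration of steps per day

The analytic bridge to experimental time uses the probability that a
connection with post-formation count `S` forms a synapse during a `T`-step
window and keeps it to the window's end, under the approximation that at
most one synapse forms per window. The geometric-series closed form is
implemented exactly as derived (its summation convention enumerates
formation steps `t = 0..T−1` with an `a^(t−1)` no-earlier-formation
factor; the brute-force test oracle enumerates the same sum), with the
degenerate case `(N−S+1)b = S·d[S]` evaluated by its analytic limit and
`(1−x)^T` computed via `log1p` for small rates.

The population fraction divides an expectation of this probability by the
mean pre-existing synapse count. The expectation measure is genuinely
underdetermined; the implemented default ("conditional") averages the
conditional probability over pre-formation counts distributed as the
working-point law restricted to formable states (renormalized) and divides
by the full working-point mean E[S]. Two alternatives ("restricted": both
moments on the restricted law; "full": unnormalized numerator) are exposed
behind a flag. At the printed working point the default gives a daily
fraction of 0.0485 at `T = 2.3e7` and a calibrated `T ≈ 2.15e7` for the 5%
target — the only reading of the three that reproduces the published
calibration.

The fraction is non-monotone in `T`: it rises on the fast lower-peak
turnover scale, overshoots, and settles as the single-formation window
saturates. The solver therefore bisects for the *settling* (descending)
crossing by default — the steady-state turnover match — with an "onset"
branch (first ascending crossing) available. The published simulation-based
re-calibration against experimental control bars requires the external
spine-count data and is out of scope; protocols default to
`T = 23·10⁶` steps/day.

## Protocols

* **Decay**: each initial count propagated under one fixed condition; MI by
  total probability on the exponential grid. Initial conditions: the wp law
  itself, the two-delta law (`1−C` at 0, `C` at `N`), and the
  piecewise-uniform law (`1−C` uniform on {0,1,2}, `C` uniform on {4..N};
  the ambiguous count 3 is excluded by default and assignable by
  configuration).
* **Learning/retention**: phase 1 equilibrates to the working point
  (initial-count independence verified by total variation < 1e−6); phase 2
  switches each branch to its condition; phase 3 reverts all branches to
  the working point. Phases that fail their convergence check log a warning
  rather than raising. τ₀.₅₀ is the 50%-of-phase-maximum crossing;
  ΔT = τ₀.₅₀(retention)/τ₀.₅₀(learning). Exact condition-mix weighting is
  the deterministic default; the sampled mode draws a condition per
  connection.
* **Retraining**: 30 d working point, 16 d early training (4.35% of
  connections low-stimulated, 0.65% high), 74 d working point, 8 d late
  training with the same assignments; control stays at the working point
  throughout, late-only trains only in the last 8 d. `N = 5`, `σ = 1.0`.
  The population is sized so the expected initial synapse count is ~160
  (`n = round(160/E_wp[S])` ≈ 310 connections) and repeated over 8 seeded
  replicates; per-day created/removed counts come from day-boundary
  occupancy overlap, reported as mean ± SEM across replicates.
* **Sweeps**: one-factor grids over (λ, μ, σ, C) with τ₀.₉₅ or ΔT per
  cell; non-bimodal cells are marked invalid rather than fatal.

**Computed discrepancy.** With the default parameters the exact τ₀.₅₀
ratio is ΔT ≈ 42 (τ₀.₅₀ ≈ 1.7e7 for learning, ≈ 7.3e8 for retention), and
it stays between ~34 and ~79 for every N in 5..12 and σ in {1.0, 1.2}. The
often-quoted "2–3 orders of magnitude" separation refers to the times at
which the phases *reach their stationary distributions* (~10⁸ versus
~10¹⁰–10¹¹ steps), which is a stricter notion than the 50%-crossing ratio.
The acceptance suite asserts ΔT ≥ 100 and that check currently fails; the
acceptance script reports the honestly computed value.

## What the generators emulate — and what they do not

The synthetic populations emulate independent, homogeneous
compound-connections with condition-controlled stationary statistics and
resolvable site identity. They do not emulate: developmental
non-stationarity (the early-life spine over-expression visible in the
early-training comparison of the in-vivo data), activity-dependent
formation rates, interactions between connections, or dendritic geometry.
Passing tests therefore validate the model's internal mathematics and its
published quantitative claims, not the fidelity of any particular biological
circuit.

## Numerical choices, briefly

Probability vectors validated to 1e−12 (stationary) / 1e−10
(trajectories); analytic identities compared at 1e−10 total variation;
MI brute-force oracles at 1e−12 bits; exponential grids with growth 1.2
(1.3 in sweeps to halve the grid); interpolation linear in log-time;
interpeak-minimum ties to the smallest count; simulator seeds derived as
`base + index`; the validity bound `S·d[S] + (N−S)·b ≤ 1` is enforced at
profile construction with the offending count named.
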