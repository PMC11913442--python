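# Methods

## Exact simulator and oracles

A reaction network is species, an N×M stoichiometric matrix S, and one
propensity rule per reaction, restricted to products of rate constants,
species counts, and 0/1-indicator complements (1 − x_s). This covers
mass-action kinetics and promoter-state switching; arbitrary callables are
accepted but flagged untested and excluded from the differentiable path.

The exact simulator is the direct-method SSA: waiting time τ = −ln(u)/R with
u ~ U(0,1] (zero excluded so −ln u is finite), and reaction index the smallest
i with cumulative probability C_i = Σ_{j≤i} r_j/R strictly above u′ (ties go
to the higher index). Ensembles evolve in a vectorized lockstep loop; a
trajectory whose next waiting time would cross the horizon t_end freezes at
its current state, so the ensemble samples the state *at* t_end.

Ground truth for distributions is the truncated chemical master equation:
transitions leaving the truncation box are blocked (reflecting truncation, so
the generator conserves probability), global balance is solved as a sparse
linear system with a normalization row, and the probability mass on the
boundary is reported — exceeding a tolerance (default 1e−6) raises an error
carrying that mass. For the telegraph promoter the default mRNA cap is
⟨m⟩ + 10σ from the closed-form moments, at least 50.

Randomness: a master seed spawns one PRNG stream per trajectory
(`NoiseSource`), each supplying one (u, u′) pair per step. Streams are
consumed in lockstep, so the exact and smoothed simulators can run on the
same sample path, and enlarging the ensemble extends it without reshuffling
existing trajectories.

## The smoothed (differentiable) simulator

Reaction selection replaces each Heaviside step of the cumulative ladder with
a sigmoid of steepness 1/a; the state update replaces the Kronecker delta
with a Gaussian kernel exp(−(i′−i)²/b). Abundances are then real numbers and
every output is, for fixed noise, a smooth function of the rates. Defaults
1/a = 200 and 1/b = 20; a guardrail warns beyond 1/a > 10³ or 1/b > 10²,
where gradients are known to become unstable.

Two stabilizing rules, both piecewise-differentiable:

* **Propensity clamping.** Real-valued states can make a propensity slightly
  negative; negative propensities are clamped to zero (and counted).
* **State clipping to physical bounds.** Each species carries a physical
  range (indicators [0,1], counts [0,∞)), and the state is clipped to it
  after every soft update. This matters because the cumulative ladder gives a
  momentarily *dead* reaction (zero propensity) a zero-width selection
  interval: when u′ grazes that boundary the soft index passes through the
  dead reaction's integer and its stoichiometry row fires at full kernel
  weight. Unclipped, promoter indicators wander to ±3 and the mRNA mean is
  biased by >30%; clipped, the accuracy metric below lands at a fraction of a
  percent.

Known accuracy limits, quantified on the telegraph benchmark
(kon=0.5, koff=1, r=10, γ=1): a reaction whose selection probability q is
comparable to a loses ≈1.6·a/q of its events to "null" steps in which the
soft index sits between two rows and both kernel weights collapse to
e^(−1/4b). At the defaults this thins the rare promoter-binding events by
~25–30%, inflating the ON-state occupancy by ~10% and the first four raw
mRNA moments by ~7–9% (all biased high). The distribution-level error,
JSD(p_DGA‖p_exact)/H(p_exact), plateaus at ~2–4×10⁻³. Tails are not
captured accurately; nothing here should be used for rare-event estimates.

## Gradients

Gradients are pathwise and forward-mode: parameters are seeded as dual
numbers (value + tangent per seed direction) and tangents propagate through
the time update, the soft selection, and the soft update; the noise is held
fixed. With ≤7 parameters throughout, forward mode is exact and cheap, and
`pathwise_gradient` verifies against central finite differences — at an FD
step small enough (1e−7 in log-parameter space) that no discrete branch
(trajectory freeze, state clip) flips inside the stencil; at larger steps the
FD estimator itself, not the gradient, is corrupted by those branch flips.
One structural consequence: a network with a single reaction has no selection
step, so a count's pathwise derivative with respect to its only rate is
exactly zero — the parameter acts only through the discrete step count.

The *exact* pathwise gradient ("full") is heavy-tailed over long horizons:
state tangents feed back into propensities and are amplified by up to
1/(4a) at each selection-boundary grazing, so per-sample gradients reach
10⁵–10⁶ while the averaged slope is O(1), and stochastic optimizers follow
the biased bulk. Fitting therefore uses the "clipped" estimator: per-step
elementwise clamping of state tangents at ±10 (in units of count per unit
log-parameter). Measured against noise-averaged macroscopic finite
differences, the clipped moment Jacobian keeps all signs and stays full
rank with magnitudes within ~2×; since the losses are residual-squared,
full rank guarantees the optimization's fixed point remains at zero
residuals regardless of the remaining Jacobian distortion. A fully
"detached" estimator (no state tangents in rates) is retained as a
diagnostic; its Jacobian loses rank and stalls fits.

## Estimation

The single-condition loss is L(θ) = (⟨m̂⟩−⟨m⟩)² + (σ̂_m−σ_m)²; the
multi-condition variant sums it over conditions with r and γ shared and a
per-condition repressor binding rate kon (box-bounded to [0.01, 99]), koff
fixed at 1 to set the time unit. Statistics are means/population-stds of
final states at t_end = 10 (not time averages), matching how the synthetic
targets are generated by exact simulation from the same initial condition
(promoter ON, zero mRNA) — target and model therefore measure the same
ensemble even where t = 10 is not fully stationary.

Optimization: ADAM on log-parameters (positivity for free), learning rate
0.05–0.1, 300 iterations, 500 trajectories per iteration, fresh noise each
iteration from one persistent per-fit stream. The returned estimate is the
Polyak-style average of the final 25% of log-iterates; with per-iteration
noise this beats any single iterate, whose "best seen loss" is largely a
lucky draw.

Confidence intervals: δθᵢ = (∂²L/∂θᵢ²)⁻¹ with the curvature from a quadratic
fit to a noise-averaged 1-D profile (9 points spanning ±10%, 10 repeats per
point). The interval is [θ̂ᵢ − δ, θ̂ᵢ + 1.96 δθᵢ] with the lower arm defined
by matching the upper arm's loss level, which under the quadratic model makes
δ = 1.96 δθᵢ. Flat or concave profiles (or curvature unresolvable over the
scanned span) return an unbounded-interval flag; this is the expected outcome
along the compensating (kon, r, γ) direction of the telegraph model, whose
moment map is degenerate when all three rates are free.

The synthetic benchmark samples kon, r, γ uniformly from [0.1, 10] (koff=1),
20 sets, targets from exact simulation with 2000 trajectories. Benchmark fits
box-bound the free rates to [0.01, 100]: along the degenerate direction an
unbounded search can drift to very large rates where every simulation
saturates its step cap, at great cost and no gain in fit quality.

Error bars on *predicted* moments (`prediction_uncertainty`) propagate the
per-parameter δθᵢ through the simulator's dual sensitivities,
σ²_pred = Σᵢ (∂stat/∂θᵢ · δθᵢ)², and add Monte-Carlo error. On sloppy
landscapes these intervals are wide or unbounded — faithfully reporting that
two moments constrain rate combinations, not individual rates.

## Circuit design

The four-state promoter (OFF/ON × activator unbound/bound) transcribes at
rate r in the two ON states. Binding is concentration-dependent (c·kb with
kb = 0.02 fixed, setting the time unit); the η factors multiply the ON-state
binding/unbinding and the bound-state activation/deactivation, and their log
ratio Δμ = ln(η_ab η_ua/η_ib η_ba) is the thermodynamic drive of the cycle;
Φ = JΔμ ≥ 0 is the dissipated power with J the stationary cycle flux. The
base (unbound) activation/deactivation rates are named k_act and k_deact.

The design loss compares the mean transcription rate r(π₂+π₃) against a
target on N = 10 log-spaced concentrations in [10⁻², 10²]; π comes from
dwell-time fractions of 600 differentiable simulations per concentration
(soft state membership renormalized per row, first 20% of each trajectory
discarded as burn-in; horizon t = 30). All ten concentrations run as one
batched ensemble via per-trajectory scaling of the two binding reactions.
Seven parameters are optimized in log space (120 ADAM iterations, lr 0.1);
iterates are scored with the exact stationary solve (cheap and
deterministic) and the best-scoring one is returned. Final reports always
evaluate the learned response with the stationary oracle; SSA dwell times
provide the non-differentiable cross-check.

The two built-in targets are synthetic: sixth-degree polynomials in ln c
fitted to the exact responses of two frozen reference parameter sets — one
near equilibrium (shallow response, sharpness ≈ 0.05·r) and one strongly
driven (sharp, ≈ 0.17·r). Generating targets from reachable parameter sets
guarantees a perfect fit exists; the design claims tested are therefore fit
quality and the sharpness→dissipation ordering, not specific curve shapes.

## Problem sizes and limitations

Default study sizes: 2000 trajectories for ensembles and accuracy curves
(horizon t = 200 for plateau measurements), 500 per fitting iteration,
600 per concentration for design, 20 synthetic benchmark sets. The
synthetic-data generator emulates moment measurements of steady-state mRNA
counts with purely Monte-Carlo error; it does not model cell-to-cell
extrinsic noise, measurement calibration error, or partial observation, so
passing recovery tests demonstrates correctness of the inference machinery,
not robustness to real experimental artifacts. The smoothed simulator's
moment bias (above) is inherited by anything computed from it; fits remain
consistent because target and prediction are compared through the same
simulator. Degenerate fits recover moment-equivalent, not true, parameters —
that is a property of the moment map, not a defect of the optimizer.
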