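# dgasim

Differentiable Gillespie simulation of stochastic chemical kinetics, with
applications to kinetic-parameter inference and the design of gene-regulatory
circuits.

## The problem

The Gillespie stochastic simulation algorithm (SSA) simulates a reaction
network exactly: given propensities r_i(x) with total rate R = Σ r_i, it draws
a waiting time τ = −ln(u)/R and fires the reaction i′ with the smallest index
satisfying Σ_{j≤i′} r_j/R > u′. Both the index choice and the integer state
update x → x + S_{i′} are discontinuous in the kinetic parameters θ, so the
simulation cannot be differentiated — which blocks gradient-based fitting of
rate constants to data and gradient-based design of stochastic circuits.

`dgasim` implements a smoothed variant in which

* the Heaviside ladder of the index selection is replaced by sigmoids of
  steepness 1/a, giving a real-valued index
  i′ = 1 + Σ_{i<N} σ((u′ − C_i)/a) with C_i the cumulative selection
  probability, and
* the Kronecker delta of the state update is replaced by a Gaussian kernel,
  x_α → x_α + Σ_i exp(−(i′−i)²/b) S_iα,

so that, for a fixed realization of the uniform draws (u, u′), every simulated
quantity is a smooth function of θ and pathwise gradients propagate through
the whole trajectory (forward-mode dual numbers; parameter vectors here are
small). Defaults 1/a = 200, 1/b = 20.

The package ships both simulators, a truncated chemical-master-equation (CME)
steady-state oracle, divergence metrics (KL, Jensen–Shannon, entropy), two
benchmark promoter architectures — the two-state *telegraph* repressed
promoter (mean mRNA ⟨m⟩ = (r/γ)·koff/(kon+koff), Fano factor
F = 1 + r·kon/((kon+koff)(kon+koff+γ))) and a four-state nonequilibrium
activated promoter with cycle drive Δμ = ln(η_ab η_ua / η_ib η_ba), flux
J = π₀kb[c] − π₁ku and dissipated power Φ = JΔμ — plus ADAM-based moment
fitting with curvature confidence intervals and dose–response design.

It is intended for quantitative/systems biologists studying stochastic gene
expression and for anyone prototyping differentiable discrete-event
simulation.

## Worked example

```bash
python examples/01_exact_vs_smoothed_simulation.py
```

```
analytic steady state: mean mRNA = 6.6667, Fano = 2.3333
exact SSA ensemble:    mean = 6.593, Fano = 2.234
smoothed (DGA):        mean = 7.171, Fano = 1.908
JSD(p_DGA || p_exact)/H(p_exact) = 0.0018
```

The telegraph promoter at (kon=0.5, koff=1, r=10, γ=1) has stationary mean
20/3; the exact ensemble agrees within sampling error, and the smoothed
simulator lands close with its characteristic slight moment overestimate.
The last line is the headline accuracy metric: the Jensen–Shannon divergence
between smoothed and exact steady-state mRNA distributions, normalized by the
entropy of the exact one — a fraction of a percent.

Gradient-based parameter recovery (`03_fit_kinetic_parameters.py`) prints

```
synthetic target: mean = 1.304, std = 1.587
fitted parameters: kon = 1.829, r = 5.515   (truth: kon = 2.0, r = 6.0)
```

— ADAM on the pathwise gradient recovers the repressor binding and
transcription rates from two simulated moments; the accompanying
curvature-based 95% CIs are wide, reflecting how weakly two moments
constrain the rates. Further examples: `02_gradients_through_simulation.py`
(pathwise gradients vs finite differences on shared noise),
`04_design_promoter_response.py` (designing a sharp dose–response and
reading off its dissipated power).

A thin CLI mirrors these workflows:
`dga simulate|accuracy|fit|design|benchmark --config FILE --out DIR [--seed N]`.

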