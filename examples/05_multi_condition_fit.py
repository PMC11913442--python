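"""Joint fit across conditions sharing transcription and degradation rates.

Emulates a titration experiment: the same promoter measured at three
repressor concentrations. Each condition has its own repressor binding rate
kon (which tracks the repressor concentration), while the transcription rate
r and the degradation rate gamma are shared. The loss sums the squared
moment mismatches over conditions.
"""

import numpy as np

from dgasim import MomentTarget, OptimizerConfig, SimConfig, TwoStateParams, build_two_state
from dgasim.estimation import fit_multi_condition
from dgasim.reaction_core import simulate_exact

r_true, gamma_true = 8.0, 2.0
kon_true = (0.2, 1.0, 5.0)
targets = []
for i, kon in enumerate(kon_true):
    system = build_two_state(TwoStateParams(kon_r=kon, r=r_true, gamma=gamma_true))
    ens = simulate_exact(system, [1, 0],
                         SimConfig(t_end=10.0, n_traj=1000, seed=40 + i, max_steps=10_000))
    m = ens.counts(system, "m")
    targets.append(MomentTarget(mean=float(m.mean()), std=float(m.std()),
                                condition_id=f"condition-{i}"))
    print(f"condition {i}: kon* = {kon:4.1f} -> target mean {m.mean():.3f}, "
          f"std {m.std():.3f}")

opt = OptimizerConfig(lr=0.08, iterations=150, n_traj=300, t_end=10.0)
result = fit_multi_condition(targets, opt=opt, seed=9)
print(f"shared rates: r = {result.theta_hat['r']:.2f} (true {r_true}), "
      f"gamma = {result.theta_hat['gamma']:.2f} (true {gamma_true})")
for i, kon in enumerate(kon_true):
    print(f"per-condition kon {i}: {result.theta_hat[f'kon#{i}']:.2f} (true {kon})")
print("The shared/per-condition tying mirrors a repressor titration; exact "
      "recovery is not expected (the moment map is sloppy) but the fitted "
      "model reproduces all six target moments jointly.")
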