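"""Simulate the telegraph promoter exactly and with the smoothed simulator.

Builds the classic two-state repressed promoter (repressor binds at kon=0.5,
unbinds at koff=1 which sets the time unit, transcription at r=10,
mRNA decay at gamma=1), runs both simulators to t=200, and compares the
final-state mRNA distribution against the truncated-master-equation steady
state.
"""

import numpy as np

from dgasim import (
    Smoothing,
    SimConfig,
    TwoStateParams,
    build_two_state,
    empirical_pmf,
    jsd_over_entropy,
    simulate_dga,
    simulate_exact,
    two_state_cme,
    two_state_mean_fano,
)

params = TwoStateParams(kon_r=0.5, koff_r=1.0, r=10.0, gamma=1.0)
system = build_two_state(params)
x0 = [1, 0]  # promoter ON, no mRNA
config = SimConfig(t_end=200.0, n_traj=2000, seed=1, max_steps=30_000)

mean, fano = two_state_mean_fano(params)
print(f"analytic steady state: mean mRNA = {mean:.4f}, Fano = {fano:.4f}")

exact = simulate_exact(system, x0, config)
m_exact = exact.counts(system, "m")
print(f"exact SSA ensemble:    mean = {m_exact.mean():.3f}, "
      f"Fano = {m_exact.var() / m_exact.mean():.3f}")

soft = simulate_dga(system, x0, config, Smoothing.from_inverse(200, 20))
m_soft = soft.counts("m")
print(f"smoothed (DGA):        mean = {m_soft.mean():.3f}, "
      f"Fano = {m_soft.var() / m_soft.mean():.3f}")

p_exact = two_state_cme(params).marginal("m")
ratio = jsd_over_entropy(empirical_pmf(m_soft), p_exact)
print(f"JSD(p_DGA || p_exact)/H(p_exact) = {ratio:.4f}")
print("The ratio is the smoothing error relative to the distribution's own "
      "uncertainty; a few tenths of a percent means the smoothed simulator "
      "reproduces the exact copy-number statistics closely, with a slight "
      "systematic overestimate of the moments.")
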