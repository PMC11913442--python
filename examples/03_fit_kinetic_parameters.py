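"""Recover telegraph-promoter rates from simulated moment data.

A ground-truth parameter set generates a synthetic "experiment" (mean and
standard deviation of the mRNA count from exact simulation); ADAM on the
pathwise gradient of the moment loss then re-estimates the repressor binding
rate kon and the transcription rate r, with the degradation rate treated as
known. A curvature-based 95% confidence interval is attached to each fitted
parameter.
"""

import numpy as np

import dgasim.autodiff as ad
from dgasim import (
    MomentTarget,
    NoiseSource,
    OptimizerConfig,
    SimConfig,
    Smoothing,
    TwoStateParams,
    build_two_state,
    confidence_interval,
    fit,
    moment_loss,
    simulate_dga,
    simulate_exact,
)
from dgasim.estimation import ensemble_mean_std

truth = TwoStateParams(kon_r=2.0, r=6.0, gamma=1.5)
system_true = build_two_state(truth)
ens = simulate_exact(system_true, [1, 0],
                     SimConfig(t_end=10.0, n_traj=2000, seed=42, max_steps=20_000))
m = ens.counts(system_true, "m")
target = MomentTarget(mean=float(m.mean()), std=float(m.std()))
print(f"synthetic target: mean = {target.mean:.3f}, std = {target.std:.3f}")

system = build_two_state(TwoStateParams(kon_r=1.0, r=5.0, gamma=truth.gamma))
opt = OptimizerConfig(lr=0.08, iterations=300, n_traj=500, t_end=10.0)
result = fit(system, ["kon", "r"], target, opt=opt, smoothing=Smoothing(), seed=7)
print(f"fitted parameters: kon = {result.theta_hat['kon']:.3f}, "
      f"r = {result.theta_hat['r']:.3f}   (truth: kon = 2.0, r = 6.0)")


def profile_loss(theta_vec, rep):
    seed = 1000 + rep
    cfg = SimConfig(t_end=10.0, n_traj=500, seed=seed, max_steps=5000)
    e = simulate_dga(system, [1, 0], cfg, Smoothing(),
                     params={"kon": theta_vec[0], "r": theta_vec[1]},
                     noise=NoiseSource(seed, 500))
    mean, std = ensemble_mean_std(e.counts("m"))
    return float(moment_loss(mean, std, target))


theta_hat = np.array([result.theta_hat["kon"], result.theta_hat["r"]])
for i, name in enumerate(["kon", "r"]):
    ci = confidence_interval(profile_loss, theta_hat, i)
    if ci.unbounded:
        print(f"95% CI for {name}: unconstrained (flat loss direction)")
    else:
        print(f"95% CI for {name}: [{ci.lower:.2f}, {ci.upper:.2f}]")
print("Fitted rates reproduce the target moments; wide or asymmetric "
      "intervals flag directions the moment data constrain only weakly.")
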