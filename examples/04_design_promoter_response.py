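"""Design a four-state promoter's dose-response curve by gradient descent.

A target input-output relation (mean transcription rate vs activator
concentration, a sixth-degree polynomial in ln c) is matched by tuning the
seven promoter transition parameters through the differentiable simulator's
dwell-time occupancies. The report quantifies response sharpness and the
power Phi = J*dmu dissipated by the nonequilibrium cycle.
"""

from dgasim import OptimizerConfig
from dgasim.circuit_design import (
    DesignConfig,
    design_fit,
    design_report,
    sharp_reference_params,
    target_from_params,
)

target = target_from_params(sharp_reference_params(), name="sharp")
cfg = DesignConfig(n_traj=600, t_end=30.0,
                   opt=OptimizerConfig(lr=0.1, iterations=120, n_traj=600))
result, learned = design_fit(target, seed=5, cfg=cfg)
report = design_report(result.theta_hat, target)

print("learned transition parameters:")
for name, value in result.theta_hat.items():
    print(f"  {name:8s} = {value:8.3f}")
print(f"max |learned - target| response error: {report.max_abs_error:.4f} "
      f"(transcription-rate units, r = {target.r_max})")
print(f"response sharpness max d<r>/d ln c:    {report.sharpness:.3f}")
print(f"cycle drive dmu = {report.drive:.2f}, mean dissipated power "
      f"Phi = {report.power.mean():.4f}")
print("A sharp response needs a strongly driven cycle: the learned circuit "
      "breaks detailed balance and pays for its sensitivity with dissipation.")
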