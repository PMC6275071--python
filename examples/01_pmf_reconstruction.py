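"""Reconstruct a potential of mean force from steered-Langevin force records.

A steered center is dragged through a chain of harmonic springs whose
integrated-out potential of mean force is exactly harmonic with
k_eff = (Σ 1/k_i)^-1, so the reconstruction can be checked against a
closed form.  Two independent-seed runs are compared for convergence.
"""

import numpy as np

import unbindkit as uk
from unbindkit import synthetic as syn

chain = syn.harmonic_chain([4.0, 6.0, 8.0])     # kcal/mol/Å^2
schedule = uk.build_schedule(5.0, [(0.0, 5.0, 0.2)])
path = np.stack([[[d, 0.0, 0.0]] for d in schedule.grid])

profiles = []
for seed in (11, 22):
    spec = syn.LangevinSpec(seed=seed, n_steps_per_segment=2000)
    windows = syn.generate_steering_records(chain, path, spec)
    series = uk.estimate_mean_forces(windows)
    profiles.append(uk.integrate_pmf(series, path, schedule))

report = uk.compare_runs(profiles, tolerance=1.0)
exact = 0.5 * chain.k_eff * schedule.grid ** 2

print(f"windows: {schedule.n_windows}, samples/window: "
      f"{windows[0].all_samples.shape[0]} (4 segments)")
print(f"PMF at 5.0 Å: {profiles[0].pmf[-1]:.3f} ± {profiles[0].sigma[-1]:.3f} "
      f"kcal/mol   (exact: {exact[-1]:.3f})")
print(f"max |ΔPMF| between the two runs: {report['max_abs_deviation']:.4f} "
      f"kcal/mol -> convergent: {report['convergent']}")
# The PMF rises as the center is pulled against the attractive springs;
# the two independent runs agreeing within their propagated uncertainties
# is the convergence evidence a steered study reports.
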