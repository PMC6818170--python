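"""Stochastic two-particle mean reaction time versus theory.

One molecule is fixed at the center of a reflecting 300 nm square; the other
diffuses and the pair reacts through the moment-matched indicator
interaction.  The ensemble-mean reaction time is compared with the exact
well-mixed MRT on the equal-area disc.
"""

import numpy as np

from tethersim import (
    DoiProblem,
    GaussianReachKernel,
    LatticeDomain,
    PairwiseRule,
    ReactionNetwork,
    SpeciesDef,
    WorldState,
    calibrate_doi,
    convert_catalytic_3d,
    equal_measure_radius,
    exact_mrt_2d_disc,
    simulate,
    trajectory_seed,
)

D_um, L, n_traj = 1.25e-3, 25.0, 500
cal = calibrate_doi(GaussianReachKernel(L, convert_catalytic_3d(0.1), 3))
R = equal_measure_radius(300.0, 2)
T_theory = exact_mrt_2d_disc(DoiProblem(2, R, D_um * 1e6, cal.epsilon, cal.lam)).T

domain = LatticeDomain(2, 300.0, 128, "reflecting")
net = ReactionNetwork(
    [SpeciesDef("A", 0.0), SpeciesDef("B", D_um)],
    [],
    [PairwiseRule("A", "B", None, None, cal)],
)
center = domain.voxels_per_axis // 2
times = []
for k in range(n_traj):
    rng = np.random.default_rng(trajectory_seed(1, k, 0))
    pos_b = rng.integers(0, domain.voxels_per_axis, size=2)
    world = WorldState(domain, np.array([0, 1]),
                       np.array([[center, center], list(pos_b)]), seed=0)
    tr = simulate(world, net, 60 * T_theory, stop_on_reaction=True,
                  seed=trajectory_seed(1, k, 1))
    times.append(tr.reaction_time)

mean = np.mean(times)
sem = np.std(times, ddof=1) / np.sqrt(n_traj)
print(f"calibrated interaction: eps = {cal.epsilon:.2f} nm, lambda = {cal.lam:.3f} /s")
print(f"simulated  <T> = {mean:.2f} +- {sem:.2f} s   ({n_traj} trajectories)")
print(f"analytic   <T> = {T_theory:.2f} s            (equal-area disc)")
print(f"z-score        = {(mean - T_theory) / sem:+.2f}")
print()
print("Agreement within a few standard errors shows the lattice jump process "
      "reproduces the continuum volume-reactivity model.")
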