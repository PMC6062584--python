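"""Trajectory metrics: navigation indices, heading histograms, response fits.

Works identically on simulated trajectories and on tracks read back from
a CSV file.
"""

import numpy as np

from larvataxis import (
    AngularDistribution,
    angular_distribution,
    bh_adjust,
    fit_saturating_curve,
    navigation_index,
    one_sample_t,
    rms_angular_deviation,
    welch_test,
)
from larvataxis.io import generate_fixture

# limiting cases: a straight escape path has NI_x = -1, a closed loop 0
_, ballistic = generate_fixture("ballistic")
_, loop = generate_fixture("loop")
print(f"ballistic path NI_x = {navigation_index(ballistic[0][0], 'x'):+.1f}")
print(f"closed loop   NI_x = {navigation_index(loop[0][0], 'x'):+.1f}")

# heading distribution of a small biased ensemble, 30-degree bins
_, ens = generate_fixture("pos_ensemble", seed=3)
dist = angular_distribution(ens.all_trajectories)
print(f"heading probabilities (n={dist.n_steps} steps): "
      + ", ".join(f"{p:.3f}" for p in dist.probabilities))
flat = AngularDistribution(np.full(6, 1 / 6))
print(f"RMS deviation from an isotropic walk: {rms_angular_deviation(dist, flat):.3f}")

# saturating intensity response: NI(I) = A (1 - exp(-I/s)); amplitude A
# is the plateau index, s the irradiance scale of the rise
intensities = np.array([1, 5, 10, 20, 40, 80.0])
ni = -0.28 * (1 - np.exp(-intensities / 10.0)) + np.random.default_rng(1).normal(0, 0.005, 6)
fit = fit_saturating_curve(np.column_stack([intensities, ni]))
print(f"saturating fit: A = {fit.amplitude:+.3f}, s = {fit.scale:.1f} W/m^2")

# the comparison statistics used on tracking data
t, dof, p = welch_test([-0.25, -0.24, -0.27, -0.23], [-0.01, 0.02, -0.02, 0.0])
print(f"Welch test wildtype vs control: t = {t:.2f}, dof = {dof:.1f}, p = {p:.2g}")
t1, p1 = one_sample_t([-0.07, -0.06, -0.09, -0.05], 0.0)
print(f"one-sample test vs 0: t = {t1:.2f}, p = {p1:.3f}")
print(f"BH-adjusted p-values: {np.round(bh_adjust([p, p1, 0.04]), 4)}")
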