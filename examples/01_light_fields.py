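"""Build, fit and query planar light fields, and integrate a spectrum.

The arena is a 23 cm square plate; projected patterns vary linearly
across it, so three coefficients (centre irradiance and two slopes)
describe the whole stimulus.
"""

import numpy as np

from larvataxis import (
    SpectrumTable,
    delta_intensity,
    field_from_coefficients,
    fit_linear_field,
    integrate_band,
    intensity_at,
    mean_intensity,
)

# a field sloping up toward the light source on the +x side
field = field_from_coefficients(a0=20.0, a1x=0.5, a1y=0.0, theta_deg=40.0)
print(f"I(0, 0)   = {intensity_at(field, 0, 0):.2f} W/m^2")
print(f"I(10, 0)  = {intensity_at(field, 10, 0):.2f} W/m^2")
print(f"<I>       = {mean_intensity(field):.2f} W/m^2  (plate mean = centre value)")
# a step toward darker ground has a negative intensity change, so the
# Metropolis rule always accepts it
print(f"dI for a 1 cm step toward -x: {delta_intensity(field, (0, 0), (-1, 0)):+.2f}")

# recover the plane from noisy point measurements (9-point grid)
rng = np.random.default_rng(0)
xs, ys = np.meshgrid([-8.0, 0.0, 8.0], [-8.0, 0.0, 8.0])
z = 20 + 0.5 * xs.ravel() + rng.normal(0, 0.1, 9)
fitted, diag = fit_linear_field(np.column_stack([xs.ravel(), ys.ravel(), z]))
print(f"fitted plane: a0={fitted.a0:.3f}, a1x={fitted.a1x:.4f}, a1y={fitted.a1y:.4f} "
      f"(rss={diag.rss:.4f})")

# total irradiance = spectral irradiance integrated over the blue/green
# band the larval photoreceptors respond to (380-570 nm)
wl = np.arange(300.0, 701.0, 5.0)
spectral = np.clip(1.0 - np.abs(wl - 475.0) / 120.0, 0.0, None)
spectrum = SpectrumTable(wl, spectral)
print(f"band-integrated irradiance [380, 570] nm: {integrate_band(spectrum):.2f} W/m^2")
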