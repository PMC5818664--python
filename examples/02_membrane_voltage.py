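"""Membrane potential by double integration of a charge density.

Builds an analytic parallel-plate profile, solves the 1D Poisson equation
by cumulative double integration, and compares the plateau difference to
the closed form sigma*d/eps0.
"""

import numpy as np

from permeon import potential_from_density
from permeon.constants import PHI_V_PER_E_PER_ANG
from permeon.synthetic import capacitor_sheet_positions, gen_charge_density

sigma, sep, n_bins = 2e-4, 30.0, 1000
rho = gen_charge_density("capacitor", n_bins=n_bins, sigma=sigma, separation=sep)
phi = potential_from_density(rho)
z1, z2 = capacitor_sheet_positions(n_bins, (0.0, 160.0), sep)
drop = phi.phi[phi.z < z1 - 2].mean() - phi.phi[phi.z > z2 + 2].mean()
analytic = sigma * (z2 - z1) * PHI_V_PER_E_PER_ANG * 1e3

print(f"sheet density {sigma} e/A^2, separation {z2 - z1:.2f} A, {n_bins} bins")
print(f"integrated plateau difference: {drop:.4f} mV")
print(f"closed form sigma*d/eps0     : {analytic:.4f} mV")
print(f"relative error               : {abs(drop - analytic) / analytic:.2e}")
# The integrator treats the binned density as piecewise constant, so the
# only error left is the binning itself.
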