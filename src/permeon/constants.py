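"""Physical constants and unit-conversion factors.

Internal units: length in Angstrom, time in ps, charge in elementary
charges, energy in kJ/mol, potential in mV.
"""

#: elementary charge, C
E_CHARGE = 1.602176634e-19

#: Boltzmann constant times Avogadro, kJ mol^-1 K^-1
KB_KJ_MOL = 0.008314462618

#: vacuum permittivity, F m^-1
EPS0 = 8.8541878128e-12

#: potential (V) produced by a double integral of charge density carrying
#: units e/A^3 integrated twice over A (net e/A), divided by eps0
PHI_V_PER_E_PER_ANG = E_CHARGE / (EPS0 * 1e-10)

#: conductance (pS) per event per (us * mV): G = n e / (t |V|)
#: n * E_CHARGE [C] / (t_us 1e-6 s * V_mV 1e-3 V) -> S, * 1e12 -> pS
PS_PER_EVENT_PER_US_MV = E_CHARGE * 1e21

#: current (pA) per event per us
PA_PER_EVENT_PER_US = E_CHARGE * 1e18
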