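"""Physical constants (CODATA 2018) used throughout the package.

The Eyring prefactor kB*T/h and the nm<->eV conversion constant live here so
that every module agrees on the same values to full precision.
"""

# Boltzmann constant, J/K
KB = 1.380649e-23
# Planck constant, J*s
H = 6.62607015e-34
# Gas constant in thermochemical units, kcal/(mol*K)
R_KCAL = 1.987204e-3
# Speed of light, m/s
C_LIGHT = 2.99792458e8
# Avogadro constant, 1/mol
NA = 6.02214076e23
# Transmission coefficient in the Eyring equation (standard assumption)
KAPPA = 1.0
# hc in eV*nm: lambda[nm] = HC_EV_NM / E[eV]
HC_EV_NM = 1239.842

LN2 = 0.6931471805599453
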