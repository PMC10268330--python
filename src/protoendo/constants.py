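"""Physical constants and unit-conversion factors.

Interface units follow bench conventions (lengths in um, concentrations in
mM, permeabilities in cm/s); internal computations convert once at the
boundary using the factors below.
"""

# CODATA values
BOLTZMANN_ERG_PER_K = 1.380649e-16  # erg/K
BOLTZMANN_J_PER_K = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT_J = 8.31446261815324  # J/(mol K)

# length conversions
CM_PER_UM = 1.0e-4
UM_PER_CM = 1.0e4

# 1 mM = 1e-3 mol/L = 1e-6 mol/cm^3 = 1 mol/m^3
MOL_PER_CM3_PER_MM = 1.0e-6
MOL_PER_M3_PER_MM = 1.0

DEFAULT_TEMPERATURE_K = 298.0


def thermal_energy_erg(T_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_B*T in erg; the native energy unit of the membrane model."""
    return BOLTZMANN_ERG_PER_K * T_K
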