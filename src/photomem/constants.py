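"""Physical constants and unit conversion factors used across the package.

All internal computation is in SI units (metres, seconds, farads per square
metre, newtons per metre, joules). File I/O uses the field-customary units
(micrometres for vesicle geometry, µF/cm² for specific capacitance,
µS/cm for conductivity, nm for AFM heights) with the conversion factors
defined here.
"""

# CODATA 2018 exact values
BOLTZMANN = 1.380649e-23  # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Room temperature of the experiments (23 °C).
DEFAULT_TEMPERATURE = 296.0  # K

#: Relative dielectric constant of the aqueous (sugar/salt) solutions.
WATER_RELATIVE_PERMITTIVITY = 80.0

# Unit conversions (multiply to go to SI)
UF_PER_CM2 = 1e-2  # 1 µF/cm² = 1e-2 F/m²
US_PER_CM = 1e-4   # 1 µS/cm  = 1e-4 S/m
MN_PER_M = 1e-3    # 1 mN/m   = 1e-3 N/m
NM = 1e-9
UM = 1e-6


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in joules."""
    return BOLTZMANN * temperature
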