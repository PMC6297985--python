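"""Physical constants and unit conversions used across the package.

Convention: volumes are entered in liters, flows in L·min⁻¹ (the practical
units of mass-flow controllers), and converted here to SI for all internal
arithmetic.  VOC concentrations are nmol·m⁻³, emission rates nmol·m⁻²·s⁻¹
per one-sided leaf area.
"""

# molar gas constant, J mol^-1 K^-1
R_GAS = 8.314462618

# specific gas constants, J kg^-1 K^-1
R_DRY_AIR = 287.0571
R_WATER_VAPOR = 461.522

# specific heat capacities at constant pressure, J kg^-1 K^-1
CP_DRY_AIR = 1005.0
CP_WATER_VAPOR = 1865.0

# electron rest mass, unified atomic mass units
ELECTRON_MASS_U = 0.000549

# most-abundant-isotope atomic masses, u
MONOISOTOPIC_MASS_U = {
    "H": 1.0078250,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
}

SECONDS_PER_DAY = 86400.0


def lpm_to_m3s(flow_lpm: float) -> float:
    """Convert a volumetric flow from L·min⁻¹ to m³·s⁻¹."""
    return flow_lpm / 60.0e3


def liters_to_m3(volume_l: float) -> float:
    return volume_l * 1.0e-3


def molar_flow(flow_lpm: float, pressure_pa: float, temperature_k: float) -> float:
    """Ideal-gas molar flow (mol·s⁻¹) of a volumetric flow at given T, P."""
    return lpm_to_m3s(flow_lpm) * pressure_pa / (R_GAS * temperature_k)
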