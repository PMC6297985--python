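"""Net CO₂ assimilation, transpiration, and the evaporative-cooling balance.

Fluxes are computed from inlet/outlet concentration differences of the
flow-through cuvette, mirroring the VOC mass balance: CO₂ mixing ratios
(µmol·mol⁻¹) are converted to molar fluxes with the ideal gas law at the
cuvette air temperature; water vapor is handled as absolute humidity in
mol·m⁻³.  Soil respiration/evaporation measured in bare-soil reference
cuvettes is removed from the plant cuvette outlet concentrations before
flux computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cuvette import ConcentrationSeries
from .errors import AlignmentError, InvalidParameterError, RangeError
from .units import (
    CP_DRY_AIR,
    CP_WATER_VAPOR,
    R_DRY_AIR,
    R_GAS,
    R_WATER_VAPOR,
    lpm_to_m3s,
)

__all__ = [
    "PsychrometricState",
    "GasExchangeRates",
    "EnergyBalanceInputs",
    "saturation_vapor_pressure",
    "absolute_humidity",
    "air_density",
    "moist_air_cp",
    "latent_heat_vaporization",
    "net_co2_assimilation",
    "transpiration_rate",
    "soil_reference_correct",
    "evaporative_delta_t",
]

# Magnus correlation constants (saturation vapor pressure over water)
_MAGNUS_A = 610.94   # Pa
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04   # degC


@dataclass(frozen=True)
class PsychrometricState:
    """Moist-air state: temperature (K), pressure (Pa), RH as a fraction."""

    temperature_k: float
    pressure_pa: float
    relative_humidity: float

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise InvalidParameterError("temperature must be positive (K)")
        if self.pressure_pa <= 0:
            raise InvalidParameterError("pressure must be positive (Pa)")
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise InvalidParameterError("relative humidity must be in [0, 1]")


@dataclass(frozen=True)
class GasExchangeRates:
    """Leaf-area-normalized rates: assimilation in µmol·m⁻²·s⁻¹ (uptake
    positive), transpiration in mmol·m⁻²·s⁻¹ (release positive)."""

    assimilation_umol_m2_s: float
    transpiration_mmol_m2_s: float


@dataclass(frozen=True)
class EnergyBalanceInputs:
    """Inputs of the steady-state evaporative-cooling balance.

    All SI except transpiration, which follows the reporting convention
    (µmol·m⁻²·s⁻¹).  ``from_practical`` accepts the inlet flow in L·min⁻¹.
    """

    transpiration_umol_m2_s: float
    leaf_area_m2: float
    latent_heat_j_mol: float
    air_density_kg_m3: float
    inlet_flow_m3_s: float
    heat_capacity_j_kg_k: float

    def __post_init__(self) -> None:
        if self.transpiration_umol_m2_s < 0:
            raise InvalidParameterError("transpiration must be non-negative")
        for name, value in self.__dict__.items():
            if name != "transpiration_umol_m2_s" and value <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    @classmethod
    def from_practical(cls, transpiration_umol_m2_s: float, leaf_area_m2: float,
                       latent_heat_j_mol: float, air_density_kg_m3: float,
                       inlet_flow_lpm: float,
                       heat_capacity_j_kg_k: float) -> "EnergyBalanceInputs":
        return cls(transpiration_umol_m2_s, leaf_area_m2, latent_heat_j_mol,
                   air_density_kg_m3, lpm_to_m3s(inlet_flow_lpm),
                   heat_capacity_j_kg_k)


def saturation_vapor_pressure(temperature_k: float) -> float:
    """Saturation vapor pressure over water, Pa (Magnus correlation).

    e_s = 610.94 · exp(17.625·t / (t + 243.04)), t in °C.
    Valid for 233 K < T < 333 K.
    """
    if not 233.0 < temperature_k < 333.0:
        raise RangeError("temperature outside Magnus correlation range (233-333 K)")
    t_c = temperature_k - 273.15
    return _MAGNUS_A * math.exp(_MAGNUS_B * t_c / (t_c + _MAGNUS_C))


def absolute_humidity(state: PsychrometricState) -> float:
    """Water vapor molar concentration, mol·m⁻³ (ideal gas)."""
    e = state.relative_humidity * saturation_vapor_pressure(state.temperature_k)
    return e / (R_GAS * state.temperature_k)


def air_density(state: PsychrometricState) -> float:
    """Moist-air density, kg·m⁻³, from the two-component ideal gas model."""
    e = state.relative_humidity * saturation_vapor_pressure(state.temperature_k)
    p_dry = state.pressure_pa - e
    return (p_dry / (R_DRY_AIR * state.temperature_k)
            + e / (R_WATER_VAPOR * state.temperature_k))


def moist_air_cp(state: PsychrometricState) -> float:
    """Specific heat of moist air, J·kg⁻¹·K⁻¹: (c_pd + w·c_pv)/(1 + w)."""
    e = state.relative_humidity * saturation_vapor_pressure(state.temperature_k)
    w = 0.622 * e / (state.pressure_pa - e)  # mixing ratio kg/kg dry air
    return (CP_DRY_AIR + w * CP_WATER_VAPOR) / (1.0 + w)


def latent_heat_vaporization(temperature_k: float) -> float:
    """Molar enthalpy of vaporization of water, J·mol⁻¹.

    Clausius–Clapeyron applied to the Magnus correlation:
    H_v = R·T²·d ln e_s/dT, with the logarithmic derivative evaluated
    analytically (B·C / (t + C)², t in °C).
    """
    if not 273.0 <= temperature_k <= 373.15:
        raise RangeError("temperature outside supported range (273-373 K)")
    t_c = temperature_k - 273.15
    dlnes_dt = _MAGNUS_B * _MAGNUS_C / (t_c + _MAGNUS_C) ** 2
    return R_GAS * temperature_k ** 2 * dlnes_dt


def net_co2_assimilation(co2_in_umol_mol, co2_out_umol_mol,
                         inlet_flow_lpm: float, leaf_area_m2: float,
                         state: PsychrometricState):
    """Net CO₂ assimilation A, µmol·m⁻²·s⁻¹ (uptake positive).

    A = molar_flow · (χ_in − χ_out) / A_leaf with the molar air flow from
    the ideal gas law at the cuvette temperature and pressure.
    """
    if leaf_area_m2 <= 0:
        raise InvalidParameterError(
            "leaf area must be positive (non-plant cuvette?)")
    if inlet_flow_lpm <= 0:
        raise InvalidParameterError("inlet flow must be positive")
    mol_flow = (lpm_to_m3s(inlet_flow_lpm) * state.pressure_pa
                / (R_GAS * state.temperature_k))
    delta = np.asarray(co2_in_umol_mol, float) - np.asarray(co2_out_umol_mol, float)
    result = mol_flow * delta / leaf_area_m2
    return result if result.ndim else float(result)


def transpiration_rate(h_in_mol_m3, h_out_mol_m3,
                       inlet_flow_lpm: float, leaf_area_m2: float):
    """Transpiration E_s, mmol·m⁻²·s⁻¹ (release positive).

    E_s = F_in · (h_out − h_in) / A_leaf, the water-vapor mirror of the
    steady-state VOC emission formula.
    """
    if leaf_area_m2 <= 0:
        raise InvalidParameterError(
            "leaf area must be positive (non-plant cuvette?)")
    if inlet_flow_lpm <= 0:
        raise InvalidParameterError("inlet flow must be positive")
    delta = np.asarray(h_out_mol_m3, float) - np.asarray(h_in_mol_m3, float)
    result = lpm_to_m3s(inlet_flow_lpm) * delta / leaf_area_m2 * 1.0e3
    return result if result.ndim else float(result)


def soil_reference_correct(plant_out: ConcentrationSeries,
                           soil_out: ConcentrationSeries,
                           inlet: ConcentrationSeries) -> ConcentrationSeries:
    """Remove the bare-soil contribution from a plant-cuvette outlet series.

    corrected_out = plant_out − (soil_out − inlet): the soil cuvette's
    excess over the inlet estimates soil respiration/evaporation, which is
    subtracted from the plant outlet concentrations before fluxes are
    computed.  Soil and inlet series are linearly interpolated onto the
    plant timestamps.
    """
    t = plant_out.timestamps
    for other, name in ((soil_out, "soil"), (inlet, "inlet")):
        if other.timestamps[-1] < t[0] or other.timestamps[0] > t[-1]:
            raise AlignmentError(f"{name} series does not overlap the plant series")
    soil = soil_out.interp(t)
    base = inlet.interp(t)
    return plant_out.replace_values(plant_out.values - (soil - base))


def evaporative_delta_t(inputs: EnergyBalanceInputs) -> float:
    """Steady-state air cooling ΔT = E_s·A·H_v / (ρ_air·F_in·c_p), K.

    The energy withdrawn from the through-flowing air to vaporize the
    transpired water, per unit heat capacity of that air stream.
    """
    numerator = (inputs.transpiration_umol_m2_s * 1.0e-6
                 * inputs.leaf_area_m2 * inputs.latent_heat_j_mol)
    denominator = (inputs.air_density_kg_m3 * inputs.inlet_flow_m3_s
                   * inputs.heat_capacity_j_kg_k)
    return numerator / denominator
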