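"""Synthetic multi-cuvette experiment generator with known ground truth.

Emulates the full measurement chain of a 24-cuvette screening platform:
per-cuvette outlet concentrations are produced by the forward cuvette
model from configured true emission/assimilation/transpiration profiles
(plus bare-soil efflux and a slow contaminant drift shared by all
cuvettes), interleaved according to the valve-multiplexing schedule, and
optionally degraded with i.i.d. Gaussian channel noise.  The ground-truth
rates at every grid time are returned alongside, so every pipeline stage
can be tested for parameter recovery without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .cuvette import (
    ConcentrationSeries,
    CuvetteConfig,
    CuvetteRole,
    EmissionProfile,
    simulate_concentration,
)
from .errors import InvalidParameterError
from .signals import MultiplexedLog, ValveSchedule
from .units import SECONDS_PER_DAY, lpm_to_m3s

__all__ = [
    "CHANNEL_CO2",
    "CHANNEL_H2O",
    "ExperimentSpec",
    "SyntheticExperiment",
    "default_cuvettes",
    "generate_experiment",
    "generate_plant_image",
]

CHANNEL_CO2 = "co2_ppm"
CHANNEL_H2O = "h2o_molm3"


def default_cuvettes(n_plant: int = 18, n_background: int = 3, n_soil: int = 3,
                     volume_l: float = 40.0, inlet_flow_lpm: float = 6.0,
                     leaf_area_m2: float = 0.05) -> Tuple[CuvetteConfig, ...]:
    """Standard platform layout: plants, empty-background and bare-soil pots."""
    cuvettes = []
    i = 1
    for _ in range(n_plant):
        cuvettes.append(CuvetteConfig(f"c{i:02d}", volume_l, inlet_flow_lpm,
                                      CuvetteRole.PLANT, leaf_area_m2))
        i += 1
    for _ in range(n_background):
        cuvettes.append(CuvetteConfig(f"c{i:02d}", volume_l, inlet_flow_lpm,
                                      CuvetteRole.EMPTY_BACKGROUND))
        i += 1
    for _ in range(n_soil):
        cuvettes.append(CuvetteConfig(f"c{i:02d}", volume_l, inlet_flow_lpm,
                                      CuvetteRole.SOIL_REFERENCE))
        i += 1
    return tuple(cuvettes)


@dataclass(frozen=True)
class ExperimentSpec:
    """Complete description of a synthetic screening experiment.

    Plant rates follow either a half-sine over the light phase
    (``profile_shape='diurnal'``; zero in the dark) or a constant
    (``'constant'``, the peak value held).  Soil efflux is a constant
    whole-cuvette source present in soil-reference *and* plant cuvettes
    (pots are not sealed).  The contaminant drift, shared by every
    cuvette on the VOC channel, is a cubic polynomial in time so that the
    spline background correction has an exact-recovery regime.
    """

    cuvettes: Tuple[CuvetteConfig, ...] = field(default_factory=default_cuvettes)
    dwell_s: float = 300.0
    lag_s: float = 30.0
    duration_s: float = SECONDS_PER_DAY
    sample_period_s: float = 10.0
    inlet_period_s: float = 60.0
    compound_id: str = "voc1"
    profile_shape: str = "diurnal"          # 'diurnal' or 'constant'
    voc_peak_nmol_m2_s: float = 1.0
    assim_peak_umol_m2_s: float = 10.0
    transp_peak_mmol_m2_s: float = 1.5
    light_on_s: float = 6 * 3600.0
    light_off_s: float = 18 * 3600.0
    soil_co2_efflux_umol_s: float = 0.05
    soil_h2o_efflux_mmol_s: float = 0.02
    contaminant_poly_nmol_m3: Tuple[float, ...] = (20.0, 4.0, -1.5, 0.25)
    co2_inlet_ppm: float = 400.0
    h2o_inlet_molm3: float = 0.8
    temperature_k: float = 298.15
    pressure_pa: float = 96000.0
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_shape not in ("diurnal", "constant"):
            raise InvalidParameterError("profile_shape must be 'diurnal' or 'constant'")
        if self.duration_s <= 0 or self.sample_period_s <= 0:
            raise InvalidParameterError("duration and sample period must be positive")
        object.__setattr__(self, "noise_sd", dict(self.noise_sd))

    @property
    def schedule(self) -> ValveSchedule:
        return ValveSchedule(tuple(c.cuvette_id for c in self.cuvettes),
                             dwell_s=self.dwell_s, lag_s=self.lag_s)

    def rate_profile(self, peak: float) -> EmissionProfile:
        if self.profile_shape == "constant":
            return EmissionProfile.constant(self.compound_id, peak)
        return EmissionProfile.diurnal_sine(self.compound_id, peak,
                                            self.light_on_s, self.light_off_s)

    def contaminant(self, t: np.ndarray) -> np.ndarray:
        x = np.asarray(t, float) / SECONDS_PER_DAY
        return sum(c * x ** k for k, c in enumerate(self.contaminant_poly_nmol_m3))


@dataclass
class SyntheticExperiment:
    """Generated experiment: raw log, inlet table, and ground truth."""

    spec: ExperimentSpec
    log: MultiplexedLog
    inlet: pd.DataFrame            # time_s, channel, value (inlet analyzer)
    truth: pd.DataFrame            # time_s, cuvette_id, true rates
    outlet_grids: Dict[str, Dict[str, ConcentrationSeries]]  # noiseless, full grid

    def inlet_series(self, channel: str) -> ConcentrationSeries:
        rows = self.inlet[self.inlet["channel"] == channel]
        return ConcentrationSeries("inlet", channel,
                                   rows["time_s"].to_numpy(float),
                                   rows["value"].to_numpy(float))


def generate_experiment(spec: ExperimentSpec) -> SyntheticExperiment:
    """Run the forward model for every cuvette and multiplex the records."""
    rng = np.random.default_rng(spec.seed)
    grid = np.arange(0.0, spec.duration_s + spec.sample_period_s / 2,
                     spec.sample_period_s)
    schedule = spec.schedule

    mol_flow = {}  # mol/s of air per cuvette
    for c in spec.cuvettes:
        mol_flow[c.cuvette_id] = (lpm_to_m3s(c.inlet_flow_lpm) * spec.pressure_pa
                                  / (8.314462618 * spec.temperature_k))

    contaminant = spec.contaminant(grid)
    voc_profile = spec.rate_profile(spec.voc_peak_nmol_m2_s)
    assim_profile = spec.rate_profile(spec.assim_peak_umol_m2_s)
    transp_profile = spec.rate_profile(spec.transp_peak_mmol_m2_s)

    outlet: Dict[str, Dict[str, ConcentrationSeries]] = {}
    truth_rows = []
    for c in spec.cuvettes:
        flow_m3s = lpm_to_m3s(c.inlet_flow_lpm)
        channels: Dict[str, np.ndarray] = {}

        if c.role is CuvetteRole.PLANT:
            plant_voc = simulate_concentration(c, voc_profile, 0.0, grid)
            channels[spec.compound_id] = plant_voc.values + contaminant
            assim = np.asarray(assim_profile.evaluate(grid), float)
            transp = np.asarray(transp_profile.evaluate(grid), float)
            # quasi-static CO2/H2O: tau (minutes) << diurnal timescale
            co2 = (spec.co2_inlet_ppm
                   - assim * c.leaf_area_m2 / mol_flow[c.cuvette_id]
                   + spec.soil_co2_efflux_umol_s / mol_flow[c.cuvette_id])
            h2o = (spec.h2o_inlet_molm3
                   + (transp * c.leaf_area_m2 + spec.soil_h2o_efflux_mmol_s)
                   * 1.0e-3 / flow_m3s)
            channels[CHANNEL_CO2] = co2
            channels[CHANNEL_H2O] = h2o
            truth_rows.append(pd.DataFrame({
                "time_s": grid,
                "cuvette_id": c.cuvette_id,
                "emission_nmol_m2_s": np.asarray(voc_profile.evaluate(grid), float),
                "assimilation_umol_m2_s": assim,
                "transpiration_mmol_m2_s": transp,
            }))
        elif c.role is CuvetteRole.SOIL_REFERENCE:
            channels[spec.compound_id] = contaminant.copy()
            channels[CHANNEL_CO2] = np.full_like(
                grid, spec.co2_inlet_ppm
                + spec.soil_co2_efflux_umol_s / mol_flow[c.cuvette_id])
            channels[CHANNEL_H2O] = np.full_like(
                grid, spec.h2o_inlet_molm3
                + spec.soil_h2o_efflux_mmol_s * 1.0e-3 / flow_m3s)
        else:  # empty background
            channels[spec.compound_id] = contaminant.copy()
            channels[CHANNEL_CO2] = np.full_like(grid, spec.co2_inlet_ppm)
            channels[CHANNEL_H2O] = np.full_like(grid, spec.h2o_inlet_molm3)

        outlet[c.cuvette_id] = {
            name: ConcentrationSeries(c.cuvette_id, name, grid, values)
            for name, values in channels.items()}

    # interleave: the downstream analyzers only see the active cuvette
    active = schedule.active_at(grid)
    channel_names = [spec.compound_id, CHANNEL_CO2, CHANNEL_H2O]
    frames = []
    for name in channel_names:
        values = np.empty_like(grid)
        for cid in schedule.cuvette_order:
            mask = active == cid
            values[mask] = outlet[cid][name].values[mask]
        sd = spec.noise_sd.get(name, 0.0)
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=values.shape)
        frames.append(pd.DataFrame({"time_s": grid, "active_cuvette": active,
                                    "channel": name, "value": values}))
    records = (pd.concat(frames, ignore_index=True)
               .sort_values(["time_s", "channel"], kind="stable")
               .reset_index(drop=True))

    inlet_t = np.arange(0.0, spec.duration_s + spec.inlet_period_s / 2,
                        spec.inlet_period_s)
    inlet = pd.concat([
        pd.DataFrame({"time_s": inlet_t, "channel": spec.compound_id, "value": 0.0}),
        pd.DataFrame({"time_s": inlet_t, "channel": CHANNEL_CO2,
                      "value": spec.co2_inlet_ppm}),
        pd.DataFrame({"time_s": inlet_t, "channel": CHANNEL_H2O,
                      "value": spec.h2o_inlet_molm3}),
    ], ignore_index=True)

    truth = (pd.concat(truth_rows, ignore_index=True) if truth_rows
             else pd.DataFrame(columns=["time_s", "cuvette_id",
                                        "emission_nmol_m2_s",
                                        "assimilation_umol_m2_s",
                                        "transpiration_mmol_m2_s"]))
    return SyntheticExperiment(spec=spec, log=MultiplexedLog(records),
                               inlet=inlet, truth=truth, outlet_grids=outlet)


_BACKGROUND_RGB = (20, 30, 220)   # blue backdrop
_PLANT_RGB = (30, 200, 40)        # foliage green, hue ~124 deg


def generate_plant_image(n_green: int, width: int, height: int,
                         seed: int = 0) -> Tuple[np.ndarray, int]:
    """Uniform blue image with exactly ``n_green`` green pixels.

    Positions are drawn without replacement from a seeded RNG; the same
    seed reproduces the image bit-for-bit.  Returns (image, truth count).
    """
    if n_green < 0 or n_green > width * height:
        raise InvalidParameterError("n_green must be in [0, width*height]")
    rng = np.random.default_rng(seed)
    image = np.empty((height, width, 3), dtype=np.uint8)
    image[:, :] = _BACKGROUND_RGB
    flat = rng.choice(width * height, size=n_green, replace=False)
    rows, cols = np.unravel_index(flat, (height, width))
    image[rows, cols] = _PLANT_RGB
    return image, int(n_green)
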