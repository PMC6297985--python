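"""End-to-end processing: raw multiplexed log → leaf-area-normalized rates.

The chain is: demultiplex and lag-discard → empty-cuvette spline
background correction of the VOC channels → steady-state and dynamic
emission-rate inversion → bare-soil reference correction of CO₂ and H₂O →
net assimilation and transpiration — everything normalized to the
(possibly time-interpolated) leaf area of each plant cuvette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .cuvette import (
    ConcentrationSeries,
    CuvetteConfig,
    CuvetteRole,
    dynamic_emission,
)
from .errors import ConfigurationError
from .gasexchange import soil_reference_correct
from .leafarea import LeafAreaTimeline
from .signals import (
    DemuxResult,
    MultiplexedLog,
    ValveSchedule,
    background_correct,
    demultiplex,
)
from .synth import CHANNEL_CO2, CHANNEL_H2O, ExperimentSpec
from .units import R_GAS, SECONDS_PER_DAY, lpm_to_m3s

logger = logging.getLogger(__name__)

NON_VOC_CHANNELS = {CHANNEL_CO2, CHANNEL_H2O, "temp_c", "rh"}

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated configuration of one processing run."""

    cuvettes: Dict[str, CuvetteConfig]
    schedule: ValveSchedule
    pressure_pa: float = 96000.0
    temperature_k: float = 298.15
    background_ids: Tuple[str, ...] = ()
    soil_reference_ids: Tuple[str, ...] = ()
    leaf_area_timelines: Dict[str, LeafAreaTimeline] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.schedule.cuvette_order:
            if cid not in self.cuvettes:
                raise ConfigurationError(
                    f"schedule references unknown cuvette {cid!r}")
        for cid in self.background_ids:
            cfg = self._require(cid, "background_cuvettes")
            if cfg.role is not CuvetteRole.EMPTY_BACKGROUND:
                raise ConfigurationError(
                    f"background cuvette {cid!r} has role {cfg.role.value!r}, "
                    "expected 'empty_background'")
        for cid in self.soil_reference_ids:
            cfg = self._require(cid, "soil_reference_cuvettes")
            if cfg.role is not CuvetteRole.SOIL_REFERENCE:
                raise ConfigurationError(
                    f"soil reference cuvette {cid!r} has role {cfg.role.value!r}, "
                    "expected 'soil_reference'")

    def _require(self, cid: str, context: str) -> CuvetteConfig:
        if cid not in self.cuvettes:
            raise ConfigurationError(f"{context}: unknown cuvette {cid!r}")
        return self.cuvettes[cid]

    @classmethod
    def from_experiment_spec(cls, spec: ExperimentSpec) -> "PipelineConfig":
        """Configuration matching a :class:`~vocscreen.synth.ExperimentSpec`."""
        cuvettes = {c.cuvette_id: c for c in spec.cuvettes}
        return cls(
            cuvettes=cuvettes,
            schedule=spec.schedule,
            pressure_pa=spec.pressure_pa,
            temperature_k=spec.temperature_k,
            background_ids=tuple(c.cuvette_id for c in spec.cuvettes
                                 if c.role is CuvetteRole.EMPTY_BACKGROUND),
            soil_reference_ids=tuple(c.cuvette_id for c in spec.cuvettes
                                     if c.role is CuvetteRole.SOIL_REFERENCE),
        )

    def leaf_area_at(self, cuvette_id: str, times_s: np.ndarray) -> np.ndarray:
        """Leaf area (m²) per timestamp: spline timeline or the static value."""
        timeline = self.leaf_area_timelines.get(cuvette_id)
        if timeline is None:
            return np.full_like(np.asarray(times_s, float),
                                self.cuvettes[cuvette_id].leaf_area_m2)
        return np.asarray(timeline.area_at(np.asarray(times_s, float)
                                           / SECONDS_PER_DAY), float)


@dataclass
class PipelineResult:
    """Rates tables plus a machine-readable run report."""

    voc_rates: pd.DataFrame
    gas_rates: pd.DataFrame
    report: Dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.voc_rates.to_csv(outdir / "voc_rates.tsv", sep="\t", index=False)
        self.gas_rates.to_csv(outdir / "gas_rates.tsv", sep="\t", index=False)
        vio.write_manifest(self.report, outdir / "run_report.json")


def _mean_series(series_list: Sequence[ConcentrationSeries],
                 timestamps: np.ndarray, cuvette_id: str,
                 compound_id: str) -> ConcentrationSeries:
    stacked = np.vstack([s.interp(timestamps) for s in series_list])
    return ConcentrationSeries(cuvette_id, compound_id, timestamps,
                               stacked.mean(axis=0))


def _inlet_channel(inlet: Optional[pd.DataFrame],
                   channel: str) -> Optional[ConcentrationSeries]:
    if inlet is None:
        return None
    rows = inlet[inlet["channel"] == channel].sort_values("time_s", kind="stable")
    if rows.empty:
        return None
    return ConcentrationSeries("inlet", channel, rows["time_s"].to_numpy(float),
                               rows["value"].to_numpy(float))


def run_pipeline(config: PipelineConfig, log: MultiplexedLog,
                 inlet: Optional[pd.DataFrame] = None) -> PipelineResult:
    """Process one experiment and return normalized rate tables.

    VOC channels are every channel not recognized as CO₂/H₂O/housekeeping;
    their inlet concentration defaults to 0 when absent from the inlet
    table.  Gas-exchange rates are computed only when both the CO₂ and H₂O
    channels and their inlet series are available.
    """
    warnings: List[str] = []
    demux = demultiplex(log, config.schedule)
    channels = log.channels
    voc_channels = [c for c in channels if c not in NON_VOC_CHANNELS]
    plant_ids = [cid for cid in config.schedule.cuvette_order
                 if config.cuvettes[cid].role is CuvetteRole.PLANT]
    if not plant_ids:
        warnings.append("no plant cuvettes configured; rates tables are empty")

    max_gap = 2.0 * config.schedule.cycle_s
    voc_frames: List[pd.DataFrame] = []
    gas_frames: List[pd.DataFrame] = []

    for cid in plant_ids:
        cfg = config.cuvettes[cid]
        unit_cfg = replace(cfg, leaf_area_m2=1.0)  # normalize to area afterwards
        flow_m3s = lpm_to_m3s(cfg.inlet_flow_lpm)

        for channel in voc_channels:
            if channel not in demux.series[cid]:
                continue
            target = demux.series[cid][channel]
            if config.background_ids:
                backgrounds = [demux.series[b][channel]
                               for b in config.background_ids
                               if channel in demux.series[b]]
                if not backgrounds:
                    raise ConfigurationError(
                        f"no background data for channel {channel!r} "
                        f"(cuvettes {config.background_ids})")
                corrected = background_correct(target, backgrounds,
                                               max_gap_s=max_gap)
            else:
                corrected = target
            inlet_series = _inlet_channel(inlet, channel)
            c_in = (inlet_series.interp(corrected.timestamps)
                    if inlet_series is not None else 0.0)
            area = config.leaf_area_at(cid, corrected.timestamps)
            emission_ss = flow_m3s * (corrected.values - c_in) / area
            dyn_total = dynamic_emission(
                corrected, inlet_series if inlet_series is not None else 0.0,
                unit_cfg)
            voc_frames.append(pd.DataFrame({
                "cuvette_id": cid,
                "compound_id": channel,
                "time_s": corrected.timestamps,
                "leaf_area_m2": area,
                "emission_ss_nmol_m2_s": emission_ss,
                "emission_dyn_nmol_m2_s": dyn_total.values / area,
            }))

        co2_ok = CHANNEL_CO2 in demux.series[cid]
        h2o_ok = CHANNEL_H2O in demux.series[cid]
        co2_in = _inlet_channel(inlet, CHANNEL_CO2)
        h2o_in = _inlet_channel(inlet, CHANNEL_H2O)
        if co2_ok and h2o_ok and co2_in is not None and h2o_in is not None:
            co2_out = demux.series[cid][CHANNEL_CO2]
            h2o_out = demux.series[cid][CHANNEL_H2O]
            if config.soil_reference_ids:
                soil_co2 = _mean_series(
                    [demux.series[s][CHANNEL_CO2] for s in config.soil_reference_ids],
                    co2_out.timestamps, "soil", CHANNEL_CO2)
                soil_h2o = _mean_series(
                    [demux.series[s][CHANNEL_H2O] for s in config.soil_reference_ids],
                    h2o_out.timestamps, "soil", CHANNEL_H2O)
                co2_out = soil_reference_correct(co2_out, soil_co2, co2_in)
                h2o_out = soil_reference_correct(h2o_out, soil_h2o, h2o_in)
            mol_flow = flow_m3s * config.pressure_pa / (R_GAS * config.temperature_k)
            area = config.leaf_area_at(cid, co2_out.timestamps)
            assim = (mol_flow
                     * (co2_in.interp(co2_out.timestamps) - co2_out.values) / area)
            area_h = config.leaf_area_at(cid, h2o_out.timestamps)
            transp = (flow_m3s
                      * (h2o_out.values - h2o_in.interp(h2o_out.timestamps))
                      / area_h * 1.0e3)
            gas_frames.append(pd.DataFrame({
                "cuvette_id": cid,
                "time_s": co2_out.timestamps,
                "leaf_area_m2": area,
                "assimilation_umol_m2_s": assim,
                "transpiration_mmol_m2_s": np.interp(
                    co2_out.timestamps, h2o_out.timestamps, transp),
            }))

    voc_rates = (pd.concat(voc_frames, ignore_index=True) if voc_frames
                 else pd.DataFrame(columns=["cuvette_id", "compound_id", "time_s",
                                            "leaf_area_m2", "emission_ss_nmol_m2_s",
                                            "emission_dyn_nmol_m2_s"]))
    gas_rates = (pd.concat(gas_frames, ignore_index=True) if gas_frames
                 else pd.DataFrame(columns=["cuvette_id", "time_s", "leaf_area_m2",
                                            "assimilation_umol_m2_s",
                                            "transpiration_mmol_m2_s"]))
    for message in warnings:
        logger.warning(message)
    report = {
        "n_records": len(log),
        "n_kept": demux.n_kept,
        "n_discarded": demux.n_discarded,
        "discarded_by_channel": demux.discarded_by_channel,
        "channels": channels,
        "voc_channels": voc_channels,
        "plant_cuvettes": plant_ids,
        "background_cuvettes": list(config.background_ids),
        "soil_reference_cuvettes": list(config.soil_reference_ids),
        "pressure_pa": config.pressure_pa,
        "temperature_k": config.temperature_k,
        "schedule": {"dwell_s": config.schedule.dwell_s,
                     "lag_s": config.schedule.lag_s,
                     "cycle_s": config.schedule.cycle_s},
        "warnings": warnings,
    }
    return PipelineResult(voc_rates=voc_rates, gas_rates=gas_rates, report=report)


def _config_error(path, key, message) -> ConfigurationError:
    return ConfigurationError(f"{path}: {key}: {message}")


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Expected layout::

        pressure_pa: 96000
        temperature_k: 298.15
        schedule: {dwell_s: 300, lag_s: 30, start_time_s: 0}
        cuvettes:
          c01: {volume_l: 40, inlet_flow_lpm: 6, role: plant, leaf_area_m2: 0.05}
        background_cuvettes: [c19]
        soil_reference_cuvettes: [c22]
        leaf_area_timelines:
          c01: {times_days: [0, 7], areas_m2: [0.05, 0.061]}

    The valve order defaults to the cuvette listing order.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    if "cuvettes" not in raw or not isinstance(raw["cuvettes"], dict):
        raise _config_error(path, "cuvettes", "required mapping is missing")

    cuvettes: Dict[str, CuvetteConfig] = {}
    for cid, entry in raw["cuvettes"].items():
        if not isinstance(entry, dict):
            raise _config_error(path, f"cuvettes.{cid}", "must be a mapping")
        try:
            cuvettes[str(cid)] = CuvetteConfig(
                cuvette_id=str(cid),
                volume_l=float(entry["volume_l"]),
                inlet_flow_lpm=float(entry["inlet_flow_lpm"]),
                role=CuvetteRole(entry.get("role", "plant")),
                leaf_area_m2=float(entry.get("leaf_area_m2", 0.0)),
            )
        except KeyError as exc:
            raise _config_error(path, f"cuvettes.{cid}",
                                f"missing field {exc}") from exc
        except ValueError as exc:
            raise _config_error(path, f"cuvettes.{cid}", str(exc)) from exc

    sched = raw.get("schedule", {})
    order = tuple(str(c) for c in sched.get("order", list(cuvettes)))
    schedule = ValveSchedule(order,
                             dwell_s=float(sched.get("dwell_s", 300.0)),
                             lag_s=float(sched.get("lag_s", 30.0)),
                             start_time_s=float(sched.get("start_time_s", 0.0)))

    timelines: Dict[str, LeafAreaTimeline] = {}
    for cid, entry in (raw.get("leaf_area_timelines") or {}).items():
        try:
            timelines[str(cid)] = LeafAreaTimeline(entry["times_days"],
                                                   entry["areas_m2"])
        except (KeyError, TypeError) as exc:
            raise _config_error(path, f"leaf_area_timelines.{cid}",
                                "needs times_days and areas_m2 lists") from exc

    return PipelineConfig(
        cuvettes=cuvettes,
        schedule=schedule,
        pressure_pa=float(raw.get("pressure_pa", 96000.0)),
        temperature_k=float(raw.get("temperature_k", 298.15)),
        background_ids=tuple(str(c) for c in raw.get("background_cuvettes", [])),
        soil_reference_ids=tuple(str(c)
                                 for c in raw.get("soil_reference_cuvettes", [])),
        leaf_area_timelines=timelines,
    )
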