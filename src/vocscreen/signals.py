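"""Demultiplexing and background correction of valve-switched sensor logs.

A single downstream analyzer samples air from many cuvettes sequentially
(2-way valves, typically 5 min per cuvette).  This module splits the
interleaved log into per-cuvette series, discards records acquired within
the tubing lag time after each valve switch, and removes the system
contaminant background measured in empty cuvettes via cubic-spline
interpolation over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cuvette import ConcentrationSeries
from .errors import (
    AlignmentError,
    ConfigurationError,
    InputError,
    InvalidParameterError,
    SchemaError,
)

logger = logging.getLogger(__name__)

LOG_COLUMNS = ("time_s", "active_cuvette", "channel", "value")

__all__ = [
    "ValveSchedule",
    "MultiplexedLog",
    "DemuxResult",
    "demultiplex",
    "background_correct",
    "AlignedPair",
    "align_pair",
]


@dataclass(frozen=True)
class ValveSchedule:
    """Round-robin multiplexing schedule.

    ``dwell_s`` seconds are spent on each cuvette in ``cuvette_order``;
    the first ``lag_s`` seconds after each switch are discarded (gas
    exchange time of the tubing between cuvette outlet and analyzer).
    """

    cuvette_order: Tuple[str, ...]
    dwell_s: float = 300.0
    lag_s: float = 30.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cuvette_order", tuple(self.cuvette_order))
        if not self.cuvette_order:
            raise InvalidParameterError("cuvette order must be non-empty")
        if len(set(self.cuvette_order)) != len(self.cuvette_order):
            raise InvalidParameterError("cuvette ids must be unique")
        if not self.dwell_s > self.lag_s >= 0:
            raise InvalidParameterError("require dwell > lag >= 0")

    @property
    def cycle_s(self) -> float:
        """Time between consecutive visits to the same cuvette."""
        return self.dwell_s * len(self.cuvette_order)

    def active_at(self, t: np.ndarray) -> np.ndarray:
        """Nominal active cuvette id at time(s) ``t``."""
        idx = (np.floor_divide(np.asarray(t, float) - self.start_time_s,
                               self.dwell_s).astype(int)
               % len(self.cuvette_order))
        return np.asarray(self.cuvette_order, dtype=object)[idx]


@dataclass
class MultiplexedLog:
    """Raw interleaved sensor records with active-valve annotation."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"multiplexed log missing columns: {missing}")
        times = self.records["time_s"].to_numpy(float)
        if len(times) and np.any(np.diff(times) < 0):
            self.records = self.records.sort_values("time_s", kind="stable")
            self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def channels(self) -> List[str]:
        return sorted(self.records["channel"].unique())


@dataclass
class DemuxResult:
    """Per-cuvette, per-channel series plus discard bookkeeping."""

    series: Dict[str, Dict[str, ConcentrationSeries]]
    n_kept: int
    n_discarded: int
    discarded_by_channel: Dict[str, int] = field(default_factory=dict)

    def get(self, cuvette_id: str, channel: str) -> ConcentrationSeries:
        return self.series[cuvette_id][channel]


def demultiplex(log: MultiplexedLog, schedule: ValveSchedule) -> DemuxResult:
    """Split a multiplexed log into per-cuvette series, discarding lag records.

    Valve switch times are reconstructed from changes of the
    ``active_cuvette`` column (time-ordered); every record acquired before
    ``switch_time + lag`` is discarded, all others are partitioned by
    active cuvette and channel.  Every input record ends up either kept or
    discarded.
    """
    df = log.records
    known = set(schedule.cuvette_order)
    present = set(df["active_cuvette"].unique())
    unknown = present - known
    if unknown:
        raise SchemaError(f"log references cuvettes not in schedule: {sorted(unknown)}")

    times = df["time_s"].to_numpy(float)
    active = df["active_cuvette"].to_numpy(object)

    # contiguous blocks of constant active cuvette = dwell windows
    if len(df):
        new_block = np.empty(len(df), dtype=bool)
        new_block[0] = True
        new_block[1:] = active[1:] != active[:-1]
        block_id = np.cumsum(new_block) - 1
        switch_times = times[new_block][block_id]
        keep = times >= switch_times + schedule.lag_s
    else:
        keep = np.zeros(0, dtype=bool)

    kept = df.loc[keep]
    discarded = df.loc[~keep]
    by_channel = discarded.groupby("channel").size().to_dict()

    series: Dict[str, Dict[str, ConcentrationSeries]] = {
        cid: {} for cid in schedule.cuvette_order}
    for (cid, channel), group in kept.groupby(["active_cuvette", "channel"],
                                              sort=True):
        t = group["time_s"].to_numpy(float)
        v = group["value"].to_numpy(float)
        # guard against duplicate timestamps within one channel
        t_unique, first_idx = np.unique(t, return_index=True)
        series[cid][channel] = ConcentrationSeries(cid, channel, t_unique,
                                                   v[first_idx])
    return DemuxResult(series=series, n_kept=int(keep.sum()),
                       n_discarded=int((~keep).sum()),
                       discarded_by_channel=by_channel)


def _pool_background_points(
        backgrounds: Sequence[ConcentrationSeries]) -> Tuple[np.ndarray, np.ndarray]:
    """Merge background series, averaging values at shared timestamps."""
    t = np.concatenate([b.timestamps for b in backgrounds])
    v = np.concatenate([b.values for b in backgrounds])
    t_unique, inverse = np.unique(t, return_inverse=True)
    sums = np.bincount(inverse, weights=v)
    counts = np.bincount(inverse)
    return t_unique, sums / counts


def background_correct(
    target: ConcentrationSeries,
    backgrounds: Sequence[ConcentrationSeries],
    bc_type: str = "not-a-knot",
    max_gap_s: float | None = None,
) -> ConcentrationSeries:
    """Subtract the spline-interpolated empty-cuvette background.

    Background samples from all supplied series are pooled (averaged at
    shared timestamps), fitted with a cubic spline over time, evaluated at
    the target's timestamps and subtracted.  Evaluation beyond the
    background's time range is suppressed: the endpoint values are held,
    and a warning is logged when the uncovered stretch exceeds
    ``max_gap_s`` (typically two multiplex cycles).

    The default ``not-a-knot`` boundary condition reproduces polynomial
    backgrounds up to degree 3 exactly; pass ``bc_type='natural'`` for a
    natural spline.  Negative corrected values are retained (clipping
    would bias downstream rate averages) and counted in a log message.
    """
    backgrounds = list(backgrounds)
    if not backgrounds:
        raise ConfigurationError("background correction requires >= 1 background series")

    bg_t, bg_v = _pool_background_points(backgrounds)
    query = np.clip(target.timestamps, bg_t[0], bg_t[-1])

    gap = max(bg_t[0] - target.timestamps[0], target.timestamps[-1] - bg_t[-1], 0.0)
    if max_gap_s is not None and gap > max_gap_s:
        logger.warning(
            "background coverage gap of %.0f s exceeds %.0f s; endpoint values held",
            gap, max_gap_s)

    if len(bg_t) >= 4:
        bg_eval = CubicSpline(bg_t, bg_v, bc_type=bc_type)(query)
    elif len(bg_t) >= 2:
        bg_eval = np.interp(query, bg_t, bg_v)
    else:
        bg_eval = np.full_like(query, bg_v[0])

    corrected = target.values - bg_eval
    n_negative = int(np.sum(corrected < 0))
    if n_negative:
        logger.info("background correction produced %d negative values (retained)",
                    n_negative)
    return target.replace_values(corrected)


@dataclass
class AlignedPair:
    """Outlet/inlet values on the outlet time base."""

    timestamps: np.ndarray
    outlet_values: np.ndarray
    inlet_values: np.ndarray
    clipped: np.ndarray  # True where the inlet value was held at an endpoint


def align_pair(outlet: ConcentrationSeries,
               inlet: ConcentrationSeries) -> AlignedPair:
    """Linearly interpolate the inlet series onto the outlet timestamps.

    No extrapolation: outlet timestamps outside the inlet range receive
    the nearest endpoint value and are flagged in ``clipped``.
    """
    if len(inlet) < 2:
        raise InputError("inlet series needs at least 2 samples")
    if (inlet.timestamps[-1] < outlet.timestamps[0]
            or inlet.timestamps[0] > outlet.timestamps[-1]):
        raise AlignmentError("outlet and inlet time ranges are disjoint")
    t = outlet.timestamps
    clipped = (t < inlet.timestamps[0]) | (t > inlet.timestamps[-1])
    if clipped.any():
        logger.warning("%d outlet timestamps outside inlet range were clipped",
                       int(clipped.sum()))
    return AlignedPair(t, outlet.values.copy(), inlet.interp(t), clipped)
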