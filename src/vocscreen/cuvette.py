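"""Well-mixed flow-through cuvette model.

Forward model: the compound quantity in a cuvette of volume ``V`` flushed at
inlet flow ``F_in`` with a plant of leaf area ``A_leaf`` emitting at rate
``E(t)`` obeys the linear first-order balance

    dc/dt = E(t) * A_leaf / V + (F_in / V) * (c_in(t) - c(t))

with ``c`` the (homogeneous) concentration.  Deposition on walls and leaves
is neglected and the outlet flow is taken equal to the inlet flow.

Inverse model: at steady state ``E = (F_in / A_leaf) * (c_out - c_in)``;
away from steady state the storage term ``V * dc/dt`` is added back using a
finite-difference derivative estimate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    InputError,
    InsufficientDataError,
    InvalidParameterError,
)
from .units import lpm_to_m3s, liters_to_m3

__all__ = [
    "CuvetteRole",
    "CuvetteConfig",
    "EmissionProfile",
    "ConcentrationSeries",
    "time_constant",
    "exchange_fraction",
    "simulate_concentration",
    "steady_state_emission",
    "dynamic_emission",
]


class CuvetteRole(str, enum.Enum):
    PLANT = "plant"
    EMPTY_BACKGROUND = "empty_background"
    SOIL_REFERENCE = "soil_reference"


@dataclass(frozen=True)
class CuvetteConfig:
    """Physical and role description of one cuvette.

    Parameters
    ----------
    cuvette_id : str
        Identifier used in logs and schedules.
    volume_l : float
        Enclosed air volume in liters.
    inlet_flow_lpm : float
        Volumetric inlet flow in L·min⁻¹ (equals the outlet flow).
    role : CuvetteRole
        ``plant``, ``empty_background`` or ``soil_reference``.
    leaf_area_m2 : float
        One-sided enclosed leaf area in m²; must be 0 for non-plant roles.
    """

    cuvette_id: str
    volume_l: float
    inlet_flow_lpm: float
    role: CuvetteRole = CuvetteRole.PLANT
    leaf_area_m2: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", CuvetteRole(self.role))
        if self.volume_l <= 0:
            raise InvalidParameterError("cuvette volume must be positive")
        if self.inlet_flow_lpm <= 0:
            raise InvalidParameterError("cuvette inlet flow must be positive")
        if self.leaf_area_m2 < 0:
            raise InvalidParameterError("leaf area must be non-negative")
        if self.role is CuvetteRole.PLANT and self.leaf_area_m2 == 0:
            raise InvalidParameterError(
                f"plant cuvette {self.cuvette_id!r} requires leaf_area_m2 > 0"
            )
        if self.role is not CuvetteRole.PLANT and self.leaf_area_m2 > 0:
            raise InvalidParameterError(
                f"non-plant cuvette {self.cuvette_id!r} must have leaf_area_m2 = 0"
            )

    @property
    def tau_s(self) -> float:
        """Air-exchange time constant V/F_in in seconds."""
        return time_constant(self.volume_l, self.inlet_flow_lpm) * 60.0


@dataclass(frozen=True)
class EmissionProfile:
    """Net emission rate of one compound as a function of time.

    ``evaluate`` maps time in seconds to nmol·m⁻²·s⁻¹ (negative = uptake)
    and must accept scalars and numpy arrays alike.
    """

    compound_id: str
    evaluate: Callable[[np.ndarray], np.ndarray]
    shape: str = "custom"

    @classmethod
    def constant(cls, compound_id: str, rate: float) -> "EmissionProfile":
        return cls(compound_id, lambda t: np.full_like(np.asarray(t, float), rate),
                   shape="constant")

    @classmethod
    def step(cls, compound_id: str, amplitude: float, t_on: float,
             t_off: float = math.inf, baseline: float = 0.0) -> "EmissionProfile":
        def _eval(t):
            t = np.asarray(t, float)
            return np.where((t >= t_on) & (t < t_off), amplitude, baseline)
        return cls(compound_id, _eval, shape="step")

    @classmethod
    def diurnal_sine(cls, compound_id: str, peak: float, light_on_s: float,
                     light_off_s: float, period_s: float = 86400.0) -> "EmissionProfile":
        """Half-sine burst over the light phase, zero in the dark.

        Peaks at ``peak`` midway between ``light_on_s`` and ``light_off_s``;
        repeats with ``period_s``.
        """
        if not 0 <= light_on_s < light_off_s <= period_s:
            raise InvalidParameterError("light phase must satisfy 0 <= on < off <= period")
        span = light_off_s - light_on_s

        def _eval(t):
            t = np.mod(np.asarray(t, float), period_s)
            phase = (t - light_on_s) / span
            lit = (phase >= 0) & (phase <= 1)
            return np.where(lit, peak * np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)

        return cls(compound_id, _eval, shape="diurnal_sine")


@dataclass
class ConcentrationSeries:
    """Timestamped concentrations of one compound in one cuvette channel.

    ``timestamps`` are seconds since experiment start, strictly increasing;
    ``values`` are concentrations in nmol·m⁻³ (or the channel's native unit
    for non-VOC channels such as CO₂ mixing ratio).
    """

    cuvette_id: str
    compound_id: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.ndim != 1 or self.values.ndim != 1:
            raise InputError("timestamps and values must be one-dimensional")
        if len(self.timestamps) != len(self.values):
            raise InputError("timestamps and values must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InputError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InputError("values must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)

    def interp(self, t: np.ndarray, clip: bool = True) -> np.ndarray:
        """Linear interpolation onto ``t``; endpoints held if ``clip``."""
        t = np.asarray(t, float)
        if not clip:
            if np.any(t < self.timestamps[0]) or np.any(t > self.timestamps[-1]):
                raise InputError("query times outside series range")
        return np.interp(t, self.timestamps, self.values)

    def replace_values(self, values: np.ndarray) -> "ConcentrationSeries":
        return ConcentrationSeries(self.cuvette_id, self.compound_id,
                                   self.timestamps.copy(), values)


InletLike = Union[ConcentrationSeries, float, int]


def time_constant(volume_l: float, inlet_flow_lpm: float) -> float:
    """Air-exchange time constant τ = V / F_in, in minutes."""
    if volume_l <= 0 or inlet_flow_lpm <= 0:
        raise InvalidParameterError("volume and inlet flow must be positive")
    return volume_l / inlet_flow_lpm


def exchange_fraction(elapsed_s: float, tau_s: float) -> float:
    """Fraction of the initial cuvette air replaced after ``elapsed_s``.

    Well-mixed model: 1 − exp(−t/τ).  After 5τ the air is exchanged to
    more than 99%.
    """
    if tau_s <= 0:
        raise InvalidParameterError("tau must be positive")
    if elapsed_s < 0:
        raise InvalidParameterError("elapsed time must be non-negative")
    return 1.0 - math.exp(-elapsed_s / tau_s)


def _inlet_func(inlet: InletLike, time_grid: np.ndarray) -> Callable[[float], float]:
    if isinstance(inlet, ConcentrationSeries):
        if (inlet.timestamps[0] > time_grid[0] + 1e-9
                or inlet.timestamps[-1] < time_grid[-1] - 1e-9):
            raise InputError("inlet series does not cover the simulation grid")
        ts, vs = inlet.timestamps, inlet.values
        return lambda t: float(np.interp(t, ts, vs))
    value = float(inlet)
    return lambda t: value


def simulate_concentration(
    config: CuvetteConfig,
    emission: EmissionProfile,
    inlet: InletLike,
    time_grid: np.ndarray,
    initial_concentration: float = 0.0,
    emission_area_m2: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ConcentrationSeries:
    """Integrate the cuvette balance ODE and sample it on ``time_grid``.

    Parameters
    ----------
    emission_area_m2 : float, optional
        Area multiplying the emission rate; defaults to the configured leaf
        area.  Pass 1.0 to interpret the profile as a whole-cuvette source
        in nmol·s⁻¹ (e.g. bare-soil efflux).

    Notes
    -----
    Explicit adaptive Runge–Kutta (RK45); the system is linear and
    non-stiff for realistic time constants of minutes.  For constant E and
    c_in the solution converges to ``c_in + E·A/F_in`` as t → ∞.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) < 2:
        raise InputError("time grid must be 1-D with at least two points")
    if not np.all(np.diff(time_grid) > 0):
        raise InputError("time grid must be strictly increasing")

    volume_m3 = liters_to_m3(config.volume_l)
    flow_m3s = lpm_to_m3s(config.inlet_flow_lpm)
    area = config.leaf_area_m2 if emission_area_m2 is None else emission_area_m2
    c_in = _inlet_func(inlet, time_grid)

    def rhs(t, c):
        return (float(emission.evaluate(t)) * area / volume_m3
                + flow_m3s / volume_m3 * (c_in(t) - c[0]))

    sol = solve_ivp(
        rhs,
        (time_grid[0], time_grid[-1]),
        [float(initial_concentration)],
        t_eval=time_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - linear system, should not happen
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return ConcentrationSeries(config.cuvette_id, emission.compound_id,
                               time_grid, sol.y[0])


def steady_state_emission(
    inlet_flow_lpm: float,
    leaf_area_m2: float,
    c_out: np.ndarray,
    c_in: np.ndarray = 0.0,
) -> np.ndarray:
    """Steady-state emission E = (F_in/A_leaf)·(c_out − c_in), nmol·m⁻²·s⁻¹.

    Accepts scalars or arrays for the concentrations.  A negative result
    signals net uptake.
    """
    if inlet_flow_lpm <= 0:
        raise InvalidParameterError("inlet flow must be positive")
    if leaf_area_m2 <= 0:
        raise InvalidParameterError(
            "leaf area must be positive (non-plant cuvette?)")
    flow_m3s = lpm_to_m3s(inlet_flow_lpm)
    # same operation order as dynamic_emission so the two agree bit-for-bit
    # on constant series (where the storage term is exactly zero)
    result = flow_m3s * (np.asarray(c_out, float) - np.asarray(c_in, float)) / leaf_area_m2
    return result if result.ndim else float(result)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    if window % 2 == 0:
        raise InvalidParameterError("smoothing window must be odd")
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def dynamic_emission(
    outlet: ConcentrationSeries,
    inlet: InletLike,
    config: CuvetteConfig,
    smooth_window: int | None = None,
) -> ConcentrationSeries:
    """Invert the cuvette balance including the storage term.

    E(t) = [V·dc_out/dt + F_in·(c_out − c_in)] / A_leaf with dc/dt from
    second-order central differences (one-sided at the boundaries).
    Reduces exactly to :func:`steady_state_emission` where dc/dt = 0.

    ``smooth_window`` (odd, samples) applies a centered moving average to
    the outlet series before differentiation; off by default.
    """
    if len(outlet) < 3:
        raise InsufficientDataError("dynamic emission needs at least 3 samples")
    if config.leaf_area_m2 <= 0:
        raise InvalidParameterError(
            "leaf area must be positive (non-plant cuvette?)")

    t = outlet.timestamps
    c_out = outlet.values
    if smooth_window:
        c_out = _moving_average(c_out, smooth_window)
    if isinstance(inlet, ConcentrationSeries):
        if inlet.timestamps[-1] < t[0] or inlet.timestamps[0] > t[-1]:
            raise InputError("inlet series does not overlap the outlet series")
        c_in = inlet.interp(t)
    else:
        c_in = np.full_like(t, float(inlet))

    volume_m3 = liters_to_m3(config.volume_l)
    flow_m3s = lpm_to_m3s(config.inlet_flow_lpm)
    # differentiate relative to the first sample: the derivative is unchanged
    # but constant series yield an exactly zero storage term
    dcdt = np.gradient(c_out - c_out[0], t, edge_order=2)
    emission = (volume_m3 * dcdt + flow_m3s * (c_out - c_in)) / config.leaf_area_m2
    return ConcentrationSeries(outlet.cuvette_id, outlet.compound_id, t, emission)
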