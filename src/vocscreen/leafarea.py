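"""Leaf-area estimation from RGB plant images.

Plants photographed against a non-green backdrop (e.g. a blue curtain) are
segmented by counting greenish pixels (hue window + saturation threshold in
HSV space).  Pixel counts are converted to physical leaf area through a
linear calibration against planimeter-measured areas, and leaf area between
measurement days is interpolated with a natural cubic spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import linregress
from skimage.color import rgb2hsv

from .errors import FitError, InputError, InvalidParameterError, RangeError

__all__ = [
    "LeafAreaCalibration",
    "LeafAreaTimeline",
    "count_plant_pixels",
    "fit_calibration",
    "estimate_area",
    "interpolate_area",
]

DEFAULT_HUE_WINDOW_DEG = (60.0, 180.0)
DEFAULT_MIN_SATURATION = 0.15


def count_plant_pixels(image: np.ndarray,
                       hue_window_deg: tuple[float, float] = DEFAULT_HUE_WINDOW_DEG,
                       min_saturation: float = DEFAULT_MIN_SATURATION) -> int:
    """Count greenish pixels in an RGB image.

    A pixel counts as plant when its hue (degrees, 0-360) lies inside
    ``hue_window_deg`` (inclusive) and its HSV saturation is at least
    ``min_saturation``.  The defaults capture green foliage against blue
    or grey backgrounds; tune per species/background.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("image is empty")
    if image.ndim != 3 or image.shape[2] < 3:
        raise InputError("expected an RGB raster of shape (H, W, 3)")
    hsv = rgb2hsv(image[:, :, :3])
    hue_deg = hsv[:, :, 0] * 360.0
    lo, hi = hue_window_deg
    mask = (hue_deg >= lo) & (hue_deg <= hi) & (hsv[:, :, 1] >= min_saturation)
    return int(mask.sum())


@dataclass(frozen=True)
class LeafAreaCalibration:
    """Linear pixel-count → leaf-area (cm²) calibration."""

    slope_cm2_per_pixel: float
    intercept_cm2: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise InvalidParameterError("calibration needs >= 2 points")


def fit_calibration(pixel_counts: Sequence[float],
                    measured_areas_cm2: Sequence[float],
                    through_origin: bool = False) -> LeafAreaCalibration:
    """Ordinary least-squares line area = slope·pixels (+ intercept)."""
    x = np.asarray(pixel_counts, float)
    y = np.asarray(measured_areas_cm2, float)
    if len(x) != len(y):
        raise FitError("pixel counts and areas must have equal length")
    if len(x) < 2:
        raise FitError("calibration needs >= 2 points")
    if np.ptp(x) == 0:
        raise FitError("degenerate calibration: all pixel counts equal")

    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        residuals = y - slope * x
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(residuals ** 2)) / ss_tot
        return LeafAreaCalibration(slope, 0.0, r2, len(x))

    fit = linregress(x, y)
    return LeafAreaCalibration(float(fit.slope), float(fit.intercept),
                               float(fit.rvalue) ** 2, len(x))


def estimate_area(calibration: LeafAreaCalibration, pixel_count: float) -> float:
    """Leaf area in cm² for a given pixel count."""
    return calibration.slope_cm2_per_pixel * pixel_count + calibration.intercept_cm2


@dataclass
class LeafAreaTimeline:
    """Leaf area measurements over an experiment with spline interpolation.

    ``measurement_times_days`` are days since experiment start (strictly
    increasing); ``areas_m2`` the measured one-sided leaf areas.  Between
    knots a natural cubic spline is used (two points degrade to a linear
    segment); extrapolation beyond the measured range is refused.
    """

    measurement_times_days: np.ndarray
    areas_m2: np.ndarray
    _spline: object = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.measurement_times_days = np.asarray(self.measurement_times_days, float)
        self.areas_m2 = np.asarray(self.areas_m2, float)
        if len(self.measurement_times_days) != len(self.areas_m2):
            raise InputError("times and areas must have equal length")
        if len(self.measurement_times_days) < 1:
            raise InputError("timeline needs at least one measurement")
        if len(self.measurement_times_days) > 1 and not np.all(
                np.diff(self.measurement_times_days) > 0):
            raise InputError("measurement times must be strictly increasing")
        if np.any(self.areas_m2 <= 0):
            raise InputError("areas must be positive")
        if len(self.measurement_times_days) >= 3:
            self._spline = CubicSpline(self.measurement_times_days, self.areas_m2,
                                       bc_type="natural")

    def area_at(self, query_times_days):
        """Interpolated leaf area (m²) at ``query_times_days``."""
        q = np.asarray(query_times_days, float)
        t = self.measurement_times_days
        if np.any(q < t[0]) or np.any(q > t[-1]):
            raise RangeError(
                f"query outside measured range [{t[0]:g}, {t[-1]:g}] days")
        if self._spline is not None:
            result = self._spline(q)
        else:
            result = np.interp(q, t, self.areas_m2)
        return result if np.ndim(result) else float(result)


def interpolate_area(timeline: LeafAreaTimeline, query_times_days):
    """Functional alias for :meth:`LeafAreaTimeline.area_at`."""
    return timeline.area_at(query_times_days)
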