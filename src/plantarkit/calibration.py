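"""Intensity-to-pressure calibration.

The optical platform responds linearly: placing cylindrical reference weights on
the plate and reading the mean intensity of the circular contact patch gives a
set of (intensity, pressure) points with pressure ``P = F / A`` and ``F = m g``.
An ordinary least-squares line maps intensity levels to pascals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import ParameterError, PressureImage, RankError, as_array

__all__ = [
    "STANDARD_GRAVITY",
    "CalibrationWeight",
    "LinearCalibration",
    "weight_to_pressure",
    "fit_calibration",
    "intensity_to_pressure",
]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class CalibrationWeight:
    """One reference weight: mass (kg), base area (m^2), observed mean intensity."""

    mass_kg: float
    base_area_m2: float
    measured_mean_intensity: float

    def __post_init__(self):
        if not self.mass_kg > 0 or not self.base_area_m2 > 0:
            raise ParameterError("mass and base area must be positive")


@dataclass(frozen=True)
class LinearCalibration:
    """Fitted line ``pressure = slope * intensity + intercept`` with its R^2."""

    slope: float
    intercept: float
    r_squared: float
    g: float = STANDARD_GRAVITY
    n_points: int = field(default=0, compare=False)


def weight_to_pressure(w: CalibrationWeight, g: float = STANDARD_GRAVITY) -> float:
    """Pressure in pascals exerted by a reference weight: ``m g / A``."""
    if not g > 0:
        raise ParameterError("g must be positive")
    return w.mass_kg * g / w.base_area_m2


def fit_calibration(weights: Sequence[CalibrationWeight],
                    g: float = STANDARD_GRAVITY) -> LinearCalibration:
    """Ordinary least-squares fit of pressure against mean intensity.

    Requires at least two distinct intensities; fewer than three points trigger
    a warning (the fit is then exact by construction and R^2 carries no
    information).  ``r_squared = 1 - SS_res / SS_tot`` from the fit residuals.
    """
    weights = list(weights)
    if len(weights) < 2:
        raise ParameterError("need at least 2 calibration weights")
    if len(weights) < 3:
        warnings.warn("fewer than 3 calibration points: R^2 is 1 by construction",
                      stacklevel=2)
    x = np.array([w.measured_mean_intensity for w in weights], dtype=float)
    y = np.array([weight_to_pressure(w, g) for w in weights], dtype=float)
    if np.unique(x).size < 2:
        raise RankError("all intensities equal: calibration line is undefined")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return LinearCalibration(slope=float(res.slope), intercept=float(res.intercept),
                             r_squared=r2, g=g, n_points=len(weights))


def intensity_to_pressure(img, cal: LinearCalibration) -> PressureImage:
    """Apply the calibration line per pixel; negative pressures clip to zero.

    The number of clipped pixels is reported in ``meta["clipped_pixels"]``.
    """
    data = as_array(img)
    pressure = cal.slope * data + cal.intercept
    clipped = int(np.count_nonzero(pressure < 0))
    pressure = np.maximum(pressure, 0.0)
    return PressureImage(pressure, meta={
        "clipped_pixels": clipped,
        "calibration": {"slope": cal.slope, "intercept": cal.intercept,
                        "r_squared": cal.r_squared, "g": cal.g},
    })
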