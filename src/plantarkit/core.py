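"""Shared containers, configuration and error types for the plantar-pressure pipeline.

Conventions used throughout the package
---------------------------------------
* Images are 2-D ``numpy`` arrays indexed ``[row, col]``, origin at the top-left,
  0-based, half-open extents.
* Point coordinates handed to users are ``(x, y) = (col, row)`` pairs; ``x`` is the
  medial-lateral axis of the platform, ``y`` the anterior-posterior axis (increasing
  downwards in image coordinates).
* Angles of foot axes are measured from the image vertical, in degrees, folded into
  ``(-90, 90]``; positive tilts the toe towards +x (clockwise on screen).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PressureImage",
    "PipelineConfig",
    "as_array",
    "PlantarKitError",
    "ParameterError",
    "DimensionError",
    "LayoutError",
    "CoverageError",
    "RegistrationError",
    "DistortionModelError",
    "DegenerateContrastError",
    "StitchError",
    "RankError",
    "NoContactError",
    "DegenerateEllipseError",
    "SegmentationError",
    "SizeError",
    "EmptyGaitError",
    "InsufficientStepsError",
    "SimilarityUndefinedError",
    "DegenerateFeatureError",
    "EvaluationError",
    "FormatError",
]


class PlantarKitError(Exception):
    """Base class for all errors raised by plantarkit."""


class ParameterError(PlantarKitError, ValueError):
    """Invalid parameter value (non-positive size, non-PSD covariance, ...)."""


class DimensionError(PlantarKitError, ValueError):
    """Geometry does not fit the requested canvas / shapes are inconsistent."""


class LayoutError(PlantarKitError, ValueError):
    """Generated scene elements overlap or cannot be placed."""


class CoverageError(PlantarKitError, ValueError):
    """Camera tiles do not cover the full platform frame."""


class RegistrationError(PlantarKitError, ValueError):
    """Landmark set is insufficient or degenerate for transform estimation."""


class DistortionModelError(PlantarKitError, ValueError):
    """Radial model is not invertible within the image extent."""


class DegenerateContrastError(PlantarKitError, ValueError):
    """Contrast equalization on a constant image."""


class StitchError(PlantarKitError, ValueError):
    """Images to be stitched do not overlap."""


class RankError(PlantarKitError, ValueError):
    """Calibration fit is rank-deficient (all intensities equal)."""


class NoContactError(PlantarKitError, ValueError):
    """Frame (or whole sequence) has no supra-threshold pressure."""


class DegenerateEllipseError(PlantarKitError, ValueError):
    """Point cloud is (near-)collinear; carries the covariance eigenvalues."""

    def __init__(self, message: str, eigenvalues=None):
        super().__init__(message)
        self.eigenvalues = eigenvalues


class SegmentationError(PlantarKitError, ValueError):
    """No foot-sized connected component found."""


class SizeError(PlantarKitError, ValueError):
    """Foot region too small for the requested measurement."""


class EmptyGaitError(PlantarKitError, ValueError):
    """No step found in a gait sequence."""


class InsufficientStepsError(EmptyGaitError):
    """Fewer steps than required for dynamic features."""


class SimilarityUndefinedError(PlantarKitError, ValueError):
    """Pearson similarity undefined (zero-variance trace)."""


class DegenerateFeatureError(PlantarKitError, ValueError):
    """A gallery feature is constant and cannot be min-max normalized."""


class EvaluationError(PlantarKitError, ValueError):
    """Score lists empty / no genuine pair can be formed."""


class FormatError(PlantarKitError, ValueError):
    """Frame files with inconsistent shapes or bit depths."""


def as_array(img) -> np.ndarray:
    """Return the pixel array of ``img`` (``PressureImage`` or array-like) as float64."""
    if isinstance(img, PressureImage):
        return img.data
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


@dataclass
class PressureImage:
    """A calibrated (or raw-intensity) 2-D pressure grid.

    Parameters
    ----------
    data:
        2-D array of pressure (or intensity) values, ``[row, col]``.
    pixel_scale_mm:
        Physical edge length of one pixel in millimetres, if known.
    meta:
        Free-form provenance (calibration used, clip counts, generator echo ...).
    """

    data: np.ndarray
    pixel_scale_mm: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError(f"PressureImage needs a 2-D grid, got {self.data.shape}")
        if self.pixel_scale_mm is not None and not self.pixel_scale_mm > 0:
            raise ParameterError("pixel_scale_mm must be positive")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class PipelineConfig:
    """Run-wide configuration shared by the CLI stages.

    Every report written by the package embeds the exact configuration used,
    because several outputs (PBI, arch index) are convention-dependent.
    """

    threshold_fraction: float = 0.1
    percentile_q: float = 95.0
    ellipse_convention: str = "chi2_95"  # or "enclosing"
    origin_mode: str = "trajectory_centroid"  # or "image_center"
    n_resample: int = 100
    alpha_weight: float = 0.5
    pixel_scale_mm: Optional[float] = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))
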