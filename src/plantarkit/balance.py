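"""Center-of-pressure trajectories and the posture balance index (PBI).

A subject standing still sways; the trajectory of the center of pressure (COP)
over the recording quantifies that sway.  The COP of each frame is the
intensity-weighted centroid of the supra-threshold pixels (the platform's
response is linear in pressure, so intensity weights are pressure weights).
Points within the 95th percentile of distance to the trajectory center are kept
and an ellipse is fitted to them; the posture balance index is the inverse
product of the ellipse radii, ``PBI = 1 / (a b)`` — higher means steadier
stance.  PBI is convention-dependent: the default radii use the 95% chi-square
coverage ellipse; an "enclosing" convention (maximum projections onto the
principal axes) is also available and recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .core import (
    DegenerateEllipseError,
    NoContactError,
    ParameterError,
    as_array,
)

__all__ = [
    "CHI2_COVERAGE_95",
    "CopTrajectory",
    "EllipseFit",
    "BalanceResult",
    "compute_cop",
    "cop_trajectory",
    "filter_percentile",
    "fit_ellipse_cloud",
    "pbi_from_points",
    "posture_balance_index",
]

#: 95% coverage quantile of the chi-square distribution with 2 dof (~5.991)
CHI2_COVERAGE_95 = float(chi2.ppf(0.95, df=2))


@dataclass
class CopTrajectory:
    """Time-ordered COP points (x medial-lateral, y anterior-posterior, px)."""

    points: np.ndarray
    origin_mode: str = "trajectory_centroid"
    pixel_scale_mm: Optional[float] = None
    dropped_frames: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 2:
            raise ParameterError("trajectory needs >= 1 point of (x, y)")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("trajectory contains non-finite coordinates")


@dataclass
class EllipseFit:
    """Fitted ellipse: center, radii ``a >= b``, orientation from +x in (-90, 90]."""

    center: tuple
    a: float
    b: float
    orientation_deg: float
    eigenvalues: tuple = (0.0, 0.0)
    convention: str = "chi2_95"
    orientation_stable: bool = True

    @property
    def axis_ratio(self) -> float:
        return self.a / self.b if self.b > 0 else np.inf


@dataclass
class BalanceResult:
    trajectory: CopTrajectory
    retained_points: np.ndarray
    ellipse: EllipseFit
    pbi: float
    config: dict = field(default_factory=dict)


def compute_cop(frame, threshold_fraction: float = 0.1):
    """Intensity-weighted centroid ``(x, y)`` of supra-threshold pixels.

    Pixels with value >= ``threshold_fraction * max(frame)`` contribute with
    their intensity as weight.  Raises :class:`NoContactError` for frames with
    no positive pressure.
    """
    data = as_array(frame)
    peak = data.max() if data.size else 0.0
    if peak <= 0:
        raise NoContactError("frame has no positive pressure")
    mask = data >= threshold_fraction * peak
    w = data[mask]
    r, c = np.nonzero(mask)
    total = w.sum()
    return (float((c * w).sum() / total), float((r * w).sum() / total))


def cop_trajectory(frames: Sequence, origin_mode: str = "trajectory_centroid",
                   threshold_fraction: float = 0.1,
                   pixel_scale_mm: Optional[float] = None) -> CopTrajectory:
    """Per-frame COP re-expressed relative to the chosen origin.

    ``origin_mode="image_center"`` reproduces the plotting convention where
    (0, 0) is the image center; ``"trajectory_centroid"`` (default) makes the
    result invariant to where the subject stands.  Frames with no contact are
    dropped and counted in ``dropped_frames``.
    """
    if origin_mode not in ("image_center", "trajectory_centroid"):
        raise ParameterError(f"unknown origin_mode {origin_mode!r}")
    pts, dropped, shape = [], 0, None
    for f in frames:
        data = as_array(f)
        shape = data.shape
        try:
            pts.append(compute_cop(data, threshold_fraction))
        except NoContactError:
            dropped += 1
    if not pts:
        raise NoContactError("no frame in the sequence has contact")
    if len(pts) < 2:
        raise NoContactError("need >= 2 frames with contact for a trajectory")
    pts = np.asarray(pts, dtype=float)
    if origin_mode == "image_center":
        origin = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
    else:
        origin = pts.mean(axis=0)
    return CopTrajectory(pts - origin, origin_mode=origin_mode,
                         pixel_scale_mm=pixel_scale_mm, dropped_frames=dropped)


def filter_percentile(traj, q: float = 95.0) -> np.ndarray:
    """Retain points whose distance to the origin is within the q-th percentile.

    The percentile uses linear interpolation between order statistics (pinned
    for reproducibility).  ``q = 100`` is the identity.
    """
    if not 0 < q <= 100:
        raise ParameterError("q must lie in (0, 100]")
    pts = traj.points if isinstance(traj, CopTrajectory) else np.atleast_2d(np.asarray(traj, float))
    d = np.hypot(pts[:, 0], pts[:, 1])
    cutoff = np.percentile(d, q, method="linear")
    return pts[d <= cutoff]


def _weighted_moments(pts: np.ndarray, weights=None):
    if weights is None:
        center = pts.mean(axis=0)
        d = pts - center
        cov = d.T @ d / len(pts)
    else:
        w = np.asarray(weights, dtype=float)
        total = w.sum()
        center = (pts * w[:, None]).sum(axis=0) / total
        d = pts - center
        cov = (d * w[:, None]).T @ d / total
    return center, cov


def fit_ellipse_cloud(points, convention: str = "chi2_95", weights=None,
                      degeneracy_rtol: float = 1e-10) -> EllipseFit:
    """Covariance ellipse of a 2-D point cloud.

    Center is the (weighted) mean; orientation the leading eigenvector of the
    2x2 covariance; radii are ``sqrt(chi2_{2, 0.95} * eigenvalue)`` for 95%
    coverage of a Gaussian cloud (``convention="chi2_95"``) or the maximum
    absolute projections of the points on the principal axes
    (``convention="enclosing"``).  A (near-)collinear cloud raises
    :class:`DegenerateEllipseError` carrying the eigenvalues.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise ParameterError("ellipse fit needs >= 3 points")
    if convention not in ("chi2_95", "enclosing"):
        raise ParameterError(f"unknown ellipse convention {convention!r}")
    center, cov = _weighted_moments(pts, weights)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    if lam_major <= 0 or lam_minor < degeneracy_rtol * lam_major:
        raise DegenerateEllipseError(
            f"point cloud is degenerate (eigenvalues {lam_minor:.3e}, {lam_major:.3e})",
            eigenvalues=(lam_minor, lam_major),
        )
    major_vec = evecs[:, 1]
    d = pts - center
    if convention == "chi2_95":
        a = float(np.sqrt(CHI2_COVERAGE_95 * lam_major))
        b = float(np.sqrt(CHI2_COVERAGE_95 * lam_minor))
    else:
        proj_major = d @ major_vec
        proj_minor = d @ evecs[:, 0]
        a = float(np.abs(proj_major).max())
        b = float(np.abs(proj_minor).max())
        if b > a:  # max projection can swap the order; keep a >= b
            a, b = b, a
            major_vec = evecs[:, 0]
    angle = np.rad2deg(np.arctan2(major_vec[1], major_vec[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    stable = (lam_major - lam_minor) / lam_major > 1e-3
    return EllipseFit(center=(float(center[0]), float(center[1])), a=a, b=b,
                      orientation_deg=float(angle), eigenvalues=(lam_minor, lam_major),
                      convention=convention, orientation_stable=bool(stable))


def pbi_from_points(points, q: float = 95.0, convention: str = "chi2_95"):
    """Percentile filter + ellipse fit + ``PBI = 1/(a b)`` for a COP point cloud."""
    traj = points if isinstance(points, CopTrajectory) else CopTrajectory(points)
    retained = filter_percentile(traj, q)
    ellipse = fit_ellipse_cloud(retained, convention=convention)
    return retained, ellipse, 1.0 / (ellipse.a * ellipse.b)


def posture_balance_index(frames: Sequence, threshold_fraction: float = 0.1,
                          q: float = 95.0, origin_mode: str = "trajectory_centroid",
                          convention: str = "chi2_95",
                          pixel_scale_mm: Optional[float] = None) -> BalanceResult:
    """End-to-end posture balance evaluation of a standing-frame sequence.

    PBI units are px^-2 (mm^-2 when ``pixel_scale_mm`` is set, in which case
    the trajectory is scaled before fitting).  Larger PBI = tighter sway.
    """
    traj = cop_trajectory(frames, origin_mode=origin_mode,
                          threshold_fraction=threshold_fraction,
                          pixel_scale_mm=pixel_scale_mm)
    if pixel_scale_mm is not None:
        traj = CopTrajectory(traj.points * pixel_scale_mm, origin_mode=traj.origin_mode,
                             pixel_scale_mm=pixel_scale_mm,
                             dropped_frames=traj.dropped_frames)
    retained, ellipse, pbi = pbi_from_points(traj, q=q, convention=convention)
    return BalanceResult(
        trajectory=traj, retained_points=retained, ellipse=ellipse, pbi=pbi,
        config={"threshold_fraction": threshold_fraction, "q": q,
                "origin_mode": origin_mode, "convention": convention,
                "pixel_scale_mm": pixel_scale_mm,
                "units": "mm^-2" if pixel_scale_mm else "px^-2"},
    )
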