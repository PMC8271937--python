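"""Static plantar features: segmentation, principal axis, arch index, foot class.

The arch index is the fraction of the foot's contact area contributed by the
midfoot after the foot is rotated to vertical and its length divided into three
equal segments (forefoot / midfoot / heel).  Feet classify as flat (arch index
>= 0.26), normal (between 0.21 and 0.26) or high-arch (<= 0.21); the boundary
values 0.26 and 0.21 map to flat and high-arch respectively, preserving the
inclusive inequalities of the clinical thresholds.

"Area" here means contact area — supra-threshold pixel counts — not
pressure-weighted mass.  Toes are included in the foot length by default (the
classical Cavanagh index truncates them; a divergence flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .balance import EllipseFit, fit_ellipse_cloud
from .core import (
    DegenerateEllipseError,
    ParameterError,
    SegmentationError,
    SizeError,
    as_array,
)

__all__ = [
    "ARCH_FLAT_THRESHOLD",
    "ARCH_HIGH_THRESHOLD",
    "FootMeasures",
    "segment_feet",
    "principal_axis",
    "thirds_counts",
    "arch_index",
    "classify_foot",
    "static_features",
]

ARCH_FLAT_THRESHOLD = 0.26
ARCH_HIGH_THRESHOLD = 0.21


@dataclass
class FootMeasures:
    """Per-foot static feature vector Fs = [arch index, foot angle, axis ratio]."""

    arch_index: float
    foot_angle_deg: float
    axis_ratio: float
    foot_class: str
    side: str

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.arch_index, self.foot_angle_deg, self.axis_ratio])


def segment_feet(img, threshold_fraction: float = 0.1,
                 min_area: int = 25) -> List[Tuple[str, np.ndarray]]:
    """Connected components of the supra-threshold mask, largest two kept.

    Side is assigned by centroid x (smaller x -> left).  Single-foot images
    return one entry; an empty image raises :class:`SegmentationError`.
    """
    data = as_array(img)
    peak = data.max() if data.size else 0.0
    if peak <= 0:
        raise SegmentationError("image has no foreground")
    mask = data >= threshold_fraction * peak
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("no connected component above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [int(order[i]) + 1 for i in range(min(2, n)) if sizes[order[i]] >= min_area]
    if not keep:
        raise SegmentationError(f"no component with area >= {min_area} px")
    feet = []
    for lab in keep:
        m = labels == lab
        cx = np.nonzero(m)[1].mean()
        feet.append((cx, m))
    feet.sort(key=lambda t: t[0])
    if len(feet) == 1:
        return [("single", feet[0][1])]
    return [("left", feet[0][1]), ("right", feet[1][1])]


def principal_axis(mask, pressures, sd_clip: float = 2.0):
    """Pressure-weighted principal axis of one foot.

    Pixels whose pressure is within ``sd_clip`` standard deviations of the mean
    pressure (the 95% retention of a Gaussian at 2 SD) enter a pressure-weighted
    covariance ellipse fit.  Returns ``(foot_angle_deg, EllipseFit)`` where the
    angle is measured between the major axis and the image vertical, positive
    tilting the toe towards +x, folded into (-90, 90].  An isotropic foot
    (degenerate axis direction) reports angle 0 and an unstable flag.
    """
    mask = np.asarray(mask, dtype=bool)
    data = as_array(pressures)
    if mask.shape != data.shape:
        raise ParameterError("mask and pressure image shapes differ")
    r, c = np.nonzero(mask)
    if len(r) < 3:
        raise ParameterError("principal axis needs >= 3 foreground pixels")
    p = data[mask]
    sd = p.std()
    keep = np.abs(p - p.mean()) <= sd_clip * sd if sd > 0 else np.ones(len(p), dtype=bool)
    if keep.sum() < 3:
        keep = np.ones(len(p), dtype=bool)
    pts = np.column_stack([c[keep], r[keep]]).astype(float)  # (x, y)
    ellipse = fit_ellipse_cloud(pts, convention="chi2_95", weights=p[keep])
    if not ellipse.orientation_stable:
        return 0.0, ellipse
    # major-axis direction (from +x); foot angle measured from image vertical
    phi = np.deg2rad(ellipse.orientation_deg)
    ex, ey = np.cos(phi), np.sin(phi)
    if ey < 0:
        ex, ey = -ex, -ey
    angle = np.rad2deg(np.arctan2(-ex, ey))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle), ellipse


def thirds_counts(length_coords) -> Tuple[int, int, int]:
    """Pixel counts in the three equal-length segments of the foot extent.

    ``length_coords`` are the coordinates of the contact pixels along the
    (vertical) foot axis.  The extent from lowest to highest value is split
    into three equal right-open segments; ties at a boundary fall into the
    farther segment.
    """
    w = np.asarray(length_coords, dtype=float)
    span = w.max() - w.min()
    if span < 2:
        raise SizeError("foot length < 3 rows; cannot split into thirds")
    e1 = w.min() + span / 3.0
    e2 = w.min() + 2.0 * span / 3.0
    n1 = int(np.count_nonzero(w < e1))
    n2 = int(np.count_nonzero((w >= e1) & (w < e2)))
    n3 = int(len(w) - n1 - n2)
    return n1, n2, n3


def arch_index(mask, angle_deg: float = 0.0) -> float:
    """Midfoot contact area over total contact area, after rotating to vertical.

    The contact-pixel coordinates are rotated (continuously, no resampling) by
    the negative of the measured foot angle so the principal axis is vertical,
    the row extent is split into equal thirds, and the arch index is
    ``midfoot / (forefoot + midfoot + heel)`` by pixel count.
    """
    mask = np.asarray(mask, dtype=bool)
    r, c = np.nonzero(mask)
    if len(r) == 0:
        raise SegmentationError("empty mask")
    th = np.deg2rad(angle_deg)
    rc, cc = r.mean(), c.mean()
    dx = c - cc
    dy = r - rc
    # inverse of the foot rotation: w is the coordinate along the foot length
    w = -np.sin(th) * dx + np.cos(th) * dy
    _, mid, _ = thirds_counts(w)
    return mid / len(r)


def classify_foot(value: float) -> str:
    """Threshold classification of an arch index into flat / normal / high_arch."""
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"arch index {value} outside [0, 1]")
    if value >= ARCH_FLAT_THRESHOLD:
        return "flat"
    if value <= ARCH_HIGH_THRESHOLD:
        return "high_arch"
    return "normal"


def static_features(img, threshold_fraction: float = 0.1) -> List[FootMeasures]:
    """Per-foot static features Fs for every foot found in the image."""
    data = as_array(img)
    out = []
    for side, mask in segment_feet(data, threshold_fraction):
        try:
            angle, ellipse = principal_axis(mask, data)
            ratio = ellipse.axis_ratio
        except DegenerateEllipseError:
            raise
        ai = arch_index(mask, angle)
        out.append(FootMeasures(arch_index=ai, foot_angle_deg=angle,
                                axis_ratio=ratio, foot_class=classify_foot(ai),
                                side=side))
    return out
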