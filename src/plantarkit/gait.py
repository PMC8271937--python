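"""Dynamic gait features from pressure-frame sequences.

A walking trial is a sequence of frames in which footprints appear one after
another.  A *step* is a maximal run of frames whose contact regions overlap
spatially frame-to-frame; its footprint is the pixelwise maximum over the run
(full contact extent for geometry; the pixelwise mean is also kept for pressure
summaries).  From consecutive steps come the dynamic features: the step angle
(difference of principal-axis angles), the step width (distance between heel
points), and the similarity of the total-pressure-versus-time traces, measured
as Pearson correlation after linear time-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import footstat
from .core import (
    EmptyGaitError,
    InsufficientStepsError,
    ParameterError,
    SimilarityUndefinedError,
    as_array,
)

__all__ = [
    "StepEvent",
    "GaitFeatures",
    "segment_steps",
    "step_angle",
    "heel_point",
    "step_width",
    "pressure_trace",
    "resample_trace",
    "trace_similarity",
    "dynamic_features",
]


@dataclass
class StepEvent:
    """One detected step: frame span, footprint, trace and axis summary."""

    step_index: int
    frame_span: Tuple[int, int]  # [start, end)
    footprint: np.ndarray        # pixelwise max over the span
    mean_footprint: np.ndarray   # pixelwise mean over the span
    mask: np.ndarray
    pressure_trace: np.ndarray
    centroid_xy: Tuple[float, float]
    axis_angle_deg: float

    def __post_init__(self):
        start, end = self.frame_span
        if len(self.pressure_trace) != end - start:
            raise ParameterError("pressure trace length must equal the frame span")


@dataclass
class GaitFeatures:
    """Dynamic feature vector Fd = [step angle, step width, trace similarity]."""

    step_angle_deg: float
    step_width: float
    trace_similarity: float
    n_steps: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.step_angle_deg, self.step_width, self.trace_similarity])


def segment_steps(frames: Sequence, threshold_fraction: float = 0.1,
                  min_frames: int = 2) -> List[StepEvent]:
    """Split a frame sequence into steps.

    The contact threshold is ``threshold_fraction`` of the global sequence
    maximum.  A new step starts whenever contact resumes after an empty frame
    or the contact region stops overlapping the previous frame's region
    (the foot has moved to a new location).  Runs shorter than ``min_frames``
    are discarded.
    """
    arrs = [as_array(f) for f in frames]
    if not arrs:
        raise EmptyGaitError("empty frame sequence")
    global_max = max(a.max() for a in arrs)
    if global_max <= 0:
        raise EmptyGaitError("no frame has positive pressure")
    thr = threshold_fraction * global_max
    masks = [a >= thr for a in arrs]

    runs = []
    current = None
    for i, m in enumerate(masks):
        active = bool(m.any())
        if not active:
            if current is not None:
                runs.append(current)
                current = None
            continue
        if current is None:
            current = [i, i + 1]
        elif (m & masks[i - 1]).any():
            current[1] = i + 1
        else:  # contact jumped to a disjoint location: a new step
            runs.append(current)
            current = [i, i + 1]
    if current is not None:
        runs.append(current)

    steps = []
    for start, end in runs:
        if end - start < min_frames:
            continue
        stack = np.stack(arrs[start:end])
        fp = stack.max(axis=0)
        fp_mask = fp >= thr
        trace = np.array([a[a >= thr].sum() for a in arrs[start:end]])
        r, c = np.nonzero(fp_mask)
        centroid = (float(c.mean()), float(r.mean()))
        angle, _ = footstat.principal_axis(fp_mask, fp)
        steps.append(StepEvent(step_index=len(steps), frame_span=(start, end),
                               footprint=fp, mean_footprint=stack.mean(axis=0),
                               mask=fp_mask, pressure_trace=trace,
                               centroid_xy=centroid, axis_angle_deg=angle))
    if not steps:
        raise EmptyGaitError("no step of sufficient duration found")
    return steps


def _fold_angle(d: float) -> float:
    d = abs(d) % 180.0
    return 180.0 - d if d > 90.0 else d


def step_angle(a: StepEvent, b: StepEvent) -> float:
    """Angle between the principal axes of two consecutive steps, in [0, 90] deg."""
    return _fold_angle(a.axis_angle_deg - b.axis_angle_deg)


def heel_point(mask, direction_xy) -> Tuple[float, float]:
    """Rear-most contact pixel of a footprint along the walking direction.

    The heel is the supra-threshold pixel with the smallest projection onto the
    walking direction (an orientation-free reading of "the lowest point").
    Ties resolve to the first pixel in row-major order.
    """
    mask = np.asarray(mask, dtype=bool)
    d = np.asarray(direction_xy, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ParameterError("walking direction is undefined (zero vector)")
    d = d / norm
    r, c = np.nonzero(mask)
    if len(r) == 0:
        raise ParameterError("empty footprint mask has no heel point")
    proj = c * d[0] + r * d[1]
    i = int(np.argmin(proj))
    return (float(c[i]), float(r[i]))


def step_width(a: StepEvent, b: StepEvent,
               pixel_scale_mm: Optional[float] = None) -> float:
    """Euclidean distance between the heel points of two consecutive steps.

    The walking direction is the vector between the step centroids; result in
    px, or mm when ``pixel_scale_mm`` is given.
    """
    d = (b.centroid_xy[0] - a.centroid_xy[0], b.centroid_xy[1] - a.centroid_xy[1])
    ha = heel_point(a.mask, d)
    hb = heel_point(b.mask, d)
    w = float(np.hypot(hb[0] - ha[0], hb[1] - ha[1]))
    return w * pixel_scale_mm if pixel_scale_mm else w


def pressure_trace(step: StepEvent) -> np.ndarray:
    """Total supra-threshold pressure per frame within the step."""
    return step.pressure_trace


def resample_trace(trace, n_resample: int = 100) -> np.ndarray:
    """Linearly time-normalize a trace to ``n_resample`` samples."""
    v = np.asarray(trace, dtype=float)
    if len(v) < 2:
        raise ParameterError("trace must have >= 2 samples to resample")
    t = np.linspace(0.0, 1.0, len(v))
    return np.interp(np.linspace(0.0, 1.0, n_resample), t, v)


def trace_similarity(a, b, n_resample: int = 100) -> float:
    """Pearson correlation of two traces after time normalization.

    Both traces are resampled to ``n_resample`` points so trials of different
    durations compare; zero-variance traces raise
    :class:`SimilarityUndefinedError`.  The result lies in [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ParameterError("traces need >= 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise SimilarityUndefinedError("zero-variance trace: correlation undefined")
    ra = resample_trace(a, n_resample)
    rb = resample_trace(b, n_resample)
    if ra.std() == 0 or rb.std() == 0:
        raise SimilarityUndefinedError("zero-variance resampled trace")
    r = float(np.corrcoef(ra, rb)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def dynamic_features(frames: Sequence, reference_trace=None,
                     threshold_fraction: float = 0.1, min_frames: int = 2,
                     n_resample: int = 100,
                     pixel_scale_mm: Optional[float] = None):
    """Dynamic feature vector Fd of a walking trial.

    Step angle and step width are averaged over consecutive step pairs.  The
    trace similarity is the mean Pearson correlation between the trial's step
    traces and ``reference_trace``; when none is given (enrollment) the
    reference is the mean of the trial's z-scored, time-normalized traces.

    Returns ``(GaitFeatures, reference_trace)`` so the enrollment reference can
    be stored and reused for probes.
    """
    steps = segment_steps(frames, threshold_fraction, min_frames)
    if len(steps) < 2:
        raise InsufficientStepsError(f"need >= 2 steps, found {len(steps)}")
    angles = [step_angle(a, b) for a, b in zip(steps, steps[1:])]
    widths = [step_width(a, b, pixel_scale_mm) for a, b in zip(steps, steps[1:])]
    resampled = [_zscore(resample_trace(s.pressure_trace, n_resample)) for s in steps]
    if reference_trace is None:
        reference = np.mean(resampled, axis=0)
    else:
        reference = np.asarray(reference_trace, dtype=float)
        if len(reference) != n_resample:
            reference = resample_trace(reference, n_resample)
    sims = [trace_similarity(s.pressure_trace, reference, n_resample) for s in steps]
    feats = GaitFeatures(step_angle_deg=float(np.mean(angles)),
                         step_width=float(np.mean(widths)),
                         trace_similarity=float(np.mean(sims)),
                         n_steps=len(steps),
                         meta={"n_resample": n_resample,
                               "pixel_scale_mm": pixel_scale_mm})
    return feats, reference
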