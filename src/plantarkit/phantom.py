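"""Synthetic phantoms for every stage of the plantar-pressure pipeline.

No public plantar-pressure dataset accompanies the optical rig this package
targets, so every analysis stage is exercised against phantoms with known
ground truth: single footprints with a controllable midfoot (hence a known
arch index), sway sequences with a known COP covariance, multi-step gait
sequences with known step geometry, four-camera tile sets with known
distortion and photometric offsets, and abstract feature populations for the
biometric evaluation.

A footprint is rendered as three stacked super-ellipse lobes (heel, midfoot
band, forefoot) with a smooth pressure falloff towards the edges.  The lobes
are congruent up to their widths, so the midfoot width fraction monotonically
controls the thirds-area ratio and can be tuned by bisection to any reachable
target arch index.  Every generator is a pure function of its parameters and
an integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import footstat, gait, mosaic
from .core import (
    CoverageError,
    DimensionError,
    LayoutError,
    ParameterError,
    PressureImage,
)
from .mosaic import CameraModel, RawTile

__all__ = [
    "FootShapeParams",
    "SwayParams",
    "PopulationParams",
    "SyntheticFootprint",
    "GaitGroundTruth",
    "make_static_footprint",
    "tune_midfoot_fraction",
    "make_platform_scene",
    "make_sway_sequence",
    "make_gait_sequence",
    "split_into_tiles",
    "make_subject_population",
]

#: super-ellipse exponent of the footprint lobes; high enough that equal-width
#: lobes are near-rectangular (equal thirds), low enough that adjacent lobes
#: keep a wide shared boundary (single connected footprint)
LOBE_EXPONENT = 6.0

MAX_LEVEL = 255.0


@dataclass(frozen=True)
class FootShapeParams:
    """Geometry and intensity of a synthetic footprint.

    ``midfoot_width_fraction`` sets the midfoot band width as a fraction of the
    forefoot width and monotonically controls the arch index; 0 gives an empty
    midfoot (two disconnected lobes, arch index 0).  Rotation is measured from
    the image vertical, positive tilting the toe towards +x.  Bands narrower
    than one pixel may vanish in the rendering.
    """

    length_px: int = 180
    forefoot_width_px: int = 64
    heel_width_px: int = 44
    midfoot_width_fraction: float = 0.5
    rotation_deg: float = 0.0
    peak_intensity: float = 180.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.length_px <= 0 or self.forefoot_width_px <= 0 or self.heel_width_px <= 0:
            raise ParameterError("footprint dimensions must be positive")
        if not 0.0 <= self.midfoot_width_fraction <= 1.0:
            raise ParameterError("midfoot_width_fraction must lie in [0, 1]")
        if not 0.0 < self.peak_intensity <= MAX_LEVEL:
            raise ParameterError(f"peak_intensity must lie in (0, {MAX_LEVEL}]")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def widths(self) -> np.ndarray:
        return np.array([
            float(self.forefoot_width_px),
            self.midfoot_width_fraction * self.forefoot_width_px,
            float(self.heel_width_px),
        ])


@dataclass(frozen=True)
class SwayParams:
    """COP sway model: i.i.d. Gaussian offsets with the stated 2-D covariance."""

    cov_xx: float = 25.0
    cov_yy: float = 25.0
    cov_xy: float = 0.0
    n_frames: int = 100
    center: Optional[Tuple[float, float]] = None  # (x, y); canvas center if None
    seed: int = 0

    def covariance(self) -> np.ndarray:
        cov = np.array([[self.cov_xx, self.cov_xy], [self.cov_xy, self.cov_yy]])
        if np.min(np.linalg.eigvalsh(cov)) < -1e-9:
            raise ParameterError("COP covariance must be positive semi-definite")
        return cov


@dataclass(frozen=True)
class PopulationParams:
    """Abstract six-feature population: per-subject means jittered per trial.

    ``between_sd`` spreads subject means around the population centers;
    ``within_sd`` jitters the trials of one subject.  The separable regime used
    throughout (``within_sd = 0.25 * between_sd``) emulates repeatable gait
    features; equal SDs give chance-level identification.
    """

    n_subjects: int = 90
    n_trials: int = 5
    between_sd: Tuple[float, ...] = (0.05, 4.0, 0.35, 4.0, 8.0, 0.08)
    within_sd: Optional[Tuple[float, ...]] = None  # defaults to 0.25 * between_sd
    seed: int = 0

    #: population centers for [arch index, foot angle deg, axis ratio,
    #: step angle deg, step width px, trace similarity]
    centers: Tuple[float, ...] = (0.23, 4.0, 2.6, 8.0, 80.0, 0.75)

    def resolved_within(self) -> np.ndarray:
        b = np.asarray(self.between_sd, dtype=float)
        w = 0.25 * b if self.within_sd is None else np.asarray(self.within_sd, float)
        if len(b) != 6 or len(w) != 6:
            raise ParameterError("feature SD vectors must have length 6")
        if np.any(b <= 0) or np.any(w < 0):
            raise ParameterError("between_sd > 0 and within_sd >= 0 required")
        return w


@dataclass
class SyntheticFootprint:
    """Rendered footprint plus the ground truth its analysis should recover."""

    image: PressureImage
    mask: np.ndarray
    ground_truth: dict


@dataclass
class GaitGroundTruth:
    steps: pd.DataFrame          # step_index, start, end, heel_x, heel_y, axis_angle_deg
    pair_angles: List[float]     # folded |angle_i - angle_{i+1}| per consecutive pair
    pair_widths: List[float]     # Euclidean heel distance per consecutive pair
    traces: List[np.ndarray]     # total rendered pressure per frame, per step


# ---------------------------------------------------------------------------
# Footprint rendering
# ---------------------------------------------------------------------------

def _footprint_patch(params: FootShapeParams, shape, center_rc, rotation_deg):
    """Evaluate the analytic footprint on a pixel grid; returns (values, mask)."""
    H, W = shape
    cy, cx = center_rc
    th = np.deg2rad(rotation_deg)
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]
    dx = cols - cx
    dy = rows - cy
    # foot frame: u lateral, w along the length; inverse of the +x-toe rotation
    u = np.cos(th) * dx + np.sin(th) * dy
    w = -np.sin(th) * dx + np.cos(th) * dy
    L = float(params.length_px)
    h = L / 3.0
    v = w + L / 2.0  # 0 at the toe tip, L at the heel end
    inside_len = (v >= 0.0) & (v < L)
    seg = np.clip(np.floor(v / h), 0, 2).astype(int)
    widths = params.widths
    Wseg = widths[seg]
    vv = v / h - seg
    b = np.abs(2.0 * vv - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(Wseg > 0, 2.0 * np.abs(u) / np.maximum(Wseg, 1e-300), np.inf)
    q = a**LOBE_EXPONENT + b**LOBE_EXPONENT
    mask = inside_len & (q <= 1.0)
    values = np.zeros(shape)
    values[mask] = params.peak_intensity * np.sqrt(1.0 - q[mask])
    return values, mask


def _footprint_radius(params: FootShapeParams) -> float:
    return float(np.hypot(params.length_px / 2.0, params.widths.max() / 2.0)) + 2.0


def _footprint_halfextents(params: FootShapeParams, rotation_deg) -> Tuple[float, float]:
    """Half-extents (rows, cols) of the rotated footprint's bounding box."""
    th = np.deg2rad(rotation_deg)
    hw = params.widths.max() / 2.0
    hl = params.length_px / 2.0
    half_c = abs(np.cos(th)) * hw + abs(np.sin(th)) * hl + 2.0
    half_r = abs(np.sin(th)) * hw + abs(np.cos(th)) * hl + 2.0
    return half_r, half_c


def _render_into(canvas_shape, params: FootShapeParams, center_rc, rotation_deg,
                 rng: Optional[np.random.Generator] = None):
    """Render a footprint into a canvas using only its bounding box."""
    H, W = canvas_shape
    cy, cx = center_rc
    hr, hc = _footprint_halfextents(params, rotation_deg)
    if cy - hr < -0.5 or cx - hc < -0.5 or cy + hr > H - 0.5 or cx + hc > W - 0.5:
        raise DimensionError(
            f"footprint (half-extents {hr:.0f}x{hc:.0f} px at ({cy:.0f}, {cx:.0f})) "
            f"exceeds canvas {canvas_shape}"
        )
    r0 = max(0, int(np.floor(cy - hr)))
    c0 = max(0, int(np.floor(cx - hc)))
    r1 = min(H, int(np.ceil(cy + hr)) + 1)
    c1 = min(W, int(np.ceil(cx + hc)) + 1)
    patch, pmask = _footprint_patch(params, (r1 - r0, c1 - c0), (cy - r0, cx - c0),
                                    rotation_deg)
    if params.noise_sigma > 0 and rng is not None:
        patch[pmask] += rng.normal(0.0, params.noise_sigma, size=int(pmask.sum()))
        np.clip(patch, 0.0, MAX_LEVEL, out=patch)
        pmask = patch > 0
    img = np.zeros(canvas_shape)
    mask = np.zeros(canvas_shape, dtype=bool)
    img[r0:r1, c0:c1] = patch
    mask[r0:r1, c0:c1] = pmask
    return img, mask


def _ground_truth_thirds(params: FootShapeParams):
    """Thirds-area ratio of the unrotated analytic mask (the arch-index target)."""
    pad = 4
    shape = (params.length_px + 2 * pad, int(np.ceil(params.widths.max())) + 2 * pad)
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    _, mask = _footprint_patch(params, shape, center, rotation_deg=0.0)
    r = np.nonzero(mask)[0]
    fore, mid, heel = footstat.thirds_counts(r)
    total = fore + mid + heel
    return (mid / total if total else 0.0), (fore, mid, heel)


def make_static_footprint(params: FootShapeParams, canvas: Tuple[int, int],
                          center: Optional[Tuple[float, float]] = None,
                          seed: int = 0) -> SyntheticFootprint:
    """Render a footprint and report its ground-truth thirds-area ratio.

    The ground truth is computed from the rendered (unrotated) mask with the
    same thirds-of-the-extent definition the arch-index analysis uses, so the
    round trip is exact in definition (discretization aside).  Raises
    :class:`DimensionError` when the rotated footprint exceeds the canvas.
    """
    H, W = canvas
    center_rc = ((H - 1) / 2.0, (W - 1) / 2.0) if center is None else (center[1], center[0])
    rng = np.random.default_rng(seed)
    img, mask = _render_into(canvas, params, center_rc, params.rotation_deg, rng)
    ratio, areas = _ground_truth_thirds(params)
    gt = {
        "arch_index": ratio,
        "areas": areas,
        "foot_class": footstat.classify_foot(ratio),
        "rotation_deg": params.rotation_deg,
        "params": dataclasses.asdict(params),
    }
    return SyntheticFootprint(image=PressureImage(img, meta={"generator": "footprint"}),
                              mask=mask, ground_truth=gt)


def tune_midfoot_fraction(base: FootShapeParams, target_ratio: float,
                          tol: float = 0.005, max_iter: int = 60) -> FootShapeParams:
    """Bisection on the midfoot width fraction to hit a target thirds ratio.

    The rendered-mask ratio is monotone in the fraction; raises
    :class:`ParameterError` when the target exceeds the reachable maximum for
    the given lobe widths.
    """
    def ratio_at(f):
        p = dataclasses.replace(base, midfoot_width_fraction=f)
        return _ground_truth_thirds(p)[0] if f > 0 else 0.0

    hi_ratio = ratio_at(1.0)
    if not 0.0 <= target_ratio <= hi_ratio:
        raise ParameterError(
            f"target ratio {target_ratio} unreachable (max {hi_ratio:.3f} at fraction 1)")
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        r = ratio_at(mid)
        if abs(r - target_ratio) <= tol:
            return dataclasses.replace(base, midfoot_width_fraction=mid)
        if r < target_ratio:
            lo = mid
        else:
            hi = mid
    return dataclasses.replace(base, midfoot_width_fraction=(lo + hi) / 2.0)


def make_platform_scene(canvas: Tuple[int, int] = (600, 720),
                        feet: Optional[Sequence[FootShapeParams]] = None,
                        centers_xy: Optional[Sequence[Tuple[float, float]]] = None,
                        background: float = 20.0, seed: int = 0) -> PressureImage:
    """A full-platform scene: two standing feet over a uniform paper background.

    The non-zero background emulates the residual glow of the glossy paper in
    the optical rig and keeps photometric equalization well-posed.
    """
    H, W = canvas
    if feet is None:
        feet = [
            dataclasses.replace(FootShapeParams(), rotation_deg=-4.0),
            dataclasses.replace(FootShapeParams(), rotation_deg=4.0),
        ]
    if centers_xy is None:
        centers_xy = [(W * 0.32, H * 0.5), (W * 0.68, H * 0.5)]
    img = np.full(canvas, float(background))
    for fp, (x, y) in zip(feet, centers_xy):
        rendered, _ = _render_into(canvas, fp, (y, x), fp.rotation_deg,
                                   np.random.default_rng(seed))
        img = np.maximum(img, rendered)
    return PressureImage(img, meta={"background": background, "generator": "scene"})


# ---------------------------------------------------------------------------
# Sway sequences
# ---------------------------------------------------------------------------

_SWAY_FOOT = FootShapeParams(length_px=90, forefoot_width_px=34, heel_width_px=24,
                             midfoot_width_fraction=0.5, peak_intensity=180.0)


def make_sway_sequence(params: SwayParams, foot: Optional[FootShapeParams] = None,
                       canvas: Tuple[int, int] = (200, 200)):
    """Standing-sway frames with a known COP ground truth.

    Each frame is the same footprint re-rendered at the base position plus an
    i.i.d. Gaussian offset with the requested covariance (the ellipse analysis
    only uses the marginal point cloud, so i.i.d. sampling gives a closed-form
    target).  Returns ``(frames, cop_xy)`` where ``cop_xy[t]`` is the rendered
    footprint centroid for frame ``t``; identical seeds give bit-identical
    sequences.
    """
    if params.n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    cov = params.covariance()
    foot = foot or _SWAY_FOOT
    H, W = canvas
    cx, cy = params.center if params.center else ((W - 1) / 2.0, (H - 1) / 2.0)
    rng = np.random.default_rng(params.seed)
    evals, evecs = np.linalg.eigh(cov)
    A = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    offsets = rng.standard_normal((params.n_frames, 2)) @ A.T  # (x, y)

    base_img, base_mask = _render_into(canvas, foot, (cy, cx), foot.rotation_deg)
    w = base_img[base_mask]
    r, c = np.nonzero(base_mask)
    centroid0 = np.array([(c * w).sum() / w.sum(), (r * w).sum() / w.sum()])

    frames = []
    for off in offsets:
        img, _ = _render_into(canvas, foot, (cy + off[1], cx + off[0]),
                              foot.rotation_deg)
        frames.append(PressureImage(img, meta={"generator": "sway"}))
    cop_gt = centroid0[None, :] + offsets
    return frames, cop_gt


# ---------------------------------------------------------------------------
# Gait sequences
# ---------------------------------------------------------------------------

def make_gait_sequence(foot: FootShapeParams, step_angles_deg: Sequence[float],
                       step_width_px: float = 30.0, frames_per_step: int = 6,
                       gap_rows: int = 30, threshold_fraction: float = 0.1,
                       canvas: Optional[Tuple[int, int]] = None):
    """A 1-3 step walking sequence with per-step ground truth.

    Consecutive footprints alternate laterally by ``step_width_px`` and advance
    ``length + gap_rows`` along the walkway; each step's total pressure follows
    a half-sine envelope (heel loading, full contact, toe-off), so every trace
    is unimodal.  Returns ``(frames, GaitGroundTruth)``; the ground-truth heel
    points and widths are computed from the rendered masks with the same heel
    definition the gait analysis uses.
    """
    angles = list(step_angles_deg)
    if not 1 <= len(angles) <= 3:
        raise ParameterError("supported sequences have 1-3 steps")
    if frames_per_step < 3:
        raise ParameterError("frames_per_step must be >= 3")
    n_steps = len(angles)
    advance = foot.length_px + gap_rows
    margin = int(_footprint_radius(foot)) + 4
    if canvas is None:
        H = (n_steps - 1) * advance + 2 * margin
        W = int(step_width_px) + 2 * margin
        canvas = (H, W)
    H, W = canvas
    cx = (W - 1) / 2.0
    centers = []
    for k in range(n_steps):
        row = H - margin - k * advance
        col = cx + (step_width_px / 2.0 if k % 2 else -step_width_px / 2.0)
        centers.append((row, col))

    imgs, masks = [], []
    for (row, col), ang in zip(centers, angles):
        p = dataclasses.replace(foot, rotation_deg=ang)
        img, mask = _render_into(canvas, p, (row, col), ang)
        imgs.append(img)
        masks.append(mask)
    for a, b in zip(masks, masks[1:]):
        if (a & b).any():
            raise LayoutError("consecutive footprints overlap; increase gap or width")

    T = frames_per_step
    env = np.sin(np.pi * (np.arange(T) + 0.5) / T)
    frames, traces = [], []
    for img in imgs:
        tr = []
        for wt in env:
            frames.append(PressureImage(img * wt, meta={"generator": "gait"}))
            tr.append(float(img.sum() * wt))
        traces.append(np.asarray(tr))

    rows = []
    for k, ((row, col), ang, mask) in enumerate(zip(centers, angles, masks)):
        rows.append({"step_index": k, "start": k * T, "end": (k + 1) * T,
                     "center_x": col, "center_y": row, "axis_angle_deg": ang})
    steps_df = pd.DataFrame(rows)

    peak = max(i.max() for i in imgs)
    thr_masks = [img >= threshold_fraction * peak for img in imgs]

    # per-pair ground truth uses the same pairwise walking direction the gait
    # analysis uses; the per-step heel column uses the overall walking direction
    pair_angles, pair_widths = [], []
    for k in range(n_steps - 1):
        pair_angles.append(gait._fold_angle(angles[k] - angles[k + 1]))
        d = (centers[k + 1][1] - centers[k][1], centers[k + 1][0] - centers[k][0])
        ha = gait.heel_point(thr_masks[k], d)
        hb = gait.heel_point(thr_masks[k + 1], d)
        pair_widths.append(float(np.hypot(hb[0] - ha[0], hb[1] - ha[1])))

    if n_steps > 1:
        global_d = (centers[-1][1] - centers[0][1], centers[-1][0] - centers[0][0])
    else:
        global_d = (0.0, -1.0)  # single step: walkway advances up the image
    for k, mask in enumerate(thr_masks):
        steps_df.loc[k, ["heel_x", "heel_y"]] = gait.heel_point(mask, global_d)

    return frames, GaitGroundTruth(steps=steps_df, pair_angles=pair_angles,
                                   pair_widths=pair_widths, traces=traces)


# ---------------------------------------------------------------------------
# Camera tiles
# ---------------------------------------------------------------------------

def _default_cameras(shape, overlap_px: int) -> Dict[str, CameraModel]:
    H, W = shape
    H2, W2 = H // 2, W // 2
    return {
        "UL": CameraModel(tile_origin=(0, 0)),
        "UR": CameraModel(tile_origin=(0, W2 - overlap_px)),
        "LL": CameraModel(tile_origin=(H2 - overlap_px, 0)),
        "LR": CameraModel(tile_origin=(H2 - overlap_px, W2 - overlap_px)),
    }


def _draw_dot(img: np.ndarray, r0: float, c0: float, amplitude: float,
              sigma: float = 1.2, radius: int = 4) -> None:
    H, W = img.shape
    rlo, rhi = max(0, int(r0) - radius), min(H, int(r0) + radius + 1)
    clo, chi = max(0, int(c0) - radius), min(W, int(c0) + radius + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi].astype(float)
    patch = amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    img[rlo:rhi, clo:chi] = np.maximum(img[rlo:rhi, clo:chi], patch)


def split_into_tiles(full, cameras: Optional[Dict[str, CameraModel]] = None,
                     overlap_px: int = 16, n_landmarks: int = 4, seed: int = 0,
                     dot_level: float = 200.0):
    """Split a full-platform image into four distorted camera tiles.

    Star/circle registration landmarks are drawn as bright Gaussian dots into
    the overlap strips before cropping; each tile is then cropped at its
    camera's origin, photometrically distorted (gain, offset, clipped to the
    8-bit range) and forward radially distorted.  Returns ``(tiles, landmark
    table, dotted full image)`` — the dotted image is the round-trip reference.
    The landmark table lists exact coordinates in each tile's undistorted
    frame (and in the column-composite frames for the left-right pair).
    """
    data = full.data if isinstance(full, PressureImage) else np.asarray(full, dtype=float)
    H, W = data.shape
    if overlap_px < 2:
        raise ParameterError("overlap_px must be >= 2")
    if n_landmarks < 1:
        raise ParameterError("n_landmarks must be >= 1")
    cams = cameras or _default_cameras(data.shape, overlap_px)
    if set(cams) != set(mosaic.TILE_IDS):
        raise CoverageError(f"need cameras {mosaic.TILE_IDS}, got {sorted(cams)}")
    H2, W2 = H // 2, W // 2
    extents = {
        "UL": ((0, H2 + overlap_px), (0, W2 + overlap_px)),
        "UR": ((0, H2 + overlap_px), (W2 - overlap_px, W)),
        "LL": ((H2 - overlap_px, H), (0, W2 + overlap_px)),
        "LR": ((H2 - overlap_px, H), (W2 - overlap_px, W)),
    }
    origins = {tid: (extents[tid][0][0], extents[tid][1][0]) for tid in extents}
    for tid, cam in cams.items():
        if cam.tile_origin is not None and tuple(cam.tile_origin) != origins[tid]:
            raise DimensionError(
                f"camera {tid} origin {cam.tile_origin} does not match the 2x2 layout "
                f"{origins[tid]}; tiles would not cover the full image")

    rng = np.random.default_rng(seed)
    m = 6  # keep dots away from strip borders
    strips = {
        "UL-LL": ((H2 - overlap_px + m, H2 + overlap_px - m), (m, W2 - m)),
        "UR-LR": ((H2 - overlap_px + m, H2 + overlap_px - m), (W2 + m, W - m)),
        "L-R": ((m, H - m), (W2 - overlap_px + m, W2 + overlap_px - m)),
    }
    dotted = data.copy()
    landmark_rows = []
    pair_frames = {"UL-LL": ("UL", "LL"), "UR-LR": ("UR", "LR"), "L-R": ("L", "R")}
    frame_origins = dict(origins)
    frame_origins["L"] = (0, 0)            # left column composite inherits UL
    frame_origins["R"] = origins["UR"]     # right column composite inherits UR
    for pair, ((rlo, rhi), (clo, chi)) in strips.items():
        pr = rng.uniform(rlo, rhi, size=n_landmarks)
        pc = rng.uniform(clo, chi, size=n_landmarks)
        ta, tb = pair_frames[pair]
        oa, ob = frame_origins[ta], frame_origins[tb]
        for r0, c0 in zip(pr, pc):
            _draw_dot(dotted, r0, c0, dot_level)
            landmark_rows.append({
                "pair": pair, "tile_a": ta, "row_a": r0 - oa[0], "col_a": c0 - oa[1],
                "tile_b": tb, "row_b": r0 - ob[0], "col_b": c0 - ob[1],
            })
    landmarks = pd.DataFrame(landmark_rows)

    tiles = {}
    for tid, ((rlo, rhi), (clo, chi)) in extents.items():
        cam = cams[tid]
        crop = dotted[rlo:rhi, clo:chi]
        photo = np.clip(cam.contrast_gain * crop + cam.intensity_offset, 0.0, MAX_LEVEL)
        captured = mosaic.radial_distort_image(photo, cam.k1, cam.k2)
        cam_with_origin = dataclasses.replace(cam, tile_origin=(rlo, clo))
        tiles[tid] = RawTile(captured, tid, cam_with_origin)
    return tiles, landmarks, PressureImage(dotted, meta={"generator": "tiles"})


def landmark_pairs(landmarks: pd.DataFrame, pair: str) -> np.ndarray:
    """Extract ((row_a, col_a), (row_b, col_b)) pairs for one tile pair."""
    sub = landmarks[landmarks["pair"] == pair]
    return np.stack([sub[["row_a", "col_a"]].to_numpy(dtype=float),
                     sub[["row_b", "col_b"]].to_numpy(dtype=float)], axis=1)


# ---------------------------------------------------------------------------
# Feature populations
# ---------------------------------------------------------------------------

def make_subject_population(params: PopulationParams) -> pd.DataFrame:
    """Table of (subject_id, trial_id, six features) for biometric evaluation.

    Subject means are drawn around the population centers with ``between_sd``;
    each trial jitters the mean with ``within_sd``.  Deterministic under seed.
    """
    if params.n_subjects < 2 or params.n_trials < 1:
        raise ParameterError("need n_subjects >= 2 and n_trials >= 1")
    within = params.resolved_within()
    between = np.asarray(params.between_sd, dtype=float)
    centers = np.asarray(params.centers, dtype=float)
    rng = np.random.default_rng(params.seed)
    means = centers + rng.standard_normal((params.n_subjects, 6)) * between
    rows = []
    from .biometrics import FEATURE_COLUMNS
    for s in range(params.n_subjects):
        for t in range(params.n_trials):
            feats = means[s] + rng.standard_normal(6) * within
            row = {"subject_id": s, "trial_id": t}
            row.update(dict(zip(FEATURE_COLUMNS, feats)))
            rows.append(row)
    return pd.DataFrame(rows)
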