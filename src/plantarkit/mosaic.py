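"""Assemble four camera tiles into one seamless full-platform pressure image.

The optical rig observes the platform with four cameras (tiles ``UL``, ``UR``,
``LL``, ``LR``).  Producing one image requires four steps: (i) radial distortion
correction, (ii) intensity/contrast equalization between cameras, (iii) landmark
registration and stitching of the vertical pairs, and (iv) stitching the two
columns, blending every overlap with complementary hyperbolic-tangent weights so
no junction line remains.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import SimilarityTransform

from .core import (
    CoverageError,
    DegenerateContrastError,
    DistortionModelError,
    PlantarKitError,
    PressureImage,
    RegistrationError,
    StitchError,
    as_array,
)

__all__ = [
    "CameraModel",
    "RawTile",
    "PlanarTransform",
    "BlendWeights",
    "hyperbolic_weights",
    "invert_radial",
    "radial_distort_image",
    "undistort",
    "equalize_intensity",
    "equalize_contrast",
    "estimate_transform",
    "stitch",
    "mosaic_four",
]

TILE_IDS = ("UL", "UR", "LL", "LR")


@dataclass(frozen=True)
class CameraModel:
    """Radial distortion + photometric model of one camera.

    ``k1 = k2 = 0``, ``intensity_offset = 0``, ``contrast_gain = 1`` is an
    identity observer.  ``tile_origin`` is the (row, col) of the tile's top-left
    corner in the full mosaic frame.
    """

    k1: float = 0.0
    k2: float = 0.0
    intensity_offset: float = 0.0
    contrast_gain: float = 1.0
    tile_origin: Optional[tuple] = None

    def __post_init__(self):
        if not np.isfinite([self.k1, self.k2, self.intensity_offset, self.contrast_gain]).all():
            raise DistortionModelError("camera coefficients must be finite")
        if not self.contrast_gain > 0:
            raise DistortionModelError("contrast_gain must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.k1 == 0.0
            and self.k2 == 0.0
            and self.intensity_offset == 0.0
            and self.contrast_gain == 1.0
        )


@dataclass
class RawTile:
    """Pixels captured by one camera, tagged with its id and camera model."""

    pixels: np.ndarray
    tile_id: str
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self):
        self.pixels = as_array(self.pixels)


# ---------------------------------------------------------------------------
# Radial distortion: r_d = r_u (1 + k1 r_u^2 + k2 r_u^4) in coordinates
# normalized by the half-diagonal about the tile center.
# ---------------------------------------------------------------------------

def _center_and_scale(shape):
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    return cy, cx, float(np.hypot(cy, cx))


def _check_invertible(k1: float, k2: float, r_max: float = 1.05) -> None:
    r = np.linspace(0.0, r_max, 256)
    deriv = 1.0 + 3.0 * k1 * r**2 + 5.0 * k2 * r**4
    if np.any(deriv <= 0):
        raise DistortionModelError(
            f"radial model with k1={k1}, k2={k2} is not monotone within the image extent"
        )


def invert_radial(r_d, k1: float, k2: float, tol: float = 1e-9, max_iter: int = 50):
    """Solve ``r_d = r_u (1 + k1 r_u^2 + k2 r_u^4)`` for ``r_u`` by Newton iteration.

    Vectorized over ``r_d``; converges in a handful of iterations for the small
    coefficients typical of webcam optics.
    """
    _check_invertible(k1, k2)
    r_d = np.asarray(r_d, dtype=float)
    r_u = r_d.copy()
    for _ in range(max_iter):
        f = r_u * (1.0 + k1 * r_u**2 + k2 * r_u**4) - r_d
        fp = 1.0 + 3.0 * k1 * r_u**2 + 5.0 * k2 * r_u**4
        step = f / fp
        r_u = r_u - step
        if np.max(np.abs(step)) < tol:
            break
    return r_u


def _radial_warp(img: np.ndarray, radius_map) -> np.ndarray:
    """Resample ``img`` so output radius r maps to input radius ``radius_map(r)``."""
    h, w = img.shape
    cy, cx, scale = _center_and_scale(img.shape)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dy = (rows - cy) / scale
    dx = (cols - cx) / scale
    r = np.hypot(dy, dx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(r > 0, radius_map(r) / np.maximum(r, 1e-300), 1.0)
    src_r = cy + dy * ratio * scale
    src_c = cx + dx * ratio * scale
    return map_coordinates(img, [src_r, src_c], order=1, mode="nearest")


def radial_distort_image(img, k1: float, k2: float = 0.0) -> np.ndarray:
    """Forward-distort an ideal image (simulating what the camera captures).

    The captured pixel at distorted radius ``r_d`` shows the ideal content at
    ``r_u = f^{-1}(r_d)``, found by Newton inversion; bilinear resampling.
    """
    img = as_array(img)
    if k1 == 0.0 and k2 == 0.0:
        return img.copy()
    return _radial_warp(img, lambda r: invert_radial(r, k1, k2))


def undistort(tile: RawTile) -> RawTile:
    """Correct barrel / pin-cushion distortion of a raw tile.

    Output pixel at undistorted radius ``r_u`` samples the raw tile at the
    forward-model radius ``r_d = r_u (1 + k1 r_u^2 + k2 r_u^4)``, bilinearly.
    Identity when ``k1 = k2 = 0`` (pixels returned unchanged).
    """
    cam = tile.camera
    if cam.k1 == 0.0 and cam.k2 == 0.0:
        return RawTile(tile.pixels.copy(), tile.tile_id, cam)
    _check_invertible(cam.k1, cam.k2)
    out = _radial_warp(tile.pixels, lambda r: r * (1.0 + cam.k1 * r**2 + cam.k2 * r**4))
    return RawTile(out, tile.tile_id, cam)


# ---------------------------------------------------------------------------
# Photometric equalization
# ---------------------------------------------------------------------------

def equalize_intensity(a, b, mask_a=None, mask_b=None, level_range=(0.0, 255.0)):
    """Match the mean intensity of ``b`` to that of ``a``.

    Returns ``(a, b_shifted, offset)`` with ``offset = mean(a) - mean(b)``;
    ``b`` is shifted by the offset and clipped to ``level_range``.  Optional
    masks restrict the statistics (not the application) to a sub-region, e.g.
    the registered overlap between two cameras.
    """
    a = as_array(a)
    b = as_array(b)
    if a.size == 0 or b.size == 0:
        raise DimensionError("equalize_intensity needs non-empty images")
    va = a[mask_a] if mask_a is not None else a
    vb = b[mask_b] if mask_b is not None else b
    offset = float(np.mean(va) - np.mean(vb))
    shifted = np.clip(b + offset, level_range[0], level_range[1])
    return a, shifted, offset


def _stretch(img, src_lo, src_hi, dst_lo, dst_hi):
    return (img - src_lo) * ((dst_hi - dst_lo) / (src_hi - src_lo)) + dst_lo


def equalize_contrast(a, b, mask_a=None, mask_b=None, target: str = "union"):
    """Linearly remap both images so their minima and maxima coincide.

    ``target="union"`` (default) stretches both to the union of the two ranges;
    ``target="first"`` remaps only ``b`` onto ``a``'s range, leaving ``a``
    untouched.  Statistics may be restricted to masks; the remap is applied to
    the whole images.  A constant image raises :class:`DegenerateContrastError`.
    """
    a = as_array(a)
    b = as_array(b)
    va = a[mask_a] if mask_a is not None else a
    vb = b[mask_b] if mask_b is not None else b
    a_lo, a_hi = float(va.min()), float(va.max())
    b_lo, b_hi = float(vb.min()), float(vb.max())
    if a_hi <= a_lo or b_hi <= b_lo:
        raise DegenerateContrastError("contrast stretching undefined for a constant image")
    if target == "union":
        lo, hi = min(a_lo, b_lo), max(a_hi, b_hi)
        a_out = a if (a_lo == lo and a_hi == hi) else _stretch(a, a_lo, a_hi, lo, hi)
        b_out = b if (b_lo == lo and b_hi == hi) else _stretch(b, b_lo, b_hi, lo, hi)
    elif target == "first":
        a_out = a
        b_out = _stretch(b, b_lo, b_hi, a_lo, a_hi)
    else:
        raise ValueError(f"unknown contrast target {target!r}")
    return a_out, b_out


# ---------------------------------------------------------------------------
# Landmark registration
# ---------------------------------------------------------------------------

@dataclass
class PlanarTransform:
    """Similarity transform (scale, rotation, translation) between tile frames.

    Maps (row, col) points of the *moving* tile into the *base* tile frame.
    Internally an ``(x, y)`` homogeneous matrix; exposed parameters follow the
    scikit-image similarity convention.
    """

    matrix: np.ndarray
    residual: float = 0.0

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, scale: float = 1.0, rotation_deg: float = 0.0,
                    translation_rc=(0.0, 0.0)) -> "PlanarTransform":
        if not scale > 0:
            raise RegistrationError("scale must be positive")
        tf = SimilarityTransform(
            scale=scale,
            rotation=np.deg2rad(rotation_deg),
            translation=(translation_rc[1], translation_rc[0]),  # (x, y)
        )
        return cls(tf.params.copy())

    @property
    def _tf(self) -> SimilarityTransform:
        return SimilarityTransform(matrix=self.matrix)

    @property
    def scale(self) -> float:
        return float(self._tf.scale)

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(self._tf.rotation))

    @property
    def translation_rc(self):
        t = self._tf.translation
        return (float(t[1]), float(t[0]))

    def apply_rc(self, points_rc) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        xy = pts[:, ::-1]
        out = self._tf(xy)
        return out[:, ::-1]

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix), self.residual)

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return PlanarTransform(self.matrix @ other.matrix)


def _pairs_to_arrays(pairs):
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 3 and arr.shape[1:] == (2, 2):
        return arr[:, 0, :], arr[:, 1, :]
    if arr.ndim == 2 and arr.shape[1] == 4:
        return arr[:, :2], arr[:, 2:]
    raise RegistrationError(f"cannot interpret landmark pairs of shape {arr.shape}")


def estimate_transform(pairs) -> PlanarTransform:
    """Least-squares similarity transform from matched landmarks.

    ``pairs`` is a sequence of ``((row, col) in base tile, (row, col) in moving
    tile)``; the returned transform maps moving-tile coordinates into the base
    tile frame.  At least two non-coincident pairs are required.
    """
    a_rc, b_rc = _pairs_to_arrays(pairs)
    if len(a_rc) < 2:
        raise RegistrationError("at least 2 landmark pairs are required")
    if np.ptp(b_rc, axis=0).max() == 0 or np.ptp(a_rc, axis=0).max() == 0:
        raise RegistrationError("landmarks are coincident; transform is underdetermined")
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(b_rc[:, ::-1], a_rc[:, ::-1])
        ok = bool(tf)
    else:  # scikit-image < 0.26
        tf = SimilarityTransform()
        ok = tf.estimate(src=b_rc[:, ::-1], dst=a_rc[:, ::-1])
    if not ok or not np.all(np.isfinite(tf.params)):
        raise RegistrationError("similarity estimation failed for the given landmarks")
    out = PlanarTransform(tf.params.copy())
    resid = out.apply_rc(b_rc) - a_rc
    out.residual = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return out


# ---------------------------------------------------------------------------
# Seam blending and stitching
# ---------------------------------------------------------------------------

@dataclass
class BlendWeights:
    """Complementary seam weights over the overlap span: ``Hl(i) + Hr(i) = 1``."""

    Hl: np.ndarray
    Hr: np.ndarray
    steepness: float
    center: float

    def __post_init__(self):
        self.Hl = np.asarray(self.Hl, dtype=float)
        self.Hr = np.asarray(self.Hr, dtype=float)
        if self.Hl.shape != self.Hr.shape:
            raise DimensionError("Hl and Hr must have equal length")


def hyperbolic_weights(n: int, steepness: Optional[float] = None,
                       center: Optional[float] = None) -> BlendWeights:
    """Hyperbolic-tangent seam weights over an overlap of ``n`` samples.

    ``Hl(i) = (1 - tanh((i - c)/s)) / 2`` and ``Hr = 1 - Hl`` so the pair is an
    exact partition of unity; the default steepness is ``n / 6``.
    """
    if n < 1:
        raise StitchError("overlap span must contain at least one sample")
    c = (n - 1) / 2.0 if center is None else float(center)
    s = max(n / 6.0, 1e-9) if steepness is None else float(steepness)
    if not s > 0:
        raise StitchError("steepness must be positive")
    i = np.arange(n, dtype=float)
    Hl = 0.5 * (1.0 - np.tanh((i - c) / s))
    return BlendWeights(Hl=Hl, Hr=1.0 - Hl, steepness=s, center=c)


def _warp_to_canvas(base: np.ndarray, moving: np.ndarray, t: PlanarTransform):
    """Warp ``moving`` into the base frame on a union canvas.

    Returns ``(base_canvas, mov_canvas, base_mask, mov_mask, origin_rc)`` where
    ``origin_rc`` is the canvas position of the base frame's (0, 0).
    """
    hb, wb = base.shape
    hm, wm = moving.shape
    corners = np.array([[0, 0], [0, wm - 1], [hm - 1, 0], [hm - 1, wm - 1]], dtype=float)
    tc = t.apply_rc(corners)
    tol = 1e-6  # absorb float round-off so near-integer extents stay integral
    r0 = int(np.floor(min(0.0, tc[:, 0].min()) + tol))
    c0 = int(np.floor(min(0.0, tc[:, 1].min()) + tol))
    r1 = int(np.ceil(max(hb - 1.0, tc[:, 0].max()) - tol))
    c1 = int(np.ceil(max(wb - 1.0, tc[:, 1].max()) - tol))
    H, W = r1 - r0 + 1, c1 - c0 + 1

    base_canvas = np.zeros((H, W))
    base_mask = np.zeros((H, W), dtype=bool)
    base_canvas[-r0:-r0 + hb, -c0:-c0 + wb] = base
    base_mask[-r0:-r0 + hb, -c0:-c0 + wb] = True

    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    pts = np.column_stack([(rows + r0).ravel(), (cols + c0).ravel()])
    src = t.inverse().apply_rc(pts)
    src_r = src[:, 0].reshape(H, W)
    src_c = src[:, 1].reshape(H, W)
    eps = 1e-9
    mov_mask = (
        (src_r >= -eps) & (src_r <= hm - 1 + eps) & (src_c >= -eps) & (src_c <= wm - 1 + eps)
    )
    # clip in-range coordinates onto the valid grid so float round-off at the
    # border does not fall outside and pick up the constant fill value
    src_r = np.clip(src_r, 0.0, hm - 1.0)
    src_c = np.clip(src_c, 0.0, wm - 1.0)
    mov_canvas = map_coordinates(moving, [src_r, src_c], order=1, mode="constant", cval=0.0)
    mov_canvas[~mov_mask] = 0.0
    return base_canvas, mov_canvas, base_mask, mov_mask, (r0, c0)


def _blend_profile(length: int, span, moving_on_positive_side: bool,
                   blend: Optional[BlendWeights]) -> np.ndarray:
    """Base-image weight along the seam axis over the whole canvas length."""
    lo, hi = span
    n = hi - lo + 1
    w = np.empty(length)
    if blend is not None and len(blend.Hl) == n:
        hl = blend.Hl
    else:
        s = blend.steepness if blend is not None else None
        hl = hyperbolic_weights(n, steepness=s).Hl
    if moving_on_positive_side:
        w[:lo] = 1.0
        w[lo:hi + 1] = hl
        w[hi + 1:] = 0.0
    else:
        w[:lo] = 0.0
        w[lo:hi + 1] = hl[::-1]
        w[hi + 1:] = 1.0
    return w


def _equalize_on_overlap(base_c, mov_c, overlap):
    """Photometrically match the moving image to the base on their overlap.

    Intensity offset first (mean matching), then a contrast stretch of the
    moving image onto the base's overlap range.  Exact whenever the overlap
    attains the scene's extreme levels in both views.
    """
    bvals = base_c[overlap]
    mvals = mov_c[overlap]
    mov_c = mov_c + (float(bvals.mean()) - float(mvals.mean()))
    mvals = mov_c[overlap]
    b_lo, b_hi = float(bvals.min()), float(bvals.max())
    m_lo, m_hi = float(mvals.min()), float(mvals.max())
    if b_hi > b_lo and m_hi > m_lo:
        mov_c = _stretch(mov_c, m_lo, m_hi, b_lo, b_hi)
    return mov_c


def _stitch_arrays(base, moving, t, blend=None, photometric=False):
    base_c, mov_c, base_mask, mov_mask, origin = _warp_to_canvas(base, moving, t)
    overlap = base_mask & mov_mask
    if overlap.sum() < 2:
        raise StitchError("transformed moving image overlaps base by fewer than 2 px")
    if photometric:
        mov_c = _equalize_on_overlap(base_c, mov_c, overlap)
        mov_c[~mov_mask] = 0.0

    # seam axis: the direction along which the two images are displaced most
    br, bc = np.nonzero(base_mask)
    mr, mc = np.nonzero(mov_mask)
    d_axis0 = mr.mean() - br.mean()
    d_axis1 = mc.mean() - bc.mean()
    axis = 0 if abs(d_axis0) >= abs(d_axis1) else 1
    positive = (d_axis0 if axis == 0 else d_axis1) >= 0

    along = np.nonzero(overlap.any(axis=1 - axis))[0]
    span = (int(along.min()), int(along.max()))
    profile = _blend_profile(base_c.shape[axis], span, positive, blend)
    wb = profile[:, None] if axis == 0 else profile[None, :]
    w_base = np.where(base_mask, wb, 0.0) * base_mask
    w_mov = np.where(mov_mask, 1.0 - wb, 0.0) * mov_mask
    total = w_base + w_mov
    covered = total > 0
    out = np.zeros_like(base_c)
    out[covered] = (w_base * base_c + w_mov * mov_c)[covered] / total[covered]
    return out, origin


def stitch(base, moving, t: PlanarTransform, blend: Optional[BlendWeights] = None,
           photometric: bool = False) -> np.ndarray:
    """Stitch ``moving`` onto ``base`` using transform ``t`` and seam blending.

    The canvas expands to the union extent; the overlap is combined as
    ``Hl * base + Hr * moving`` along the seam axis, and single-coverage
    regions are copied.  With ``photometric=True`` the moving image is first
    intensity/contrast matched to the base on the registered overlap.
    """
    out, _ = _stitch_arrays(as_array(base), as_array(moving), t, blend, photometric)
    return out


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except PlantarKitError as e:
        raise type(e)(f"[{name}] {e}") from e


def mosaic_four(tiles: Sequence[RawTile], landmarks: dict,
                blend: Optional[BlendWeights] = None,
                photometric: bool = True) -> PressureImage:
    """Full four-tile pipeline: undistort, equalize, stitch columns, stitch rows.

    Parameters
    ----------
    tiles:
        Four :class:`RawTile` with ids ``UL, UR, LL, LR``.
    landmarks:
        Mapping with keys ``"UL-LL"``, ``"UR-LR"`` and ``"L-R"``; each value is
        a landmark pair list as accepted by :func:`estimate_transform`, with
        the first-named tile (or the left column composite) as the base frame.
        The left-right pairs are expressed in the column composites' frames
        (which inherit the UL / UR origins).
    """
    by_id = {t.tile_id: t for t in tiles}
    if set(by_id) != set(TILE_IDS) or len(tiles) != 4:
        raise CoverageError(f"need exactly tiles {TILE_IDS}, got {[t.tile_id for t in tiles]}")
    for key in ("UL-LL", "UR-LR", "L-R"):
        if key not in landmarks:
            raise RegistrationError(f"missing landmark set {key!r}")

    with _stage("undistort"):
        und = {tid: undistort(by_id[tid]).pixels for tid in TILE_IDS}
    with _stage("register"):
        t_ll = estimate_transform(landmarks["UL-LL"])
        t_lr = estimate_transform(landmarks["UR-LR"])
        t_col = estimate_transform(landmarks["L-R"])
    with _stage("stitch-columns"):
        left, o_left = _stitch_arrays(und["UL"], und["LL"], t_ll, blend, photometric)
        right, o_right = _stitch_arrays(und["UR"], und["LR"], t_lr, blend, photometric)
    with _stage("stitch-mosaic"):
        # re-express the L-R transform in the composite canvases' coordinates
        shift_l = PlanarTransform.from_params(translation_rc=(-o_left[0], -o_left[1]))
        shift_r = PlanarTransform.from_params(translation_rc=(o_right[0], o_right[1]))
        t_adj = shift_l.compose(t_col).compose(shift_r)
        full, _ = _stitch_arrays(left, right, t_adj, blend, photometric)
    return PressureImage(full, meta={"stages": ["undistort", "equalize+stitch"],
                                     "photometric": photometric})
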