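# Methods

This note records the models, conventions and numerical choices behind
`plantarkit`, and what the synthetic phantoms do and do not establish about
real optical plantar-pressure data.

## Coordinate and angle conventions

Images are `[row, col]` arrays, origin top-left, 0-based, half-open extents.
User-facing points are `(x, y) = (col, row)`: `x` is the platform's
medial–lateral axis, `y` the anterior–posterior axis (increasing down the
image). Foot-axis angles are measured from the image vertical in degrees,
folded into `(−90, 90]`, positive tilting the toe towards `+x`. Ellipse
orientations are measured from `+x`. These conventions are pinned because
step-angle arithmetic and landmark files are meaningless without them.

## Mosaicking

**Radial distortion.** The Brown radial model
`r_d = r_u (1 + k1 r_u² + k2 r_u⁴)` in coordinates normalized by the
half-diagonal about the tile center. Undistortion samples the raw tile at the
forward-mapped radius with bilinear interpolation; the phantom's forward
distortion needs the *inverse* mapping, solved per radius by Newton iteration
(tolerance 1e-9, ≤ 50 iterations). Models whose derivative
`1 + 3k1 r² + 5k2 r⁴` changes sign inside the image are rejected as
non-invertible. Distortion coefficients are accepted as known; estimating
them from chessboards is out of scope.

**Registration.** A similarity transform (scale, rotation, translation) is
estimated from manually provided landmark pairs by least squares (Umeyama,
via scikit-image). Similarity rather than affine/projective: the cameras
share intrinsics and differ essentially by translation, and the
better-conditioned 4-dof model recovers noiseless transforms to machine
precision. At least two non-coincident pairs are required.

**Photometric equalization.** The standalone operations follow the classic
recipe: intensity offset = difference of means, then contrast stretching onto
the union range. Inside `mosaic_four`, however, the statistics are computed
**on the registered overlap region only**, and the moving image is stretched
onto the *reference* tile's overlap range. Rationale: the two cameras see the
same physical content only in the overlap; whole-image means differ whenever
content differs, so whole-image matching would shift pixels even for
identical cameras, and the union-range target would let one camera's gain
distort the already-correct reference. With overlap statistics, identity
cameras round-trip exactly and affine photometric distortions are inverted
exactly whenever the overlap attains the scene's extreme levels — which the
phantom guarantees by placing bright landmark dots in every overlap strip
over a non-zero paper background. The equalization order (intensity, then
contrast) is preserved.

**Seam blending.** `Hl(i) = (1 − tanh((i − c)/s))/2`, `Hr = 1 − Hl` over the
overlap span; `s` defaults to span/6, `c` to the span center. Computing `Hr`
as the complement makes the partition of unity exact in floating point. The
seam axis is chosen as the axis of larger displacement between the two
images; pixels covered by only one image are copied with renormalized
weights.

**Pipeline order** is undistort → register → equalize → blend, per column
pair (UL+LL, UR+LR) and then across columns; error messages are annotated
with the failing stage.

## Calibration

Reference weights give `(intensity, pressure)` points with `P = mg/A`;
`g = 9.81 m/s²` by default and configurable. Ordinary least squares (via
`scipy.stats.linregress`) with `R² = 1 − SS_res/SS_tot` from the residuals.
Fewer than three points produce a warning (the fit is exact by
construction); a single distinct intensity is a rank error. The circular-ROI
mean intensity is supplied externally (CSV); ROI detection is not modeled.
Negative calibrated pressures clip to zero with a reported count.

## Posture balance

The COP of a frame is the intensity-weighted centroid of pixels at or above
`threshold_fraction` (default 0.1) of the frame maximum — justified by the
platform's linear intensity–pressure response. The trajectory is re-expressed
relative to either the image center (the plotting convention) or the
trajectory centroid (default for PBI, making the index independent of where
the subject stands). Points within the q-th percentile (default 95, linear
interpolation between order statistics) of distance to the origin are kept;
a covariance ellipse is fitted (center = mean, orientation = leading
eigenvector, population covariance with ddof 0) and

* `chi2_95` convention (default): radii `√(χ²₂,₀.₉₅ · eigenvalue)` with
  `χ²₂,₀.₉₅ ≈ 5.991`, the 95% coverage ellipse of a Gaussian cloud;
* `enclosing` convention: radii = maximum absolute projections of the
  retained points on the principal axes.

`PBI = 1/(a·b)`, units px⁻² (mm⁻² with a pixel scale). PBI values are
convention-dependent; every report records the convention, and cross-study
comparison requires matching conventions. Near-collinear clouds (minor
eigenvalue < 1e-10 of the major) raise a degenerate-ellipse error carrying
the eigenvalues; isotropic clouds are fitted but flagged orientation-unstable.

## Static foot features

Feet are segmented as the largest (≤ 2) connected components of the
supra-threshold mask, sides assigned by centroid `x`. The principal axis is a
pressure-weighted covariance ellipse over pixels whose pressure lies within
2 SD of the mean (≈ 95% retention); the foot angle is the major axis against
the vertical, with isotropic feet reporting 0 and an instability flag. For
the arch index the contact-pixel *coordinates* are rotated by the measured
angle (continuous rotation, no resampling), the extent is split into equal
thirds, and areas are pixel counts — "area" means contact area, not
pressure-weighted mass. Toes are included in the foot length (the classical
Cavanagh index truncates them; this divergence is deliberate and flagged).
Classification: flat at arch index ≥ 0.26, high-arch at ≤ 0.21, normal
strictly between; the boundary values follow the inclusive inequalities of
the clinical thresholds. The contact threshold (0.1 of maximum) is a
documented choice; arch indices shift slightly with it.

## Gait features

A step is a maximal run of frames whose supra-threshold contact regions
overlap frame-to-frame (threshold relative to the sequence maximum); contact
jumping to a disjoint location starts a new step, and runs shorter than
`min_frames` (default 2) are dropped. The step footprint is the pixelwise
maximum over the run (full contact extent for geometry); the pixelwise mean
is kept for pressure summaries. The heel point is the contact pixel with the
smallest projection onto the walking direction (the vector between
consecutive step centroids) — an orientation-free reading of "the lowest
point". Step angle = |difference of axis angles| folded into [0, 90]; step
width = Euclidean heel distance; both are averaged over consecutive pairs
for the trial-level feature vector. Pressure traces are linearly
time-normalized to `n_resample` (default 100) samples before Pearson
correlation, the minimal alignment for trials of different durations; the
enrollment reference is the mean of the trial's z-scored normalized traces.

## Biometric evaluation

The six features carry incommensurate units (index, degrees, pixels), so a
mean-squared-difference score is only meaningful after per-feature min–max
normalization over the enrollment gallery (probes clip to [0, 1] with a
count). Fusion is the weighted concatenation `S = [2α·Fd, 2(1−α)·Fs]`; the
factor 2 makes α = 0.5 reproduce the plain `[Fd, Fs]` concatenation
bit-for-bit. α = 1 keeps only dynamic features (the shoe-wearing case).
Matching score = `1 − mean((s−t)²)`, which is 1 for identical templates and
stays in [0, 1] for normalized inputs. The ROC sweeps every distinct
observed score plus ±∞ endpoints (exact step function, no binning); ties
share a threshold and contribute diagonal segments, so the trapezoidal AUC
equals the Mann–Whitney statistic with the half-tie convention. The EER is
the interpolated operating point where the false match rate equals the false
non-match rate — algebraically the intersection of the ROC with the
anti-diagonal `TMR = 1 − FMR`.

## Synthetic phantoms: what they emulate and what they do not

**Footprints** are three stacked super-ellipse lobes (forefoot, midfoot
band, heel; exponent 6) with a smooth `√(1−q)` pressure falloff. The lobes
are congruent up to width, so equal widths give an arch index of exactly 1/3
and the midfoot width fraction controls the thirds ratio monotonically —
enabling bisection to any reachable target ratio. The default foot
(180 px long, 64/44 px forefoot/heel widths, peak level 180) is sized to the
platform's ~0.5 mm/px scale; grids that need arch indices up to 0.40 narrow
the heel to 26 px, since the reachable maximum is `1/(2 + W_heel/W_fore)`.

**Sway** draws i.i.d. Gaussian COP offsets with the requested covariance
(not a random walk): the PBI analysis uses only the marginal point cloud, so
i.i.d. sampling gives a closed-form target covariance. Each frame re-renders
the footprint analytically at the offset position, so the ground-truth COP
is exact up to pixel discretization (< 0.1 px in practice).

**Gait** places 1–3 footprints alternating laterally by `step_width_px` and
advancing by `length + gap` along the walkway, with a half-sine loading
envelope per step (unimodal trace). Ground-truth heels and widths are
computed from the rendered masks with the *same* heel definition the gait
module uses, so round trips compare like with like; the per-pair widths use
the pairwise walking direction (the analysis convention), the per-step table
the overall direction.

**Camera tiles** crop the full scene in a 2×2 layout with `overlap_px`
margins, apply gain/offset (clipped to 8 bit), and forward radial
distortion. Landmark dots (level 200, σ ≈ 1.2 px Gaussians) are drawn into
the overlap strips before cropping, and the scene has a non-zero background
(level 20, the paper's residual glow), anchoring each tile's extremes so
contrast equalization is exactly invertible.

**Populations** draw per-subject feature means around realistic centers
(arch index 0.23, foot angle 4°, axis ratio 2.6, step angle 8°, step width
80 px, trace similarity 0.75) with between-subject SDs
(0.05, 4, 0.35, 4, 8, 0.08) and jitter trials at within = 0.25 × between —
the "separable" regime standing in for repeatable human gait. Note that
setting within = between does **not** give chance-level identification under
this model (imposter pairs still differ by subject means, roughly doubling
their variance); chance level requires the subject means to carry no
information (between → 0), which is how the no-information control is
simulated.

Passing phantom tests establishes that the implementations recover the
quantities they define, at the stated tolerances, under controlled noise.
They do not establish robustness to the things the phantoms omit: skin
texture and partial contact, non-Gaussian or temporally correlated sway,
double-support frames, lighting drift, or landmark localization error
(landmarks are exact by construction).

## Problem sizes and determinism

Default experiment sizes — 600×720 mosaic scenes, 2000-frame sway sequences
(5 seeds per condition), 13-point arch-index grids, 6 randomized gait
sequences, 90 × 5 populations (900 genuine / 100 125 imposter pairs), 10⁴ + 10⁴
binormal score draws — were chosen so every documented recovery is measured
with comfortable statistical margin while a full run stays interactive on a
single CPU. Every generator is a pure function of its parameters and one
integer seed; fixed-seed runs are replay-identical.
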