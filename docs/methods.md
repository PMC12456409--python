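# Methods

This note documents the models, conventions, and numerical choices behind
`dcmigration`, and what the synthetic ground truths do and do not establish
about real data.

## Coordinate and unit conventions

Tracks are planar, y-up Cartesian, in µm, with times in minutes; images are
row-major rasters with the origin top-left (row index increases downward);
localizations are in nm inside an axis-aligned rectangular window.
Conversions between track and image conventions are always explicit. Every
reader validates units at import: pixel-valued tracks require a µm/px
calibration and a frame interval in minutes, images require a pixel size in
µm (from TIFF metadata or as an explicit override — never guessed).

## Synthetic motility model

Cell tracks are generated by a biased persistent random walk (PRW). The
heading angle performs a wrapped-Gaussian random walk with per-step standard
deviation √(2·dt/P), where P is the persistence time (P = 0 redraws the
heading uniformly each step; P = ∞ freezes it). The realized step direction
is the renormalized convex combination (1 − b)·û + b·ĝ of the heading û and
the gradient direction ĝ, with fixed step length s·dt. This makes the two
limits exact: b = 0 is the isotropic PRW whose displacement angles are
uniform on [0°, 180°] with mean 90°, and b = 1 moves every cell straight up
the gradient (angle exactly 0°); the mean angle is strictly decreasing in b
between them. The unbiased walk has 2D diffusion coefficient D = s²P/2, and
in the P → 0 limit with s = √(4D/dt) it reproduces MSD(τ) = 4Dτ, which the
tests use as a closed-form oracle.

Defaults are chosen at the scale of mature dendritic cells in 3D collagen:
s = 4 µm/min, dt = 4 min (time-lapse acquisition interval), P = 10 min,
25 positions per track (≥ 90 min of tracking). The PRW is a standard
amoeboid-motility null, not a mechanistic model of any particular cell; it
generates the statistical structure (persistence, isotropy under the null,
tunable drift) that the angle and MSD analyses assume, nothing more.

## Track kinematics

Velocity is total path length over elapsed time, so it is always ≥ the
straight-line (chord) speed. Per-cell MSD uses overlapping start points at
integer multiples of the frame interval; the group curve averages per-cell
values without weights over the cells whose tracks support each lag, with
the contributing cell count and SEM reported per lag — the correction for
unequal tracking lengths. (Weighting cells by their number of intervals is
available as an option but is not the default, matching the
per-cell-then-average convention.) The Euclidean displacement at a horizon
(default 60 min) takes the first sample at or after the horizon rather than
interpolating, so no positions are invented; shorter tracks are excluded
with a logged count.

## Chemotaxis statistics

Alignment to the gradient frame is a proper rigid motion (rotation +
translation, no reflection) mapping the source border onto the x axis and
the gradient to +y; distances, and therefore MSD and speeds, are invariant.
The displacement angle of an aligned track is arccos(Δy/|Δr|) in degrees.
Angles are summarized by their arithmetic mean on [0°, 180°] — the statistic
is an unsigned deviation from the gradient axis, so circular statistics are
deliberately not used. Zero-net-displacement tracks have no direction and
are excluded (logged), never assigned 90°.

Groups are compared by the percentile bootstrap of the difference in mean
angle: B resamples (default 10,000) drawn with replacement within each
group at fixed group sizes, CI from the empirical α/2 and 1 − α/2 quantiles.
The percentile variant was chosen over BCa for transparency; donors are not
resampled hierarchically in pooled analyses (cells are exchangeable under
the null being tested), and per-donor means are reported alongside when
donor labels are present. At group sizes near 50 the percentile interval is
known to undercover slightly (empirically ≈ 94% for a nominal 95%), which
the calibration test's ±2.5 pp band accommodates.

## Polarity imaging

Segmentation is a global threshold (Otsu by default, configurable to a
fixed value) followed by largest-connected-component selection (area ties
broken by the lowest centroid row, logged) and hole filling. Background
pixels are invalid, not zero: every statistic is computed over cell pixels
only, so padding the canvas changes nothing.

The polarity axis is the principal axis of the cell mask (PCA of pixel
coordinates) passed through the nucleus centroid; axis–boundary
intersections are found by marching along the axis at quarter-pixel steps.
The rear is the side with the shorter nucleus-edge-to-cell-edge distance;
exact ties (symmetric nucleus) resolve deterministically to the negative
principal-axis side and are flagged. The rear/front intensity ratio uses
regional means over the two partitions induced by the line through the
nucleus centroid perpendicular to the axis. This replaces interactive
surface-plot reads with an objective statistic while preserving the
rear-over-front definition.

Line profiles assign each cell pixel an axial offset from the rear-most (or
front-most) point, bin at the pixel size, and average intensity over the
full cell width per bin; each cell's profile is normalized by the maximum
of its own full-length width-averaged profile, so per-cell maxima equal 1,
and group curves are means ± SEM of the per-cell normalized profiles (never
a normalization of the group mean). The default profile length is 25 µm;
a 0.1136 µm/px calibration makes that 220 samples, but the sampling step is
always the image's own pixel size, not a constant.

Foci and particle counts threshold within the mask or region, count
connected components at or above a minimum area, and report density per µm².

## Nanoscale clustering

The pair correlation function is estimated on annular bins: ordered pairs
weighted by the reciprocal of the translation-shifted window area
(translational edge correction; configurable to none), normalized by the
unbiased squared intensity n(n−1)/|W|². r_max must stay below half the
shorter window side. The estimator is validated against the Thomas-process
closed form g(r) = 1 + exp(−r²/4σ²)/(4πκσ²).

The cluster model g(r) = baseline + A·exp(−r²/4σ²) is fitted by weighted
least squares (weights √pair-count per bin; empty bins excluded; σ bounded
within [r₁/10, 10·r_max]). A fit with σ at its bounds or an optimizer
failure is flagged non-converged and excluded from group summaries — no
value is fabricated; amplitude below 0.1 flags the pattern as consistent
with complete spatial randomness. The reported cluster diameter is 4σ (the
two-sided 2σ extent, enclosing ≈ 95% of a Gaussian cluster); this is this
package's reporting convention, and absolute diameters are not comparable
across conventions. Localization-uncertainty deconvolution and
multi-blinking corrections are not applied, so σ is the apparent (imaged)
cluster scale.

The synthetic null is a Thomas process at localization-microscopy scale:
κ = 8×10⁻⁶ parents/nm², µ = 20 offspring/parent, σ = 25 nm in a
5,000 × 5,000 nm window (≈ 4,000 points per cell). Parents are simulated on
a 4σ-dilated window to avoid boundary bias in offspring retention.

## Population indices

Percent migration is 100·migrated/input (counts validated: migrated ≤
input); relative migration normalizes each treatment to its reference
within each donor before any averaging, because donors differ in baseline
motility. The homing index is the ratio-of-ratios
(fr_t/v_t)/(fr_i/v_i); it is invariant to common rescaling of the tissue
(or input) percentages and maps to its reciprocal under a dye swap —
HI(a,b,c,d)·HI(b,a,d,c) = 1 exactly. Percentages may be supplied directly
or derived from counts; both paths validate identically.

## Reproducibility and problem sizes

All randomness flows from one integer seed through numpy `SeedSequence`;
fixed seeds give bit-identical outputs, and the CLI requires a seed for
every stochastic subcommand while recording it in the run manifest. Test
and acceptance problem sizes are chosen so each statistical check resolves
its stated tolerance: 10,000 tracks for the 90° null (SE ≈ 0.5°), 1,000
tracks for the MSD slope, 500 × B=2,000 bootstrap replications for CI
calibration, 50 seeds per σ for cluster-parameter recovery, and 20 seeds
for polarity recovery.

## Limitations

Everything is planar: no z-resolved tracks or volumetric image analysis
(real 3D data are analyzed as projections). The PRW is a stand-in motility
model — passing recovery tests on it shows the estimators are correct under
persistence and drift, not that real DC motility follows a PRW. The
synthetic polarized cell is a noise-free geometric idealization plus
Gaussian noise; it validates the geometry and ratio pipeline, not
robustness to staining artifacts, touching cells, or segmentation failure
modes of real micrographs. Nucleus-free (time-lapse) polarity proxies,
uropod-duration scoring, circular statistics, and DBSCAN/Voronoi clustering
alternatives are out of scope.
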