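# Methods

This note documents the models, conventions and numerical choices behind
`gastrumorph`, and what its synthetic benchmarks do and do not demonstrate
about real microscopy data.

## Coordinate and unit conventions

All geometry is computed in continuous Cartesian micrometres after
calibration: origin at the image top-left, x to the right (columns), y
downward (rows), pixel centers at half-integer pixel coordinates. Time is
in minutes. Angles are degrees; cell and mediolateral (ML) axes are
undirected, so orientations live in (−90°, 90°] and ML angles in [0°, 90°].
Calibration (μm/pixel) is always a required user input — exported
microscopy files cannot be trusted to carry it.

## Track motility metrics

A trajectory is one nucleus' time-ordered positions. Metrics:

* **Instantaneous velocity** `v = |Δr| / Δt` per consecutive sample pair.
  Frame gaps are permitted; the true time difference is used. The per-cell
  scalar is the arithmetic mean of the instantaneous speeds (median is
  available as an option); the mean is the conventional reducer for
  one-point-per-cell velocity plots.
* **Directional persistence** = net (first-to-last) displacement divided by
  total path length; 1 for straight motion, undefined (and excluded from
  summaries) for a perfectly stationary track.
* **Track filters**: cells enter group comparisons only if they were
  (i) tracked ≥ 45 min, (ii) moved ≥ 20 μm, and (iii) ended < 80 μm from
  the annotated blastopore lip. (i) and (ii) are inclusive, (iii) strict.
  Criterion (ii) uses net displacement by default (stationary jitter can
  accumulate path length without translocation); a path-length mode is
  available (`displacement_mode="path"`). With a z column present all
  distances are 3D; mixed tables are rejected.
* **Persistence histogram**: 0.05-wide bins descending from 1.0
  ([0.95, 1.00], [0.90, 0.95), …, [0.70, 0.75)) plus one aggregate bin
  below 0.70; reported as percentages summing to 100.

## Spatial organization

At a configurable analysis time point (default 150 min) the nucleus
centers are triangulated with the Delaunay criterion (SciPy/Qhull; the
vertex processing order is fixed, so degenerate cocircular inputs resolve
reproducibly across runs). Each nucleus' spatial statistic is the mean
Euclidean distance to its Delaunay neighbors. Convex-hull nuclei have
truncated neighborhoods that bias this mean upward; they are flagged and
excluded by default (`exclude_hull=True`).

Distance to the lip is the minimum point-to-segment distance over the
annotated polyline. Per-nucleus values are stratified into overlapping
lip-distance windows of width 30 μm and step 25 μm — [0, 30), [25, 55),
[50, 80), … — so consecutive windows share a 5 μm strip and a nucleus in
the strip contributes to both. Empty windows are reported with n = 0 and
an undefined mean.

## Cell-shape morphometrics

Each labelled region is summarized by the ellipse with matched second
central moments: axis lengths are 4·√(eigenvalues) of the pixel-coordinate
covariance (with the 1/12 uniform-pixel variance added so thin regions
stay non-degenerate), orientation is the leading eigenvector folded into
(−90°, 90°]. The polarity index is major/minor. Regions touching the image
border are excluded by default (incomplete shapes bias axis ratios);
regions under 4 pixels are dropped. The ML axis is a required annotation,
never inferred from the image. ML angles are folded to [0°, 90°] and
binned into eight 11.25° bins, half-open except the last ([78.75°, 90°]
closed) so every angle is counted exactly once.

Rasterization limits accuracy: for regions ≥ 200 px the polarity index is
rotation-invariant to within ~2%.

## Macro-morphometrics

Blastopore closure = blastopore area / vegetal-hemisphere area in vegetal
view (0 = closed). Inputs are polygon annotations (shoelace area, via
shapely, self-intersections rejected) or binary masks (pixel count ×
pixel area). The ratio is not clamped; values > 1 warn (annotation error).
Axis and explant lengths are measured as polyline arc length (straight
chord available). Explant percent elongation is
`100 × (Lf − Li) / mean_ref(Lf − Li)` with the uninjected group's mean
length change defining 100%; shrinkage gives negative values, not clamped.

## Intensity profiles

A 25 × 100 μm rectangle (long axis parallel to the cleft, placed
300 μm from the lip along a user-supplied review-able direction hint) is
sampled on a regular grid with bilinear interpolation; the default step is
half the pixel size (Nyquist with respect to the raster). I_x is the mean
along the 100 μm length at each transverse position, I_m the mean over the
whole rectangle; the reported profile is I_x / I_m, which averages to 1 by
construction and is invariant to global intensity scaling. Normalization
is per rectangle, so cross-specimen comparisons rest on profile shape,
not absolute brightness. No background subtraction or projection handling:
inputs are assumed to be single selected/projected planes.

## Statistics

* Mann–Whitney U, two-tailed; statistic reported as min(U_x, U_y). Exact
  enumeration when n_x + n_y ≤ 12 without ties, otherwise tie-corrected
  normal approximation with continuity correction.
* Kruskal–Wallis with tie correction; H = 0, p = 1 when every pooled
  observation is identical.
* Dunn's post-hoc z tests from pooled midranks with tie correction,
  Bonferroni-adjusted over all pairs by default (raw p available). The
  commercial packages' exact multiplicity adjustment for Dunn varies;
  Bonferroni is the declared convention here.
* Pearson chi-square on count tables: independence for 2D tables
  (no Yates correction), uniformity for one-way bin vectors.

Per-cell values pooled across embryos are treated as independent points,
matching how such data are conventionally plotted and tested; per-embryo
means can be computed from the summary tables for a pseudoreplication
sensitivity check.

## Synthetic data: what it emulates

Generators are pure functions of parameters + seed.

* **Persistent walks**: headings evolve by wrapped-Gaussian increments
  (`turning_sd`) and are blended with the direction to the nearest lip
  point by a weighted circular mean (`drift_weight`). Walks can stop
  within `stop_distance` of the lip, emulating tracker loss at
  involution. The default two-condition dataset uses, per 3-min frame:
  control-like — step 3.6 μm (1.2 μm/min), turning_sd 25°, drift 0.30;
  morphant-like — step 2.4 μm (0.8 μm/min), turning_sd 30°, drift 0.25;
  60 steps, starts 60–130 μm from the lip. These values were chosen so
  the control-like ensemble's persistence is ≈ 0.92 ± 0.06 and the
  morphant-like ≈ 0.84 ± 0.07 — the scale observed for involuting
  marginal-zone cells — while keeping both groups past the track filters.
* **Point clouds**: hexagonal rows marched away from a straight
  lip-aligned reference axis, in-row spacing and row gap set by the local
  s(d). Constant spacing with zero jitter is an exact lattice (every
  interior nucleus has six neighbors at exactly s); where s(d) changes
  there is a one-row seam, so graded clouds recover their spacings per
  window only approximately (≤ 5% in the benchmark).
* **Cell mosaics**: non-overlapping ellipses of exact area, aspect ratio
  and sampled orientation, rasterized on a jittered square lattice with a
  pitch that precludes collisions; label 0 fills the inter-cell space like
  membrane gaps. A Voronoi-based space-filling construction was
  considered and rejected: with a single shared anisotropic metric over an
  isotropic lattice the stretch cancels in the bisectors and cells come
  out isotropic, exactly in the aligned regime where elongation matters.
  Orientations are axial von Mises: φ ~ VM(0, κ) on the doubled circle,
  θ = φ/2, so κ = 0 is uniform and large κ concentrates along the ML (x)
  axis.
* **Vegetal views**: concentric ≥ 64-gon disks; a closed blastopore
  (r = 0) is represented as `None` → area 0 → ratio 0.
* **Fibril images**: constant background plus a straight band of elevated
  intensity at a configurable angle, plus i.i.d. Gaussian noise.

What passing these benchmarks does **not** show: the generators have no
segmentation error, no tracking gaps or identity switches, no uneven
illumination, no z-projection artifacts, no cell divisions or deaths, and
cell shapes are ideal ellipses rather than polygonal epithelial outlines.
Results on real microscopy depend on upstream segmentation/tracking
quality that this package deliberately takes as given.

## Numerical choices and degenerate inputs

* Delaunay requires ≥ 3 non-collinear points (rank check with relative
  tolerance 1e-9).
* Window stratification iterates from 0 in 25 μm steps until the largest
  observed lip distance is covered.
* Histogram and rose bins are half-open with the extreme bin closed, so
  boundary values (persistence 1.0, angle 90°) are counted exactly once.
* Stationary tracks (path length 0) raise rather than return NaN.
* Profile sampling clamps interpolation at the image edge
  (`mode="nearest"`), but rectangles must lie fully inside the image, so
  clamping never affects reported values.
* Benchmark problem sizes (tens of cells per group, 100–500 Monte-Carlo
  replicates, ~500-point clouds) were chosen as the smallest ensembles at
  which the checked contrasts are decisive and stable across seeds.

## Known limitations

* The point-cloud generator assumes an approximately straight lip; a
  strongly curved lip would need a curvilinear lattice frame.
* The mosaic is not space-filling; analyses that depend on shared cell
  junctions (e.g. neighbor-exchange statistics) cannot be benchmarked
  with it.
* 3D label masks are out of scope; tracks may be 3D but the spatial
  organization analysis is planar.
* Published group means from the original light-sheet/confocal recordings
  cannot be reproduced numerically because the raw data are not deposited;
  the package instead demonstrates direction-of-effect reproduction and
  exact recovery of known synthetic ground truth.
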