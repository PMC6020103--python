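# Methods

This note documents the models implemented in `urbancanopy`, the choices
made where the design was genuinely open, and what the synthetic test bed
does and does not demonstrate.

## Pre-clustering filters

Airborne tiles are assumed height-normalised (z = height above ground). Two
pointwise filters isolate vegetation:

* **Return-count filter** — keep points with `number_of_returns > 1`
  (strict). Vegetation is porous to the laser pulse and typically yields
  several returns per pulse; hard surfaces yield one. The field is the LAS
  "Number of Returns (given pulse)" metafield, *not* "Return Number"; since
  datasets sometimes confuse the two, the reader exposes both and the
  filter targets the per-pulse count explicitly.
* **Low-point filter** — remove points with z ≤ 1 m (boundary removed).

Both predicates are pointwise, so they are idempotent and commute; the
order of application is irrelevant and the pipeline applies the
return-count filter first only because it shrinks the data most.

A grid-minimum normaliser (1 m cells) is included as plumbing for synthetic
scenes and gently sloping ground. It is not a terrain model: real tiles
should be normalised against a proper DTM upstream.

## Individual tree detection

**Stage 1 — density clustering.** DBSCAN in 3-D (x, y, z in metres,
unscaled), defaults `eps = 3.5 m`, `min_samples = 20`. These defaults suit
~2 pulses m⁻² capture, where the eps disc covers ≈ 38 m²; denser data can
use smaller eps with proportionally larger min_samples. Clusters are
density-connected components; unclustered points are returned as noise.

**Stage 2 — allometric canopy splitting.** A cluster with height H and
equivalent radius r = √(Ar/π) is a *merged canopy* when `β + α·H < r`
(strict), the line being a linearised upper 95 % prediction bound of a
radius-on-height regression over calibration trees (see Threshold lines
below). Canopies are split iteratively: per iteration, BIRCH clusters the
member points with radius threshold `B_t = β′ + α′·H` (the mean regression
line, recomputed from the current cluster's H), run twice — first with the
cluster count free, to discover how many subclusters the radius threshold
supports, then with that count fixed, which lets the global step merge
fragments into a refined partition. H, Ar, r are recomputed per subcluster
and the bound re-applied; the loop ends when no subcluster exceeds the
bound, or after `max_iterations = 20`, in which case survivors carry a
`non_convergent` flag (they are kept, not discarded).

Choices made where the design was open:

* BIRCH operates on **xy only**. Its threshold is a *crown radius* — a
  horizontal-extent quantity — so including z would mix units into the
  distance; H is recomputed afterwards as the max z of each subcluster's
  members. (DBSCAN stays 3-D: density connectivity is genuinely spatial.)
* The termination rule is "no subcluster still exceeds the width bound".
  This is the only reading consistent with the split criterion itself — a
  rule that *stopped* when clusters exceeded the bound would divide
  exactly the crowns the criterion says to leave alone.
* Subclusters with fewer than `min_subcluster_points = 5` members are
  discarded as noise rather than re-merged; 5 points cannot support a
  meaningful hull and re-merging would re-inflate the very canopies being
  split.

**Cleaning.** Crowns with hull area < `min_polygon_area = 10 m²` are
removed (they coincide with building-edge slivers); crowns taller than
`max_crown_height = 50 m` are removed (cranes, aerials — comfortably above
any plausible urban tree); among pairs of crowns whose hulls overlap with
IoU ≥ `duplicate_iou = 0.7` (vertically offset duplicates of one tree) the
crown with more supporting points wins, ties broken by height. The IoU
default is a package choice: high enough that genuinely adjacent crowns
(which rarely exceed IoU 0.3) are safe, low enough to catch duplicates.

## Crown metrics

H is the maximum member height; Ar the area of the 2-D convex hull of
*all* member points (not a height slice); r = √(Ar/π). Degenerate hulls
(< 3 non-collinear points) get area 0 rather than raising, so the
min-area cleaning rule disposes of them uniformly.

## Allometry

**QSM quality control.** A tree's reconstruction set passes when the
t-based 95 % confidence half-width of its (up to 10) QSM volumes is ≤ 10 %
of the mean volume, and when every 1 m height slice of its point cloud
(excluding the uppermost, which is sparse by nature; slices with < 5
points skipped) has mean 4-nearest-neighbour distance ≤ 5 cm.

**Volume model.** `V = k_Ar·Ar + k_exp·(a·bᴴ)`, intercept fixed at zero so
small trees cannot receive negative volumes. R² is computed against the
*uncentred* total sum of squares, as is proper for through-origin
regression. The exponential height term is handled in one of two ways:

* If an `ExponentialHeightModel` is supplied, it is held fixed and
  (k_Ar, k_exp) come from OLS — the natural route when the exponential is
  calibrated on independent data.
* Otherwise (a, b) are estimated **jointly** with k_Ar by nonlinear least
  squares, initialised from a marginal fit of a·bᴴ to V. A purely
  sequential fit (exponential first, then OLS) is not identified: crown
  area itself grows with height, so the marginal exponential absorbs the
  area share of volume and both coefficients are biased. The reported
  k_exp is then the OLS coefficient on the fitted exponential values
  (≈ 1 by construction); only the product k_exp·a is identified, which the
  prediction uses.

The marginal exponential fit itself uses a log-linear start refined by
iteratively reweighted least squares with relative (1/fitted²) weights,
because volume scatter grows with tree size; unweighted original-scale
least squares lets the largest trees dominate and destabilises `a`.

Prediction sd is the constant residual sd of the fit; negative raw
predictions are clipped to zero and flagged. dbh is carried in the QSM
schema for exploration but is deliberately not a predictor: it has no
airborne analogue.

**Threshold lines.** Both ITD threshold lines come from OLS of r on H over
calibration trees. `bt_mean` is the OLS line itself. `split_95pi` takes
the exact upper 95 % prediction bound at each training height — which
curves with distance from the mean height — and re-fits a straight line
through those bound points, since the applied criterion is linear. The
bound line dominates the mean line over the training range by
construction. The prediction bound (not a confidence bound) is used so
that naturally large single crowns are not needlessly split.

## Biomass, carbon, mapping

AGB = V·ρ/1000 (Mg, with ρ in kg m⁻³); carbon = 0.471·AGB. Crowns map to
grid cells (default 100 m, so cell sums read directly as Mg ha⁻¹) by hull
centroid — the simplest rule that conserves mass exactly. Area-weighted
apportionment across overlapped cells is available (`method="area"`); it
smooths cell boundaries at the cost of fractional tree counts, and totals
are unchanged. Per-cell sd aggregates in
quadrature, assuming inter-crown error independence (consistent with the
Monte Carlo design, which draws every crown independently). Rasters are
written as plain-text ESRI ASCII grids, one per layer, nodata −9999.

## Monte Carlo uncertainty

Three components, each freezable:

* `qsm` — Gaussian volume noise per crown (sd from reconstruction spread,
  or any user-supplied level);
* `als` — Gaussian H and Ar perturbations, truncated at zero, with
  per-crown sds estimated by repeated random subsampling of the crown's
  points. The subsampling retains a **fraction 0.75 of points** per
  iteration, 100 iterations. Crowns too small to subsample inherit the
  mean relative sd of the crowns that could be, scaled by their own H and
  Ar;
* `density` — wood density drawn uniformly with replacement from the
  empirical per-tree density values, one draw **per tree per simulation**
  (drawing one density per simulation shared across trees was the
  alternative; per-tree draws match the fact that different trees really
  are different species, and make total-AGB uncertainty scale correctly
  with tree count).

Default 100 simulations. With every component frozen each simulation
reproduces the deterministic pipeline bit-for-bit — this is tested, not
just expected. Variance shares are single-component variances normalised
by their sum (so shares total 100 %); interactions between components are
thereby folded proportionally, which is adequate for the mildly nonlinear
AGB model.

## Synthetic scenes

The generator emulates the target data regime: 2 pulses m⁻² capture over
parametric tree crowns (ellipsoid or cone envelopes), buildings emitting
single returns (with an optional multi-return edge-noise fraction), and
ground at z ≈ 0. Crown points are sampled on the envelope surface —
airborne LiDAR predominantly sees the canopy surface — so sampled maxima
never exceed the true apex, reproducing the familiar slight height
underestimate. Vegetation pulses yield two returns each by default.

Population defaults: H ~ U(5, 35) m; crown radius β + α·H + N(0, σ_r) with
α = 0.15, β = 1.0 m and σ_r = 2.0 m; volume law k_Ar = 0.05 m³ m⁻²,
k_exp = 1, a = 0.08 m³, b = 1.17 with 10 % multiplicative lognormal noise;
wood density 560 kg m⁻³. The radius scatter of 2 m is deliberate: urban
crowns of similar height differ severalfold in area between street,
parkland and closed-canopy settings, and that plasticity is both what the
splitting thresholds must tolerate and what makes the two allometry
regressors separately identifiable. QSM tables carry 10 reconstruction
volumes per tree at 3 % relative sd (leaf-off reconstruction stability);
dbh is synthesised through a monotone power law of volume (0.1·V^0.4) as a
placeholder with the right ordering, and is never used as a predictor.

Benchmark scenes used by the test suite and acceptance script place 50
trees (H 12–18 m, σ_r = 0.25 m) on a 14 m jittered grid — spacing chosen
so crowns cannot density-connect, isolating detection performance from
splitting performance, which is exercised separately on two-tree merged
canopies 8 m apart. Scene sizes (50 trees, ~30 k points) keep the whole
suite under ten seconds while leaving every code path exercised.

**What passing these tests does not show:** real canopies overlap far more
than the merged-pair construction; real ground is not flat; leaf-on/off
phenology, occlusion by buildings, co-registration error and waveform
effects are all absent. Synthetic recovery bounds are therefore
best-case; on real tiles, crown overlap is the dominant unmodelled error
and biases AGB low.

## Known limitations

* LAZ is not read; tiles must be decompressed to LAS first.
* No CRS interpretation or reprojection; coordinates are trusted as a
  projected metric system.
* The duplicate-removal and centroid-assignment rules are O(n²) per
  overlap neighbourhood and per crown respectively; city-scale runs should
  tile the input.
* Only the product k_exp·a of the exponential term is identified when the
  exponential is fitted internally; interpret a and b jointly.
* Variance shares fold interaction terms proportionally rather than
  reporting them separately.
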