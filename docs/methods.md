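# Methods

`pvvkit` estimates pulmonary vessel-like volume (PVV) — the total volume of
structures segmented as vessels on chest CT — and its partition into
sub-volumes by vessel cross-sectional area: PVV5 (< 5 mm²), PVV10
(5–10 mm², inclusive at both edges), PVV10+ (> 10 mm²).  Two estimators are
provided so their artifacts can be compared on identical inputs, together
with a synthetic phantom generator that supplies analytic ground truth, and
a mixed-model layer for cohort-level comparisons.

## The two estimators

### Slice-wise ("unfiltered") estimator

Each image plane is processed independently: 2D 8-connected components of
the binary vessel-like mask are measured by cross-sectional area
(pixel count × dx·dy), and each component contributes `area × slice
thickness` of volume to the bin its area falls in.  No 3D connectivity and
no denoising — deliberately, since this is the estimator whose artifacts
the graph-based method is designed to remove.

Two properties matter for interpreting it:

* **Oblique area inflation.** A vessel tilted by θ from the slice normal
  shows an elliptical cross-section of area ≈ πr²/cos θ.  This inflates
  per-slice areas (we verify the 1/cos θ law on tilted cylinder phantoms to
  within 20% at 30–60°) and pushes branches into higher area bins —
  sub-volume *misclassification*.
* **The total is conserved.** When the volume multiplier equals the grid
  slice spacing, the slice-wise total is *identically* voxel count × voxel
  volume: per-slice areas inflate by 1/cos θ, but the number of occupied
  slices shrinks by cos θ.  Orientation therefore corrupts the partition,
  not the total.  The total is corrupted instead by unconnected clutter
  (below) and by any mismatch between slice thickness and slice spacing
  (the multiplier is the thickness by default; `--multiplier spacing`
  exposes the alternative for overlapping reconstructions).

### Graph-based estimator

The connectivity-aware pipeline keeps only connected branching structures
and measures each branch along its own axis:

1. **3D component thresholding** — 26-connected components with physical
   volume below `min_component_volume` (default 50 mm³) are dropped.  This
   is what removes unconnected speckle such as reticular pattern
   misclassified as vessel.
2. **Morphological closing** — a physical-space ball element (default
   1 mm; discretized per-axis, so it has no through-plane extent on 3 mm
   slices) closes sub-radius gaps.
3. **Skeletonization** — EDT-ordered sequential topological thinning
   (`pvvkit._thinning`): border voxels are deleted one at a time, lowest
   Euclidean distance first, only when they are simple points and not
   curve endpoints.  Sequential deletion makes annihilation of a component
   impossible and the EDT ordering (computed with the anisotropic physical
   spacing) keeps the curve on the distance ridge.  We implemented this
   after finding that parallel 6-subiteration thinning can delete
   lattice-symmetric tubes *entirely* (a voxelized cylinder whose axis
   falls midway between voxel centers thins to zero voxels) and produces
   hairpin artifacts on strongly anisotropic grids.
4. **Per-voxel radius** — the anisotropic EDT of the mask, sampled at the
   centerline with a 26-neighborhood maximum ("centered maximal ball"):
   the discrete centerline sits up to one voxel off the true axis, where
   the raw EDT under-reads the radius.
5. **Conditional removal near the pleura** — a skeleton voxel at pleural
   depth `d` (EDT of the lung mask) is removed when its radius falls below
   a raised-cosine (Hann) floor anchored at the lung boundary:

       r_min(d) = r_core + (r_boundary − r_core) · ½(1 + cos(π·min(d,D)/D)),

   defaults `r_core = 0`, `r_boundary = 0.7 mm`, `D = 15 mm`.  Thin,
   shallow structures — the subpleural reticular-mimicry regime — fall
   below the floor; segmental vessels do not.
6. **Graph construction** — skeleton voxels with ≥ 3 skeleton neighbors
   (26-connectivity) cluster into junction nodes, degree-1 voxels are
   endpoints, maximal chains become edges.  Short terminal twigs whose
   length is under twice the inscribed radius at their junction are spurs
   of the thinning (they lie inside the parent's own cylinder) and are
   pruned; junctions left with degree 2 are contracted so split branches
   re-merge.  Pure cycles (e.g. artery–vein contacts merged by
   segmentation) are kept as cycles.
7. **Branch measurement** — edge length is the physical polyline length of
   the path after a short moving-average smoothing (window 5; removes the
   staircase of the discrete lattice), completed to junction centers and
   extended at terminal ends by marching through the mask along the
   outward tangent (thinning retracts tips by roughly one voxel-space
   radius, which is many millimetres on 3 mm slices).  Edge radius is the
   median EDT radius over the path, excluding voxels within one local
   radius of either end node, where the EDT inflates; area = πr²; volume
   = πr²L (cylinder model).  `volume_mode="voxel"` instead assigns every
   mask voxel to its nearest branch and sums voxel volumes — it conserves
   mask volume exactly but blurs the per-branch attribution; the cylinder
   model is the default and the validated mode.

Edge volumes are accumulated into the same area bins as the slice-wise
method, so PVV5/PVV10/PVV10+ are directly comparable between methods, and
the partition is exact by construction for both.

### Accuracy on phantoms

On rasterized Murray trees (generations 1–4, rotations 0–45°, grids
(0.5, 0.5, 3.0) and (0.7, 0.7, 2.0) mm) the graph estimator recovers the
analytic volume within ±13%, with the dominant residual errors being
half-pixel radius quantization (area error ≈ 2·Δr/r) and junction-region
double counting in the cylinder decomposition.  Adding 500 unconnected
sub-threshold speckles changes the graph-based PVV by exactly zero while
the slice-wise total grows by the clutter's full slice-area × thickness.

## The vesselness entry stage

For grayscale inputs a multiscale Frangi-type filter produces the
vessel-likeness map: per-scale Gaussian Hessians (σ in mm, converted
per-axis to voxel units — essential at 6:1 anisotropy), eigenvalues ordered
by magnitude, the standard plate/blob/structure ratios with α = β = 0.5 and
an adaptive noise scale (half the maximal Hessian norm per scale), maximum
over scales {0.7, 1.4, 2.8, 5.6} mm.  The default binarization threshold is
0.3: the tube response decays radially from the axis, so the half-max level
(0.5) segments only the core of the lumen (≈ −60% volume), while 0.3
recovers cylinder volumes within ≈ 10% on phantoms.  This stage is a
functional stand-in for the proprietary clinical segmentation, not a
replication of it; its parameters are all exposed.

## The phantom generator

Synthetic trees are symmetric bifurcating cylinder trees obeying Murray's
law exactly (`r_child = r_parent·2^(−1/e)`, exponent e = 3), with branch
length = 8 × radius, 35° branch angle, a 90°-per-generation bifurcation
plane rotation with small seeded jitter, and an arbitrary rigid rotation of
the whole tree.  Default root radius 3 mm populates PVV10+ at the root
(28 mm²), PVV10 in mid branches (generation 4, ≈ 7 mm²) and PVV5 in deeper
terminals — every partition path is exercised.  Branches are straight
cylinders without caps, so the ground truth is exactly πr²L per branch.

Rasterization marks a voxel foreground iff its center lies within one
radius of the branch axis, within the axial extent; the default grid
(256×256×60 at 0.5×0.5×3.0 mm) mirrors the clinical acquisition regime
(3 mm slices, ~0.5 mm pixels, 512² matrices at whole-lung field of view).
The grid origin is offset a quarter voxel so branch axes avoid the exactly
mid-lattice planes where voxelized cross-sections become degenerate-
symmetric.  The lung mask is an enclosing ellipsoid with 12 mm clearance.
Clutter is placed as subpleural spheres (default radius 0.5–0.8 mm, within
10 mm of the pleura) with an enforced 3D gap to the tree, so every speckle
is its own component.

What the phantoms do *not* emulate: CT intensity texture and noise,
partial-volume/slab averaging through the 3 mm slice profile, tapered or
curved vessels, airway walls, and real fibrotic texture.  Passing the
phantom battery therefore validates the geometry and connectivity logic of
the estimators, not their behaviour against scanner physics or a real
texture classifier.

## Cohort statistics

Controls contribute one scan each; patients contribute up to three
(baseline plus follow-ups), so observations cluster within participant.
Group contrasts and covariate slopes are estimated by linear mixed models
(REML, statsmodels MixedLM): a random intercept per participant plus a
visit-within-participant variance component whenever any participant has
repeated visits (with single-visit participants the component collapses
and the model reduces to a participant intercept, which keeps control-only
fits estimable).  Method contrasts (graph vs unfiltered) are paired within
scan through the same structure.

Fixed-effect uncertainty uses the participant-clustered *sandwich*
covariance rather than the model-based one, so inference does not lean on
residual normality or the assumed variance structure.  We use the
bias-reduced (CR2-type) form: each cluster's marginal residual is
pre-multiplied by the matrix `A_g` solving
`A_g (V_g − X_g M X_g') A_g' = V_g`, which undoes the downward bias of the
plain sandwich when clusters are small (here: 1–3 observations each).
Confidence intervals use the normal approximation; with this adjustment
the 95% intervals achieve 95.1% empirical coverage over 1000 simulation
replicates of the study design (100 participants, repeated visits in one
cohort).  Regression slopes with a cohort interaction are reported per
cohort by contrasting the interaction terms under the same robust
covariance.

Simulated cohorts (`simulate_two_cohorts`, `simulate_slope_cohort`) are the
validation harness: participant random intercepts (SD 1–2 mL), residual SD
1–2 mL, a built-in group difference (5 mL) or fibrosis slope (0.30 mL/%),
one visit for controls and two for patients.  They emulate the clustering
structure of the study design, not the empirical PVV distributions
(which are right-skewed in patients).

## Numerical choices and degenerate inputs

* All geometry is computed in physical millimetres; nothing assumes
  isotropy.  EDTs use `scipy.ndimage.distance_transform_edt` with the
  voxel spacing as sampling.
* Empty masks yield empty skeletons and all-zero results (not errors);
  a mask that is non-empty but filtered to nothing warns.
* Components thinned to nothing (possible only for degenerate flat shapes)
  are restored as one-voxel skeletons to preserve the component count.
* Zero-length edges are dropped with a logged count; an edge whose
  junction-exclusion empties its radius sample falls back to the
  unexcluded median and is flagged in its attributes.
* Volume files with non-positive header spacing are rejected — spacing is
  never silently assumed to be 1 mm.
* Cohort rows whose PVV partition does not sum to the total (relative
  tolerance 10⁻⁴) are rejected with row numbers; blank lung-function cells
  are allowed, blank PVV cells are not.

## Known limitations

* Branch volumes use a constant-radius cylinder per edge; tapered vessels
  are represented piecewise by their bifurcation-delimited branches.
* The junction region is shared between parent and children, giving a
  small systematic over-count that partially cancels the radius
  quantization under-count; both are within the validated ±15% envelope.
* The pleural Hann taper is one concrete reading of depth-conditioned
  removal; its thresholds are configuration, not estimates.
* Problem sizes in the test-suite and validation scripts (phantom grids up
  to 256×256×60, 100–300 simulation replicates) are chosen as desk-scale
  validation conditions; all scale linearly if enlarged.
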