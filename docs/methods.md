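# Methods

This note documents the models and procedures implemented in `phenocloud`,
the parameter defaults and their rationale, what the synthetic-field
generator does and does not emulate, and the numerical choices that keep the
pipeline deterministic.

## Scope and units

All geometry is in meters, z-up after ground alignment, with the ground
leveled at z = 0; centimeter-scale parameters quoted below are stored in
meters internally. Point indexing is 0-based everywhere, including label
sidecars. Label 0 means "not a plant" (ground, unassigned, clustering noise);
plants are labeled 1..K.

## Dense sampling from Gaussian-splat scenes

A splat scene represents the crop as anisotropic Gaussians with center μ,
covariance Σ = R S Sᵀ Rᵀ (R from a unit quaternion, S = diag of per-axis
standard deviations), opacity in [0,1] after a logistic squash, and RGB from
the band-0 spherical-harmonic coefficient (color = 0.5 + f_dc/(2√π)). Points
are drawn per primitive as μ + R S z with z ~ N(0, I); the Mahalanobis
distance of such a draw is exactly ‖z‖, so outlier rejection (default
threshold 3, retaining ~97 % of each Gaussian's mass) happens in the whitened
frame and never requires inverting Σ — important for splats thinner than
machine-noise scales. Draws are allocated ∝ opacity · (s₁s₂s₃)^{1/3}
(opacity-weighted size; no allocation rule is standard in splat exports), and
primitives with opacity < 0.05 are skipped as floaters. Identical seeds give
identical clouds.

## Preprocessing

**Ground alignment.** RANSAC plane fit (point-triple hypotheses, inlier count
at the distance tolerance, least-squares refit on inliers) with the normal
oriented toward the crop side. The rotation taking the ground normal to
(0, 0, 1) is built from the axis–angle quaternion; the antiparallel
degenerate case (axis undefined) rotates 180° about a fixed axis
perpendicular to the target. The cloud is also translated so the ground
plane sits at z = 0, since every later height is a plain z-difference.

**Denoising.** Statistical outlier removal discards points whose mean k-NN
distance (k = 20) exceeds the global mean by 2 standard deviations. Note
this thresholding is *not* idempotent on clouds whose density varies between
organs — each re-run trims a few percent more of the upper tail; it is
designed as a single-pass gross-outlier filter. Bilateral smoothing (k = 20,
σ_s = 1 cm, σ_r = 0.5 cm) displaces each point along its normal by the
bilaterally weighted mean of neighbor offsets, damping lamina noise while
preserving creases; the point count never changes.

**Hue-aware cloth ground filter (HCSF).** A virtual cloth (grid spacing
2 cm) settles onto the inverted cloud: nodes fall under gravity, pin where
they touch the inverted terrain of their cell, are pulled toward their
neighbor mean (3 stiffness passes per step), and unsupported nodes finally
relax to the harmonic interpolation of the pinned cloth. Points within
1.5 cm of the settled cloth are ground candidates — which necessarily
includes plant stem bases. The hue veto recovers them: candidates whose HSI
hue lies in the vegetation band [60°, 180°] with saturation > 0.1 are
returned to the plant side. The gray-saturation guard keeps colorless noise
from being vetoed. The two outputs partition the input exactly.

## Per-plant localization

In seedling-stage row crops the canopies entangle but stems stay separated,
so a bare-stem height slab (default [2 cm, 6 cm] above the corrected ground)
contains one compact cluster per plant. The slab is clustered with DBSCAN —
our own deterministic implementation: core points expand in index order and
border points attach to the lowest cluster id, making the labeling a
contract rather than an artifact of scan order. Production uses the
calibrated ε = 1.2 cm, MinPts = 6; a density-derived mode computes
ε = (T · MinPts · Γ(n/2+1) / (m π^{n/2}))^{1/n} with T the bounding-box
volume — the radius at which a ball holds MinPts points on average for
roughly uniform data. Clusters below 2·MinPts points are dropped as
weeds/noise. Each cluster yields a locator (mean x, mean y, L_h); plant
indices follow row-major (y, x) order with y quantized to 5 cm so planting
jitter cannot scramble the walking order. Duplicate locators (within 1 μm)
are an error, signalling double detection.

## Dynamically constrained instance segmentation

Each plant grows from its stem-layer cluster inside a private cylinder whose
radius scales with that plant's own measured height: R_hk is the maximum z
within 3 cm (d) of the locator, and r_k = R_hk · tan(α) with α = 35°; the
cylinder floor is the minimum z of the region of interest. Growth is
breadth-first in synchronized rounds across plants; a neighbor q joins plant
k when

* ‖p − q‖ < δ (1.5 cm, the branch-diameter scale),
* |n_p · n_q| ≥ τ_N (0.85) — absolute cosine, because eigen-normals are
  unoriented,
* q lies in the plant's cylinder.

The normal test is waived when either endpoint is quasi-linear (curvature
λ₀/Σλ > 0.10): eigen-normals of thin tubes (stems, petioles) carry no
orientation signal at realistic sampling densities, and without the waiver a
plant's own wave can stall on its stem while a neighbor's wave walks through
touching leaves. Points reached by ≥ 2 plants in the same round become
*contested* and stop growing; round-synchronous claiming makes the contested
set independent of plant ordering.

Contested points are settled by local leaf geometry: for each candidate
plant, its points within R_loc = 2 cm of the contested point are filtered
for normal consistency, a trimmed total-least-squares plane is fitted
(≥ 3 supports required), and the candidate is accepted when the point lies
within γ₂ = 0.5 cm of the plane and its curvature is within γ₁ = 2 standard
deviations of the neighborhood mean. The accepting plant with the smallest
plane distance wins; ties go to the smaller id; points no plant accepts stay
unassigned rather than being force-attached. Resolution runs in
synchronized passes to a fixpoint — each pass's decisions see only the
previous pass's labels — so the outcome is invariant to point ordering while
early resolutions still support their neighbors. For the same reason, every
reduction that feeds a decision (cluster means, plane fits, curvature
moments) is computed in value-sorted order.

Two properties are deliberately *not* claimed: growth is monotone in δ only
for a single plant (with several plants a larger δ also widens wave
collisions, and contested points that fail adjudication end unassigned), and
neighbor queries are exact fixed-radius searches — the spatial index is an
implementation detail, exactness is the contract.

## Trait extraction

Traits are computed per labeled plant after bilateral smoothing (raw
curvature at field noise levels blurs the lamina/stem contrast the leaf
steps rely on).

**Ground datum.** z_gd is the median z of ground points within 15 cm of the
locator, so sloped plots do not bias heights; with fewer than 10 local
points it falls back to the global ground median with a warning.

**Plant height.** PH = max z − z_gd. The alternative datum from the
cotyledon node is available as z_msv − z_fn for protocols that measure from
the node.

**Cotyledon node (FCNH).** A robust near-vertical stem axis is found by
trimmed PCA with a vertical prior; points beyond the stem-core guard
(1.2 cm ≈ stem radius + 3σ of sensor noise) are clustered into lateral
structures. A structure is an attached branch when its trimmed line is
> 20° off the stem axis and its innermost points come within 1 cm of the
stem core; its node height is the median z of that attachment zone — read
directly off the points rather than extrapolated from a 3-D line
intersection, which is unstable for short noisy branches. z_fn is the
minimum accepted node (cotyledons are the lowest lateral pair on a
seedling) and FCNH = z_fn − z_gd. With no acceptable branch the lowest
off-stem point is returned flagged low-confidence.

**Leaves.** The stem core is removed first — it is the only structure
connecting different leaves, so its removal isolates each petiole+lamina
branch. Region growing then starts from the lowest-curvature unassigned
point (curvature ≤ 0.05, a lamina interior) and expands across 1.2 cm links
whose normals agree (|cos| ≥ 0.80); points keep expanding only below
curvature 0.15, so bent rims are captured without tunneling through
junctions. Clusters under 30 points are dropped.

**Leaf area.** Each cluster is expressed in its principal frame and a
bivariate quadratic height field is fitted — leaves are gently bent laminae,
so the quadratic captures the fold while suppressing residual noise. The
footprint is Delaunay-triangulated, triangles with any edge beyond the
support tolerance (1 cm) are trimmed so concavities and stray bridges do not
inflate the area, and the lifted triangle areas are summed. Because the
triangulation reaches only the outermost samples, half a point-spacing of
surface beyond them is missed; the estimate adds back rim-perimeter ×
spacing/2. On a 3 cm planar disc at 2000 points this lands within 5 % of
πr²; doubling the sampling density moves the estimate by < 2 %.

## Evaluation

Predicted and ground-truth plants are matched greedily one-to-one by
point-set IoU. A ground-truth plant whose match reaches IoU ≥ 0.5 is a TP;
unmatched predictions are FP; unmatched ground-truth plants are FN — a
numeric operationalization of the verbal over/under-segmentation cases used
in field benchmarks. r, p, F are percentages rounded half-up to two decimals
(matching how benchmark tables print); micro aggregation sums counts before
computing r/p/F. mIoU is the mean IoU over matched pairs. Convex-hull
densities are reported in points/mm² and points/mm³.

The package ships the published plot-level and cultivar-level confusion
counts of the cotton field study this pipeline targets
(`phenocloud.benchmarks`) as *inputs*: every r/p/F value is recomputed from
the counts at run time, never stored.

## Parameter sensitivity protocol

The robustness check perturbs each core parameter (ε, MinPts, d, α, δ, τ_N)
one-at-a-time by ±20 % around its default on a fixed seeded synthetic field
and records the mIoU change against ground truth. Perturbed values are
clipped to the parameter's documented admissible range (ε ∈ [0.8, 2.0] cm,
MinPts ∈ [3, 10], d ∈ [2, 4] cm, α ∈ [20°, 50°], δ ∈ [1, 3] cm,
τ_N ∈ [0.70, 0.95]): the ranges are part of the calibration contract, and a
cosine threshold of 0.85 × 1.2 = 1.02 would be meaningless. MinPts is
rounded to an integer. At the default study conditions the maximum |ΔmIoU|
across all 12 perturbed runs is well below 1 percentage point.

## The synthetic field generator

The generator emulates the study conditions of a seedling-stage (6–7 leaf)
cotton breeding plot: a jittered planting grid at 0.66 m row / 0.10 m plant
spacing inside a 2 m plot, a near-planar ground (2 mm long-wave roughness)
of distinct hue (30° vs 110° for plants), and additive isotropic Gaussian
sensor noise (default σ = 3 mm). Plant morphology is deliberately simple —
a gently bowed stem cylinder (3.5 mm radius, height U(0.25, 0.35) m), a
horizontal cotyledon branch pair at U(0.05, 0.07) m, and 4–6 bent elliptical
leaf patches on short petioles — rich enough to exercise every stage (bare
stems for localization, planar laminae for plane fits and areas, curvature
contrast, entangled canopies for overlap resolution) with exact truth:
per-point instance labels, stem heights, node heights, and per-leaf areas by
converged polar quadrature of the generating parametrization (midpoint rule;
doubling resolution moves areas by < 0.1 %).

`overlap_factor` controls canopy interpenetration: each plant's allowed
horizontal reach is half the distance to its nearest neighbor minus a margin,
plus 3 cm per unit of overlap, and its first leaf points at that neighbor.
At 0 the canopies stay ≥ 2 cm apart (noise-free); at the default 1.0 the
canopies entangle as in dense plantings; at 1.5 a guaranteed share of points
falls inside several constraint cones, exercising contested resolution.

Geometry and sensor noise use separate random streams: changing only the
noise level perturbs coordinates but never labels or the truth table. Point
budgets default to 1500 points/plant and ~3000 points/m² of ground — the
problem size the test suite and the sensitivity protocol run at; real
reconstructions are one to two orders denser, and the defaults here are the
package's own desk-scale operating point.

What passing on synthetic fields does **not** show: robustness to real
reconstruction artifacts (ghost geometry, holes, anisotropic splat residue),
botanical variation in leaf shape and branching, weeds, or wind-deformed
plants. The synthetic trait-recovery figures (PH rRMSE ≤ 2 %, FCNH ≤ 5 %,
leaf area ≤ 10 % at σ = 3 mm across 50 plants) are parameter-recovery
results under the generator's assumptions, not field-validation statistics.

## Known limitations

* The cloth filter assumes the ground is visible at the grid scale almost
  everywhere; fully mulched or fully occluded plots would need a coarser
  cloth or an external terrain model.
* Cotyledon-node detection expects a single dominant, near-vertical stem;
  multi-stem or lodged plants return low-confidence flags.
* Leaf areas are one-sided lamina areas of near-quadratic surfaces; strongly
  curled leaves would be underestimated.
* Localization assumes the stem layer is weed-free up to the cluster-size
  guard; dense weeds at stem height would register as plants.
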