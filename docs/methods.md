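# Methods

This note documents the statistical machinery in `bonebed`: what each
procedure assumes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where more than one convention exists.

## Coordinate and coding conventions

Planar coordinates x, y are metres on the site grid; z is stratigraphic
height in centimetres above a site datum, increasing upward. Long-axis
orientations are *axial* data: trend in [0, 360) degrees (a reading and its
antipode are the same axis), plunge in [0, 90] degrees from horizontal.
Missing values are empty CSV fields, never zeros. Body-mass size classes
partition (0, ∞) kg with half-open intervals [lower, upper): herbivores
0 (< 25), 1 (25–50), 2 (50–125), 3a (125–250), 3b (250–500), 4 (500–1000),
5 (≥ 1000); class 3 is the union of 3a and 3b. Carnivores use exemplar
classes small (< 20 kg, fox-sized), intermediate (20–120 kg, wolf-sized)
and large (≥ 120 kg); the cut points are conventional and editable in the
shipped vocabulary. Fragment lengths are recorded to 0.1 cm; exactly 3.0
(5.0, 10.0) cm falls in the lower length class, closing the gaps between
printed class labels ("< 3" vs "3.1–5"). The "long bone" set is humerus,
radius, ulna, femur, tibia, the metapodials, and indeterminate long-bone
shaft fragments.

## Level detection

**Model.** A fossiliferous level is a contiguous band of z concentration
separated from its neighbours by sterile gaps. Detection is a three-stage
workflow: unsupervised proposal, human-in-the-loop curation, supervised
assignment.

**Proposal.** The z marginal is estimated with a Gaussian KDE and split at
interior minima whose density falls below `valley_fraction` (default 0.5)
of the smaller adjacent mode. The kernel uses Scott's factor scaled by
`bw_scale` (default 0.4): Scott's rule minimises integrated squared error
for a roughly unimodal density and, at realistic sample sizes, its ~8 cm
bandwidth smooths straight across a 10 cm sterile gap; mode *detection*
needs a finer kernel, and the relative valley criterion plus a minimum
segment share (`min_fraction`, default 5% of finds — a level must hold a
non-negligible share of the assemblage) guard against spurious splits and
outlier bumps.

**Assignment.** Two probabilistic classifiers are trained on (x, y, z)
only — no taphonomic feature may leak into stratigraphy: a 500-tree random
forest and an RBF-kernel SVM with sigmoid-calibrated posteriors. A
specimen gets the agreed label; on disagreement the classifier with the
higher maximum posterior decides (recorded, so the report can state which
classifier is the more decisive); if both posteriors are below the
confidence threshold (default 0.80) the specimen is indeterminate.
Specimens falling in inter-band gaps are prediction-only. Reliability is
reported as raw agreement, Cohen's κ on the two classifiers'
cross-tabulation, decisiveness, and mean posterior with (max − mean,
mean − min) deviations — the bound construction around mean confidence is
an interpretation, flagged as such.

## Point-pattern statistics

All statistics operate on a `PointPattern2D`: points in an axis-aligned
rectangular window W (polygonal windows are out of scope).

- **Quadrat CSR test.** W is divided into nx × ny equal-area quadrats
  (default 8 × 8); χ² = Σ(nᵢ − n̄)²/n̄. Because quadrat counts are far from
  the χ² asymptotics at archaeological sample sizes, the null is simulated:
  p = (1 + #{χ²_sim ≥ χ²_obs})/(nsim + 1) with one-sided "greater"
  alternative, nsim defaulting to 4999 (minimum attainable p = 2·10⁻⁴).
  Per-quadrat Pearson residuals (nᵢ − n̄)/√n̄ feed the residual heat map.
- **K and L.** Homogeneous K uses the unbiased |W|·pairs/(n(n−1))
  normalisation; the inhomogeneous variant weights each ordered pair by
  1/(λ̂ᵢλ̂ⱼ) and renormalises by Σ 1/λ̂ᵢ over retained points. Border
  correction is the reduced-sample estimator (reference points farther
  than r from the boundary); translation/isotropic corrections are not
  implemented. The centred L̂(r) − r with L = √(K/π) linearises K, zero
  under CSR.
- **Intensity model.** λ̂ is a leave-one-out Gaussian kernel estimate with
  uniform edge renormalisation (the kernel mass retained inside W at the
  evaluation point). Its default bandwidth is **2× Scott's factor**: the
  intensity model must describe the broad first-order trend, and smoothing
  at the density-estimation optimum would let λ̂ absorb exactly the
  cluster-scale structure the K function is meant to detect. The bandwidth
  is logged and overridable.
- **Hopkins–Skellam.** A = Σeᵢ²/Σdᵢ² with eᵢ the nearest-neighbour
  distances of m sampled events and dᵢ the empty-space distances of m
  uniform locations. The orientation is chosen so clustering ⇒ A < 1
  (conventions differ in the literature). Under CSR, A ≈ F(2m, 2m); the
  reported p is Pr(F ≤ A), one-sided for the clustered alternative. The F
  null is exact only for sparse sampling; at the default m = n/5 it is
  mildly approximate (coverage ≈ 93–95% in simulation).
- **DBSCAN.** Hand-written for determinism: core points have ≥ min_pts
  neighbours (self included) within ε; clusters are maximal
  density-connected sets created in ascending order of their smallest core
  index; border points are claimed by the earliest-created adjacent
  cluster; remaining points are noise (label 0). ε defaults to the knee
  (maximum distance to the end-to-end chord) of the sorted k-NN distance
  profile with k = min_pts.

## Orientation statistics

Axial statistics use the standard doubling construction: double the angles
mod 360, compute directional statistics, halve the mean into [0, 180).
R̄ = 0 leaves the mean undefined (reported missing). Uniformity is tested
with Rayleigh's z = nR̄² and the series approximation
p ≈ e^(−z)[1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)],
clipped to [0, 1] and requiring n ≥ 4; the test choice is isolated so a
Kuiper alternative could be substituted. Plunge profiles report flat
(< 10°), intermediate, and steep (> 45°) fractions among records with a
plunge value. Per-cluster fabric summaries flag clusters whose uniformity
cannot be rejected at α = 0.05 as having no preferential orientation;
clusters with n < 4 get no p-value. Rose diagrams bin at 10° and mirror
axial data; stereograms are polar trend/plunge scatters (equal-angle,
plunge increasing inward).

## Synthetic site generator

`simulate_site` emulates the structure the pipeline assumes: two fossil
bands at 0–50 and 60–90 cm (≤ 30 cm local thickness, 10 cm sterile gap,
1000 specimens each) dipping 1 cm/m along azimuth 45° (the published
account gives the direction but no magnitude; the default is a
configurable placeholder), horizontal Thomas-cluster structure (parent
intensity 0.45/m² — of the order of the reported cluster counts over a
39 m² window — mean offspring 40, offspring spread σ = 0.35 m; for fixed
per-level counts each point attaches to a uniformly chosen parent), an
axial von Mises fabric (mean axis 35°, κ = 4, 10% uniform contamination),
a plunge mixture of 79% < 10° / 17% intermediate / 4% > 45°, and
taphonomic attributes drawn from the reference assemblage's marginal
frequencies. One seeded generator drives every draw, so equal seeds give
identical tables.

What it does **not** emulate: spatial correlation between attributes and
position (attributes are independent of coordinates), skeletal
articulation, hydraulic transport or winnowing, inter-level taphonomic
differences, and measurement error. Passing recovery tests on these sites
therefore shows the estimators work under the stated geometric and
distributional assumptions, not that they are robust to every feature of
real excavation data.

`build_vm4_fixture` is different in kind: a deterministic 1609-specimen
table constructed so that every marginal count the profiler reads equals
the published Venta Micena 4 accounting (per-taxon NISP and MNI age
structure, fragmentation, fracture, circumference, preservation,
weathering, abrasion, staining, tooth-mark, taphotype and notch tables).
Fields the published tables do not constrain are filled deterministically.
The build re-derives every constrained marginal from the finished table
and refuses to return if any fails.

Three published cells are mutually inconsistent and resolved as follows
(documented, not silently corrected): the green-fracture share recomputes
to 55.0% (186/338) against a printed 55.1; the tooth-mark typology counts
(38 + 7 + 4 + 1 = 50) exceed the 43 marked bones, so the fixture keeps the
43 total and the percentages consistent with it (38 pits-only = 88.4%,
4 pits-and-scores = 9.3%, 1 punctures = 2.3%) and sets scores-only to 0;
the furrowing percentages (4.5% / 5.8%) match no denominator present in
the table, so only the counts (17 total, 9 on long bones) are held. In the
tooth-mark anatomical table the row and column totals are consistent (43)
but the within-row column placement is partly interpretive.

## Taphonomic accounting

Percentages are printed to one decimal with round-half-up, computed on
exact integer ratios (decimal arithmetic, no binary-float rounding
artefacts); counts stay integers; zero denominators yield missing values,
never zeros. Denominators follow the conventional rules: length classes
over all specimens; green/dry over fractured long bones; circumference
types over green-fractured long bones only; poor preservation over
specimens excluding teeth; weathering, abrasion, staining and biochemical
alteration over all specimens; tooth-marked bones over well-preserved
non-dental specimens; typology and furrowing over marked bones; taphotype
and notch tables over their own totals.

MNI uses one defensible reading of "laterality plus ontogenetic age",
isolated in a single function so alternatives can be swapped: within each
taxon and age class (unknown age forms its own class), each element
contributes max(n_left, n_right, ⌈n_unsided/2⌉); the class takes the
maximum over elements and the taxon sums over classes. The rule is
monotone — adding a record never lowers an MNI. Taxa too indeterminate for
individual counts (family-level and size-class-only rows) are flagged in
the shipped faunal vocabulary and excluded from MNI/mortality tables.

## Problem sizes used in the checks

The test-suite and acceptance checks run at desk scale, chosen as the
smallest sizes at which the distributional statements are sharp: level
recovery on 2 × 1000-specimen sites over 20 seeds (full classification on
3); quadrat-test calibration on 500 CSR patterns of n = 200 with 199
Monte Carlo replicates each; Hopkins–Skellam null coverage on 500 patterns
of n = 500 with m = 100; fabric recovery over 200 seeds of n = 300;
plunge-profile recovery at n = 5000; DBSCAN versus a brute-force
density-reachability oracle on 200 instances of n ≤ 50; Cohen's κ against
an independent label-expansion oracle on 1000 random matrices.

## Known limitations

- Windows are rectangles; irregular excavation outlines need a bounding
  rectangle and will bias border-corrected statistics near concavities.
- The published coordinate database of the motivating site is not
  deposited, so its spatial headline numbers (χ², A, cluster counts, mean
  axes) are *not* reproduction targets; the synthetic generator reproduces
  their direction and order of magnitude only. The taphonomic tables are
  fully printed and are reproduced exactly.
- The Hopkins–Skellam F null degrades as m → n; keep m ≲ n/5.
- The consensus classifier sees only coordinates; levels that interleave
  laterally (facies changes, faults) violate the banded-geometry
  assumption of the proposal stage.
- Attribute sampling in the generator is marginal, not joint: it will not
  reproduce correlations such as tooth-marked bones being longer, nor any
  spatial segregation of taphonomic classes.
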