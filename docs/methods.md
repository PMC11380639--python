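# Methods

## Problem and scope

Segmental reconstruction of maxillary defects with free fibula transplants
currently requires either full virtual surgical planning or freehand
osteotomies. A mean-value-based, partially adjustable cutting-guide system
would sit between the two, but it needs quantitative evidence that midface
anatomy is regular enough: how far do individual maxillae deviate from a
common reference surface, region by region, and how variable are the
distances and angles that define a two-segment reconstruction of a
hemimaxillectomy defect?

This package implements that measurement pipeline: surface extraction from
CT-like volumes, rigid registration of each subject skull to a reference,
signed region-wise surface-deviation analysis, construction of the
reconstruction landmarks with the derived segment lengths and bend angle,
and the cohort statistics. Because no patient CT cohort ships with the
package, every stage is validated on synthetic skull phantoms whose
deformations are known exactly; the phantom generator is first-class,
tested code.

## Coordinate frame and sign convention

RAS-like axes: +X lateral (left-right measured as |x|), +Y anterior,
+Z superior; "caudal" means smaller z. Signed deviations follow the
inspection-software convention: **negative = subject surface in front of /
outside the reference** (blue in a false-color map), positive = behind
(red), |d| < 1 mm = green, invalid = grey. Phantom region offsets are
specified on this same scale, so an offset of −2 mm displaces the region
outward by 2 mm and is recovered downstream as Dmean ≈ −2 mm.

## Surface extraction (volume_seg)

Bone is selected by an inclusive Hounsfield window, default 226–48,060 HU
(the protocol's virtual-dissection thresholds; the printed bounds do not
state inclusivity, so inclusive bounds were chosen). The binary mask is
zero-padded and converted to a triangle surface by marching cubes at
iso-level 0.5 with voxel spacing applied; orientation is forced outward via
the signed volume. Cleaning keeps the largest connected component and drops
zero-area faces and unreferenced vertices, and is idempotent. No
morphological post-processing is applied. Note that binary marching cubes
chamfers sharp edges: a 10 mm cube loses ~6% of its analytic area, a 20 mm
cube ~3%; the smooth anatomical surfaces this stage targets do not have
such edges.

## Registration (registration)

Alignment follows optical-inspection practice in two stages:

1. **3-point alignment** — a Kabsch least-squares rigid fit (SVD with
   determinant correction; no scaling, no reflection) on the A-point and
   the two deepest points of the inferior orbital rims (IOr/IOl).
   Collinear triplets are rejected.
2. **Local best fit** — trimmed point-to-point ICP refinement. Samples are
   the moving mesh's face centroids (all faces). Each iteration finds the
   exact closest point on the fixed surface for every sample and keeps only
   correspondences within the matching radius, default **4.0 mm** (the only
   parameter the protocol states); the trim is re-applied every iteration.
   Correspondences whose closest point lands on an open boundary edge or
   vertex of the fixed mesh are also rejected — there is no genuine surface
   there. Iteration stops when the RMS change falls below 1e-6 mm or after
   100 iterations (both configurable). Within an iteration the Kabsch
   re-fit can only decrease the RMS over that iteration's correspondence
   set; the per-iteration RMS history is returned and asserted
   non-increasing in the tests.

Closest-point queries use a KD-tree over triangle centroids with an exact
point-to-triangle distance on the candidate set. The candidate radius
`d_guess + r_max` (r_max = the largest centroid-to-vertex distance over all
faces) makes the full query provably exact; inside ICP a k-nearest-centroid
approximation (k = 8) is used, which is exact in practice for near-surface
queries and substantially faster.

**Known property, not a defect:** a least-squares surface fit partially
compensates systematic regional offsets. With labeled regions totalling
~7% of the phantom's surface and a −2 mm offset in one region, the fit
absorbs ~0.05–0.1 mm of the offset. The same property applies to any
best-fit-based inspection workflow; it is why the phantom keeps its labeled
regions a realistically small fraction of the total registered surface.

## Deviation analysis (deviation)

Each labeled reference region is discretized one sample per face (centroid,
outward face normal, face area). For a registered subject, the deviation at
sample p is the distance to the closest point q on the subject surface,
signed negative when q lies along the outward reference normal. A sample is
**valid** iff the unsigned distance is within the measurement window
(default ±5 mm, a stated clinical tolerance) *and* the closest point does
not lie on an open boundary of the subject mesh. The boundary rule is what
turns missing surface (edentulous areas, mesh holes) into grey/invalid
area rather than a spurious short distance to the hole's rim; without it,
valid-area recovery on phantoms with known dropout is geometrically
impossible at realistic region sizes.

Seven parameters summarize a region over its valid samples with area
weights a_i: Dmax, Dmin, the area-weighted mean Dmean = Σa_i d_i / Σa_i and
standard deviation DSD, the valid area AVD = Σa_i (mm²), and the integrals
ID = Σa_i d_i and IAD = Σa_i |d_i| (mm³). The identity ID = Dmean · AVD
holds by construction and is asserted to 1e-9 relative; IAD ≥ |ID| with
equality iff the field is single-signed. Area weighting (rather than a
plain per-sample average) was chosen because the published per-region
tables satisfy ID ≈ Dmean · AVD. A fully invalid region yields AVD = 0,
ID = IAD = 0 and NaN distances. Closest-point deviation (not
normal-shooting) is the implemented definition.

## Landmarks and the cutting-guide template (planner)

Per side: J is the most caudal-lateral vertex of the zygomatic region,
scored as w_c·caudal + w_l·lateral with both coordinates standardized to
the region's bounding box (weights default (1,1); "most caudal and lateral"
is not otherwise operationalized), ties to the lowest vertex index. O is
the closest point on the orbital-rim polyline to J (segment interiors
included; ties to the earlier segment). M = (J+O)/2. The A-point and the
premolar apices X are annotations (on phantoms, generated; on patients they
would be picked or reconstructed by approximation). Segment lengths are
AX = ‖A−X‖ and MX = ‖M−X‖, and the bend angle ∢AB is the 3-point angle at
the shared endpoint X between legs XA and XM — the only construction that
uses exactly the three named points. The lengths are labeled strictly AX
and MX, never anterior/posterior.

Side pooling concatenates the left and right scalar values (no mirroring is
needed for side-symmetric scalars), doubling the sample; for equal side
counts the pooled mean equals the mean of the side means. Side cells report
sample SD (n−1). Reports round to two decimals; the reproduction of
published combined cells truncates at two decimals.

## Cohort statistics (stats)

Tukey fences at 1.5×IQR (normal) and 3×IQR (extreme) with
linear-interpolation quantiles; Welch's t with Welch–Satterthwaite df for
two groups; one-way ANOVA for more; Pearson chi-square on contingency
counts (Yates correction available, off by default); Pearson r; and
univariate k-means (best of 10 initializations, deterministic under seed,
centers sorted) with the elbow criterion — the k maximizing the second
difference of the within-cluster sum of squares over k = 1..6, ties to the
smaller k, and a flat curve therefore resolving to k = 2 (low confidence).
The pipeline fixes k = 2 for clustering and keeps the elbow as a
diagnostic. p-values are reported unadjusted; Bonferroni/BH adjustment
exists behind a flag. Every statistic is verified against an independent
brute-force textbook implementation in the test suite.

## The phantom generator (phantom)

The reference phantom is a closed ellipsoid "head" (semi-axes
75 × 65 × 85 mm, icosphere triangulation; ~5k faces at the coarse setting,
~20k at medium) carrying, on its anterior face, the eight labeled regions
(R1 paranasal, R2 facial sinus wall, R3 zygomatic, R4 alveolar; left/right),
an orbital-rim vertex polyline per side whose designed dip makes the
deepest rim point unique, and the landmark seeds, all exactly on the
surface. A smooth 8 mm lateral-caudal protrusion inside each zygomatic
region makes the J score maximum unique and stable under modest rotations —
a cartoon of the zygoma's shape. Region boxes are sized to give areas near
the published per-region valid areas (~300–600 mm²) and are separated by
≥ 8° parameter gaps so no vertex belongs to two regions. A closed surface
(rather than an open midface patch) keeps the labeled regions ~7% of the
registered surface, as on a real skull; this matters because of the
best-fit compensation property above. The phantom is deliberately not
anatomically realistic: validation rests on recovering known deformations,
not on realism, so passing tests demonstrate correctness of the measurement
chain, not performance on real anatomy.

Subjects are generated from the reference by, in order: per-region normal
offsets drawn N(mean, sd) conditioned on sex (and optionally age), applied
along analytic ellipsoid normals (mesh-smoothed normals inside the zygoma
protrusion); i.i.d. per-vertex Gaussian noise; contiguous face dropout in
R4 (one breadth-first patch per side, grown to the target area fraction);
and a random rigid misalignment (uniform random axis, angle uniform within
the configured magnitude, translation uniform per component). Subject
landmarks are defined as the rigid transform of the reference landmarks
(plus optional jitter, default 0), so ground-truth landmark correspondence
is exact — mirroring that on patients the missing premolar apex is
reconstructed by approximation rather than re-derived from the deformed
surface. All draws are recorded in a truth table; identical spec and seed
give bit-identical cohorts.

Default study conditions: 50 subjects, 68% male, ages uniform on 20–89
(the reported cohort structure); male-only offsets of −1.5 mm (outward) in
R1 and R3 echoing the reported sex effect qualitatively — no quantitative
per-region effect sizes are published, so the magnitude is an explicit
config placeholder; offset SD 0.1 mm and vertex noise SD 0.05 mm, chosen
small because the phantom is a validation instrument (the injected means
are the signal; the jitter only avoids degenerate identical subjects);
dropout fraction 0.1; misalignment within 3 mm / 3°. Age is not coupled to
geometry by default (an age-slope parameter exists, default 0).

## Pipeline and problem sizes

The pipeline registers each subject, computes all eight region fields and
the seven parameters, constructs landmarks on the registered subject,
measures both sides, pools the cohort, and excludes subjects whose R4
valid area is an extreme IQR outlier from the R4 cohort summary (the
edentulous analog), logging every exclusion. Outputs are CSV/JSON with the
configuration hash in every CSV header; identical config + seed give
byte-identical tables.

The shipped analyses and the validation runs use the coarse phantom
(5,120 faces, ~1.5 s per subject for the full register-measure chain) and
a 50-subject cohort; the deviation oracles use icosphere spheres at ~5k
faces. These sizes keep discretization error an order of magnitude below
every tolerance asserted (closest-point error scales with the squared edge
length over the curvature radius, ~0.01 mm here).

## Known limitations

- Point-to-point trimmed ICP converges slowly in the tangential directions
  of smooth, feature-poor surfaces; from an exact landmark initialization
  this is irrelevant, but a cold start needs up to ~200 iterations for
  0.1° accuracy on the phantom.
- The best-fit offset compensation (above) shrinks recovered region
  offsets by a few percent; cohort-level recovery is asserted within
  ±0.1 mm of a −2 mm injected offset.
- The phantom does not model human shape variability, soft tissue, CT
  artifacts, or tooth geometry; statistics on phantom cohorts exercise the
  code paths, not clinical effect sizes.
- The published pooled SDs for the template cells are not reproducible
  from pooling the concatenated side values and are not reproduced here;
  only pooled means are.
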