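# Methods

This note documents the models, conventions and design choices behind
`mandiseg`, in the spirit of a statistical/computational appendix.

## Coordinate conventions

All world coordinates are LPS millimetres (+x toward the subject's left,
+y posterior, +z superior), 0-based voxel indices, and
`world = origin + direction · (index ∘ spacing)`.  NIfTI files are
converted between their native RAS affine and LPS on read/write;
Slicer `.fcsv` fiducials are treated as RAS unless their header says
otherwise.

## Reference frame

The mid-sagittal plane passes through Sella, Nasion and Basion; its
normal is oriented toward the subject's left (resolved from the
inter-Gonion direction).  The horizontal plane is obtained by rotating
the plane through S and N (perpendicular to the mid-sagittal plane,
normal oriented away from Basion, i.e. superiorly) by 6° about the
mid-sagittal normal through S.  The rotation sign is chosen so the plane
tilts *below* the S–N line: after the tilt, Nasion lies on the positive
(superior) side of the horizontal plane.  The vertical and sagittal
planes complete an orthonormal, right-handed triple
(anterior, left, superior) through S.

## Cutting planes and orientation conventions

Deterministic half-space labels require fixed normal orientations:
median normal toward the left; horizontal/C-point normals superior;
Gonion–Menton normal superior; Condylion–Gonion normal anterior; the
Mandibular-Angle normal is oriented so Condylion has positive signed
distance.

The Condylion–Gonion plane is built perpendicular to the *mid-sagittal*
reference plane.  The source description ("normal to the aforementioned
reference plane") has an unresolved antecedent among the three reference
planes; perpendicularity to the mid-sagittal plane reproduces the
classical 2D lateral-cephalogram ramus line swept laterally, which is
the reading adopted here.

**Mandibular-Angle plane.**  Two planes bisect any non-parallel plane
pair: the locus where the two signed distances are equal (normal ∝
n₁ − n₂ for normals oriented consistently) and the locus where they are
opposite (normal ∝ n₁ + n₂).  `bisecting_plane` defaults to the
normals-agree, n₁ + n₂ convention; for the gonial angle this selects the
*exterior* bisector, which would place the entire mandibular body on the
Condylion side.  `build_mandibular_planes` therefore passes an interior
probe point — Gonion displaced along the mean of the unit directions
toward Condylion and Menton, i.e. along the gonial-angle bisector ray —
which selects the interior bisector of the dihedral wedge containing the
bone.  The parent pair defaults to Condylion–Gonion × Gonion–Menton (the
anatomically meaningful split of the ramus line against the mandibular
base); the literal Condylion–Gonion × C-point pairing is available via
`bisector_parents="condylion_gonion+c_point"`.

## Voxel partition

Voxels are classified at their center point.  Tie rules are fixed so an
independent per-voxel oracle can match exactly: "above the C-point
plane" means strictly positive signed distance; zero distance to the
median plane assigns Left; zero distance to the C-point or
Mandibular-Angle plane assigns the inferior label (ramus, resp.
hemibody).  The condyle/coronoid separation is not pointwise: the
26-connected components of the above-C-point mask are split by the
component containing (or nearest to) Condylion.  Fused components
degrade gracefully (everything above the plane becomes condyle, with a
warning).  The hemimandible is defined as *all* foreground on a side —
condyle + coronoid + ramus + hemibody — so the additivity identity is an
exact integer voxel-count identity, and total = left + right.

Cavity filling uses 6-connected background labelling (the dual of
26-connected foreground); a morphological closing with a physical radius
(default 1.0 mm, anisotropy-aware structuring element) is applied first
because the mandibular canal opens at the foramina and a pure hole fill
cannot close it.  On the cavity-free phantom the closing only adds a
small (~20 mm³, resolution-independent) fillet at the condylar-neck
concavity, so discretization-accuracy evaluations run with the closing
disabled; on real data the radius should be left at its default.

Crown removal is abstracted to clipping plane(s) with normals pointing
occlusally: foreground with strictly positive signed distance is
removed.  The per-tooth tailored cutting surfaces of the original manual
workflow are out of scope.

## Phantom

The phantom is a constructive solid: a U-shaped corpus (a box with a
lingual cavity behind a 14 mm chin, leaving two 16 mm lateral arms), a
ramus slab per side rising posteriorly at the gonial angle (default
120°), a vertical condylar neck topped by a condylar ellipsoid, a
triangular coronoid wedge, and clinical-crown cylinders protruding
anteriorly from the symphysis face (removed by a vertical alveolar clip
plane just anterior of the chin — a flat plane above occlusal-surface
bumps would unavoidably also clip the rami, so crowns protrude forward
instead).  Default spacing is 0.4 mm, the typical CBCT acquisition
voxel.

Ground truth is computed by a brute-force per-voxel classifier written
independently of the segmentation module (its own scalar plane algebra
and primitive-membership tests), so segmentation tests are not
self-referential.  Geometry is arranged so the truth rules are exact:

- No corpus voxel lies above the C-point plane, making the literal
  "condyle = above the C-point plane" rule exact.
- The condylar ellipsoid and coronoid wedge are disjoint (26-connexity)
  above the C-point plane, so the component split is unambiguous; the
  generator asserts this at construction time.
- The ramus top stays 2 mm below the sigmoid-notch level so that small
  landmark jitter of the C-point does not sweep the whole ramus surface
  across the cutting plane; the C-point itself sits on the anterior
  surface of the condylar neck.
- The condylar ellipsoid is anchored at its inferior pole just above the
  C-point plane, so an isotropic per-side scale factor `s` changes the
  condyle volume by `s³` (up to voxelization), emulating the condylar
  deficit of JIA.
- Cutting-plane constants and lattice-parallel slab faces are placed
  strictly between voxel centers of the 0.2/0.4/0.8 mm grids, and
  lattice-parallel thicknesses are multiples of 0.8 mm, so voxel counts
  are identical in effect across those resolutions (no tie-breaking on a
  voxel center, no coherent half-cell quantization).  The x-lattice is
  symmetric about the mid-sagittal plane with no center on it, making
  reflection an exact lattice involution.

What the phantom does *not* emulate: trabecular texture and
cortical/trabecular distinction, beam hardening and scatter, the
TMJ fossa, per-tooth anatomy, and the curved continuity of real
cortical surfaces.  Passing the phantom suite therefore demonstrates the
geometric and bookkeeping correctness of the pipeline, not robustness to
real-CBCT artifacts.

## Cohort simulator

Each study arm is parameterized by published per-segment "mean ± SD"
values: for the unilateral arm per affected/unaffected side, for the
bilateral and control arms the published side-averaged parameters are
used for both sides.  Per segment, the two sides are drawn from a
bivariate normal with inter-side correlation ρ (default 0.8 — the
source reports no inter-side correlation; 0.8 makes paired within-
subject contrasts behave like the published paired tests) and resampled
(not clipped) while any side is ≤ 0.  The total mandibular volume is
drawn from its own published distribution rather than summed from
hemimandibles, because the published marginals are not mutually additive
(the control total differs from twice the control hemimandible by
~340 mm³); the simulator reproduces each published marginal, not
within-subject additivity.  Resample truncation is negligible for
mean/SD ratios above ~3.5 (< 0.1%); for the bilateral condyle
(mean/SD ≈ 2.6) it shifts the mean by about +0.9%, which is inherent to
requiring positive volumes.

Two group-size presets exist (the source reports 29/48/25 in its tables
and 40/48/45 in its text); the table preset is the default because the
calibration constants come from the same tables.

## Statistics

- Independent t-tests pool variances (Welch by flag); paired tests are
  used for side contrasts.  Zero-variance degenerate inputs: identical
  constant groups give t=0, p=1.
- Chi-square is Pearson without continuity correction (Yates by flag).
- "Tukey's test with Bonferroni's correction" is contradictory as
  stated in the source; both are implemented.  Bonferroni-adjusted
  pairwise pooled-t (p × k(k−1)/2, capped at 1) is the default, matching
  the pairwise-comparison column of the source tables; Tukey HSD uses
  the studentized-range distribution.
- The four-group ANOVA compares the unilateral affected side, the
  unilateral unaffected side, the bilateral arm (per-subject side
  average) and controls (side average).  Treating the two unilateral
  sides as independent groups replicates the source design but ignores
  the within-subject dependence; this fidelity choice is a documented
  statistical caveat, not corrected.  Since the two sides are positively
  correlated, the test is conservative under the null.
- A failed Shapiro–Wilk gate logs a warning and the pipeline proceeds
  parametric, as the source analysis did.
- ICC defaults to ICC(2,1) (two-way random effects, absolute agreement,
  single rater; the source does not state the model); ICC(3,1)
  (consistency) is available, and the model token is recorded in every
  report.  Both match pingouin's ICC(A,1)/ICC(C,1) to 1e-10.
- Percentage differences use the larger of the two group means as the
  100% reference; the source's own convention is unstated and its
  printed percentages are internally inconsistent, so they are not
  asserted against.
- The a-priori sample size iterates n from 2, computing two-sample
  noncentral-t power with ncp = d·√(n/2), df = 2n−2, and d = |Δ|/SD
  with SD pooled (default) or taken from either group.  With the
  reference values 1007.82 ± 384.27 vs 1424.69 ± 417.64 (α=.05, power
  .95, two-tailed) this gives 26 (pooled), 24 (group-1 SD) or 28
  (group-2 SD) per group; the historically printed 23 is not
  reproducible under any standard two-tailed convention.

## Reliability simulation

The re-digitization study is emulated on phantoms: each synthetic
subject (randomized anatomy) is segmented twice with landmark jitter at
the intra-rater precision (default σ = 0.5 mm, roughly the landmark
click precision at 0.4 mm voxels) and once at a larger inter-rater
precision (default σ = 0.8 mm).  Per segment, the intra pair gives the
intra-rater ICC and the Dahlberg error; the first intra measurement
against the inter measurement gives the inter-rater ICC.  On the default
phantom, 0.5 mm jitter produces per-segment coefficients of variation
below 5% for every study segment (the small coronoid process, which the
study design excludes from its tables, is more sensitive).

## Problem sizes

Defaults were chosen so a full run is interactive on one CPU: the
default phantom grid is ≈ 221×229×129 voxels at 0.4 mm (about 1 s to
generate, 1 s to partition); property suites use 0.8 mm phantoms; the
reliability study uses 10 subjects at 0.8 mm; calibration checks use 200
replicate cohorts.  The half-spacing (0.2 mm, ≈ 3×10⁷ voxel) accuracy
check classifies foreground in 2×10⁶-voxel chunks to bound memory.

## Known limitations

- Plane-based cuts only; no curved cutting surfaces, no mesh-based
  volumetry.
- The median plane is determined by three closely spaced midline
  landmarks; its yaw is the least-conditioned degree of freedom under
  landmark noise, and posterior structures amplify it by the lever arm.
  This is a property of the landmark scheme itself, visible in the
  jitter simulations.
- The cohort simulator reproduces published marginal summaries, not the
  joint distribution of a real cohort (no cross-segment correlations, no
  covariate–volume association).
- No claim about real-patient reproducibility is made or testable here:
  no raw imaging data are available, so all validation is synthetic.
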