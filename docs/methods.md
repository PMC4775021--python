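# Methods

This note documents the geometric model, the synthetic data, the numerical
choices, and the known limits of `femur3d`.

## Coordinate conventions

Meshes are in mm in an arbitrary world frame; every derived axis and angle
is equivariant under rigid motions of the input (verified to ≤ 0.1°, in
practice ≈ 1e-8°). The canonical frame used by the *generator* (not
required of inputs) is: +z proximal, +x medial, +y anterior, left femur.
Right femurs are mirrored across a sagittal-type plane before measurement
so a single sign convention serves both sides; torsion is reported signed
(+ anteversion, − retroversion), and `retroverted` is `torsion < 0` — a
neck lying exactly in the condylar plane (0°) is counted as not
retroverted, because retroversion denotes a strictly posterior neck
orientation.

## Measurement chain

**Longitudinal direction.** Principal axis of the outer surface, refined
by a second PCA pass over the 30–80 % mid-shaft band. The refinement
matters: the head and condyles are asymmetric masses that tilt a
whole-surface principal axis by several degrees; the band-restricted axis
is within ~0.2° of the constructed shaft axis on synthetic bones. The
band is selected along the *oriented* axis (proximal→distal, fixed by the
trochanter-tip landmark) so the result is frame-independent.

**Shaft axis.** Cross sections of the *inner* cortical surface at 25 % and
35 % of bone length; each level's centroid is the area centroid of the
largest closed contour (cortical shells can split into several loops near
the trochanter — the canal is the largest). The two centroids define the
proximal shaft axis. Section planes are perpendicular to the longitudinal
direction; small errors in that direction are immaterial because an oblique
section of a straight tube is an ellipse centered on the tube axis.

**Head center.** Algebraic least-squares sphere fit (linear system from the
expansion of |p−c|² = r²; deterministic, no initialization; exact to 1e-9
on noiseless sphere samples). Head vertices are selected around a seed
point — the farthest off-axis vertex of the proximal fifth, restricted to
the medial half (opposite the greater trochanter) and excluding a 25 mm
ball around the trochanter tip — then the fit is iterated up to four times,
keeping vertices within 1.15 r of the current center and discarding
residuals beyond 2× RMS, which expels neck vertices contaminating the cap.
The fit refuses (low-sphericity error) above an RMS gate of 1.0 mm, and
radii outside 10–40 mm raise a QC flag; both gates are configurable in
`MeasureConfig`.

**Neck isthmus.** Iterative minimal-cross-section search. The candidate
direction starts as head-center → nearest point of the shaft axis; planes
perpendicular to it are swept in 1 mm stations over 0.25–0.9× of the
head-to-shaft distance (1 mm is below the mesh edge length of the default
fixtures); the station of minimal outer-contour area re-anchors the
direction (head-center → minimal-area centroid), and the sweep repeats
until the centroid moves < 0.1 mm (max 20 rounds, error with trace
otherwise). Two robustness details: stations inside the fitted head sphere
are excluded (a section plane grazing the head has near-zero area and would
hijack the minimum in valgus necks), and at each station the contour whose
centroid lies nearest the candidate axis is selected rather than the
largest (the largest would be the head or the shaft cap). The minimized
area is that of the *outer* contour: the narrowest outer cross section is
what "isthmus" denotes geometrically, and on tubular necks its centroid
coincides with the inner one by symmetry. A neck with no waist (area range
< 1 % of the minimum across the sweep) returns the mid-station centroid
flagged `flat_minimum`.

**Condylar tangent ("table-top" line).** Vertices of the distal 25 % are
projected along the shaft direction into a plane; the tangent is the 2D
convex-hull edge whose outward normal points posterior (within 40°) and
whose support vertices are ≥ 15 mm apart — one support per condyle; a
single-condyle geometry has no such edge and errors. Posterior is
disambiguated without any global orientation assumption: the condylar mass
centroid of the distal 10 % lies behind the mid-shaft axis point.

**Angles.** CCD is the full 3D angle between neck direction (isthmus→head)
and shaft direction (proximal→distal) — no frontal-plane projection, since
both axes are true 3D lines and a projected angle would understate valgus
necks with high anteversion. Torsion magnitude is the acute angle between
the neck axis projected into the transversal plane and the condylar
tangent; its sign is the side (anterior/posterior) of the projected head
end. The frontal plane (shaft axis + projected condylar direction, normal
oriented anterior) exists in the API for completeness and fixes the sign.

## Synthetic femurs

`SyntheticFemurSpec` builds a femur from implicit primitives: a shaft tube
(optionally bowed anteriorly, but only distal to 40 % of bone length so the
25 %/35 % levels are provably straight), an hourglass neck tube, a head
sphere, a greater-trochanter sphere, and two condylar spheres placed
mirror-symmetrically so their common posterior tangent is exactly
medio-lateral. The signed-distance min-union is sampled on a voxel grid
aligned to integer voxel multiples (preserving the condylar mirror
symmetry exactly) and the zero level set extracted with marching cubes —
one watertight, non-self-intersecting outer surface without a boolean mesh
engine. The medullary canal is a separate straight tube spanning 45–88 %
of bone length. Grid nodes falling exactly on the surface are nudged
inward by 1e-5 voxel to avoid degenerate triangles.

Both ground-truth angles are imposed analytically and independently: CCD
as the polar angle of the neck axis from the shaft direction, torsion as
the azimuth of its transversal projection from the condylar direction
(applied in that order). `ground_truth_axes` therefore reproduces the spec
angles to 1e-9 by pure trigonometry, and mesh-based measurements can be
scored against exact truth.

Key defaults (mm): bone length 430, head radius 24, neck length 65 with
the waist 32 mm from the head center (clear of the head sphere) and waist
radius 11, shaft outer radius 13.5, canal radius 7, condyle radius 21 at
±22.5 separation — adult dimensions at the scale of a skeletally mature
population. `mesh_subdivisions` is a refinement level mapping to voxel
size 2.0/2^(level−1) mm; the default level 2 (1.0 mm voxels) matches the
~0.8–1.0 mm pixel/slice spacing of clinical thin-slice CT. Optional iid
Gaussian vertex jitter (default 0) emulates segmentation noise; the
voxelized extraction itself already carries CT-like discretization.

**Cohort simulator.** Per-subject true angles follow the covariate
structure reported for large adult left-femur populations: 45 % female;
torsion medians 16.4° (F) / 12.1° (M) with ≈ 9° spread; CCD medians
123.0 / 121.5 with ≈ 5.8° total spread; ethnicity mix 75.7 / 20.3 / 2.5 /
1.5 % (Caucasian / Asian / African / Middle Eastern) with a +1.3° Asian
CCD offset; age clipped-normal (mean 64, sd 15.5, range 19–109, ≈ 92 %
available) driving declines of −1.2°/decade (CCD) and −0.5°/decade
(torsion) about the reference age 65; log-normal BMI (median 25.7,
σ_log 0.168, ≈ 75 % available) with a −0.15°/unit torsion slope — the
mechanism that makes retroverted subjects heavier on average. Residual
spreads (5.5° CCD, 8.9° torsion) are set so the *total* spreads match the
published ones after the age/BMI terms are added. The drift and slope
magnitudes are back-computed from the published Spearman correlations
(ρ ≈ −0.31 age–CCD, ≈ −0.07 BMI–torsion) given those spreads. Derived,
not imposed: the retroverted fraction (≈ 6–8 %, from the normal tail
below 0°), the male excess among retroverted hips, and the young/old
torsion gap.

What the simulator does **not** emulate: cortical thickness variation,
non-circular neck cross sections, osteophytes or pathology, true femoral
neck anteversion–inclination coupling, and segmentation artifacts beyond
iid jitter. Passing recovery tests therefore demonstrate correctness of
the geometry chain on clean anatomy-scale surfaces, not robustness to
real segmentation quality.

## Statistics

Medians and quartiles use linear interpolation between order statistics
(the common spreadsheet/statistics-package default; at n ≈ 1000 the choice
of quartile rule moves the IQR bounds by far less than the 0.1° reporting
precision). Mann–Whitney U uses midranks; p-values are exact by
enumeration when the pooled sample is ≤ 12 without ties, otherwise the
normal approximation with tie and continuity corrections. Wilcoxon drops
zero differences and is exact up to 12 nonzero pairs. Spearman is the
Pearson correlation of midranks with the t-approximation for p. All tests
are two-sided; no multiple-testing correction; missing covariates are
deleted pairwise per analysis. The continuity-corrected normal
approximation agrees with exact enumeration to within 0.02 in p for
per-group sizes ≥ 6 (Mann–Whitney) and ≥ 9 pairs (Wilcoxon); at the very
smallest sizes (pooled n = 8) the intrinsic gap reaches ≈ 0.03, which is a
property of the approximation itself, so the exact path is the default
there. Ethnic subgroups below a configurable floor (default 30) are
excluded from subgroup tables and listed with their sizes.

## Numerical choices and degenerate inputs

* Section loops are assembled from plane–triangle segments welded at 1e-9
  of mesh scale; open chains (numerically grazing contacts) are dropped. A
  plane coincident with mesh faces is retried after a 1e-7 × scale nudge
  along its normal.
* Contour area/centroid use the shoelace formula in an orthonormal
  in-plane chart; self-intersecting contours are rejected (shapely
  simplicity test).
* Coplanar point sets are rejected by the sphere fit (rank test); a
  non-positive fitted radius is an error.
* Containment validation (inner surface inside outer) uses a
  self-contained vectorized ray-parity test, so no spatial-index backend
  is needed.
* All arithmetic is double precision; angles are degrees at the API
  surface and radians internally.

## Problem sizes used in the shipped analyses

The validation grid is 50 noiseless femurs (CCD 110–140°, torsion −20–40°)
at the default 1 mm voxels; rigid-motion invariance uses 20 random
motions; the rank-test comparison uses 200 seeded draws per test; the
simulated cohorts are n = 1070 (analysis scripts) and n = 500 (emulation
checks), with meshes built for small subsets where the end-to-end chain is
exercised. These sizes make the whole pipeline reproducible in a few
minutes on one CPU while keeping every estimate's sampling error well
below the tolerances being checked.

## Known limitations

* The landmark heuristics (trochanter tip, patellar saddle) are simple
  geometric extremal rules, adequate for the synthetic anatomy and for
  seeding, but not anatomically validated; real-data workflows should
  supply landmarks.
* The isthmus search assumes a roughly tubular neck; grossly non-convex
  neck cross sections (severe cam morphology) may bias the centroid.
* The condylar tangent assumes two posterior prominences ≥ 15 mm apart in
  the transversal projection.
* Measurement accuracy is reported on synthetic surfaces; CT segmentation
  error of real bones adds variance not modeled here beyond optional
  vertex jitter.
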