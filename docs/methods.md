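# Methods

`condylefit` implements a parametric, hand-inspired design procedure for the
bone-facing (attachment) surface of femoral condylar prostheses.  The central
idea is to replace free-form CAD surface modelling with a small set of
anatomically meaningful parameters: each condyle carries four "finger"
contour feature lines (the index/middle/ring/little fingers of the hand
analogy), each line is a five-point chain parameterized by three interior
bending angles and four phalanx segment lengths, and the chain family is
anchored to the condyle's extremal landmarks.  Lofting the four lines gives a
fitting surface; projecting it back onto the bone, segmenting the enclosed
region and reconstructing it gives the attachment surface.  Fit is measured
by the symmetric Hausdorff distance between point samples of the attachment
surface and the native condylar region.

## Anatomical frame and landmarks

The frame is a right-handed orthonormal triad: *coronal* axis
(medial→lateral), *sagittal* axis (posterior→anterior), *vertical* axis
(distal→proximal).  The coronal plane is spanned by (coronal, vertical) and
the sagittal plane by (sagittal, vertical); widths are coronal-plane
projections, heights sagittal-plane projections.  Without a user hint the
frame is the mesh's principal-axis triad, labelled by extent (vertical gets
the largest extent, then medial–lateral, then anterior–posterior); with CT- or
generator-derived data the frame should be passed explicitly.

Each condyle contributes four landmarks, the extremal vertices of its region
along the coronal and vertical axes: `M_medial`, `M_lateral`, `M_high`,
`M_low` for the medial condyle and the `L_*` analogues for the lateral one.
The medial condyle lies on the negative side of the coronal axis.  Regions
come from per-face tags when available, otherwise from a sagittal split plane
placed at the emptiest coronal cross-section (the intercondylar fossa).
Extremal ties resolve to the lowest vertex index, so detection is
deterministic and equals an exhaustive vertex scan by construction.  Landmark
detection is automatic here; on clinical data the landmarks can equally be
supplied as a JSON file.

## Contour feature lines

For a finger with index *i* ∈ {1..4} on one side, the three joint-level key
points are anchored at the side's high / extreme / low landmarks (extreme =
`M_medial` medially, `L_lateral` laterally — the outward extreme of each
condyle) and displaced by offsets

    h_k = (i − 1) · span_k / 3 · c_k ,   k = 1, 2, 3

where `span_k` is a condylar landmark span and `c_k` one of six dimensionless
coefficients (`delta1..3` medially, `epsilon1..3` laterally; calibrated
population default 0.76).  As published, the medial level-1 offset uses the
medial span while levels 2–3 use the lateral span; a `span_convention`
switch selects the all-medial variant.  Index finger (*i* = 1) offsets vanish,
so its joints sit exactly on the landmarks.

**Offset direction.** Successive fingers are displaced along the
anterior–posterior axis (medial fingers posteriorly, lateral fingers
anteriorly, matching the sides' negative/positive sign convention), so the
four lines of one side drape across the condyle's AP depth like fingers over
a knuckle.  Displacing them along the medial–lateral axis instead — a
reading the terminology would also admit — collapses all four lines onto a
single silhouette curve after the medial–lateral projection of Step 3, i.e.
it cannot produce a two-dimensional attachment patch; the AP convention is
therefore the only self-consistent one and is fixed here.

**Start/end points.** The chain's start and end lie on an "osteotomy plane"
taken parallel to the adjacent phalanx segment at perpendicular distance `d0`
on the outward (convex) side of the chain.  With that convention the
end-segment length identity `m = d0 / cos(α − 90°)` holds for every
end-segment slant α, and the slant itself is a free parameter: it is taken
from the design row's first/third bending angle when available, else 135°.
`d0` is a surgical input with no canonical value; the package default is
5 mm.  `compute_segment_lengths` measures the end segments either through the
`d0`-identity (when `d0` is given) or as Euclidean lengths (`d0=None`); the
reference design rows are not mutually consistent with a single `d0`
(`m1·cos(α1−90°)` ≠ `m4·cos(α3−90°)` in group 1), so round-trip checks use
the Euclidean form.

**Parameterization and inversion.** Bending angles are the interior angles at
the three joints (arccos of normalized incident segment dot products,
degrees; radians internally); middle lengths are joint distances.
`forward_construct` rebuilds a planar chain from any valid
(angles, lengths) row with all joints turning toward the same half-plane;
re-measuring the chain reproduces the row to ≈1e−12, and all eight reference
design rows round-trip within 0.01°/0.01 mm.

Smooth feature curves interpolate the five key points with a chord-length
parameterized cubic spline (`not-a-knot`); the key points are kept verbatim
among the dense samples.

## Fitting surface (loft)

The four curves of one side are lofted: per sample column, a transverse
chord-length cubic spline through the four corresponding points is tessellated
into `transverse_samples` intervals per band, producing a quad grid that is
triangulated along shortest diagonals.  Input curve samples remain mesh
vertices, so the surface interpolates the curves exactly.  A transverse-order
check (monotone projection onto the first→last chord per column) rejects
crossing curves.  With the default coefficients the loft's transverse extent
is 0.76× the landmark width parameter by construction; the discrepancy with
the nominal width is reported, not enforced.

## Projection, segmentation, reconstruction

Each side's curves are cast onto that side's condylar submesh along the
per-side-signed coronal axis (medial curves toward −coronal, lateral toward
+coronal); restricting the target to the side submesh prevents rays from
crossing the fossa onto the opposite lobe.  Only the span between the first
and third joint points is projected — the start/end phalanx extensions belong
to the resection planes and deliberately overhang the bone.  Samples whose
line misses the mesh clamp to the closest surface point and are flagged; a
curve erroring out when more than `max_miss_fraction` of its samples miss
(0.5 for standalone use, 0.9 in the pipeline where outer fingers may overhang
the silhouette at their offset station).

The segmentation boundary is the projected index-finger curve plus the
reversed little-finger curve; consecutive points snap to nearest mesh
vertices and gaps are bridged by shortest edge paths (geodesic connectors),
closing the loop.  Face adjacency is cut along the resulting edge walk and
the connected component containing an interior seed (a midpoint sample of the
projected middle finger) is extracted.  Reconstruction fan-fills interior
holes (the outer boundary loop is kept) and fairs interior vertices by a
Laplacian update projected onto the vertex normal (relaxation 0.5, 1 pass by
default) with all boundary vertices fixed.  The normal projection matters:
the plain umbrella operator slides irregular marching-cubes vertices
tangentially by millimetres while the actual off-surface correction is only
tenths of a millimetre, and that tangential slide would contaminate a
point-sampled surface-distance metric.

## Fit assessment

Fit is the symmetric Hausdorff distance

    H(A, B) = max( max_a min_b |a − b| , max_b min_a |a − b| )

between point sets on the attachment surface (A, the "plate") and the native
condylar region (B).  Sampling is area-uniform at 10 points/mm² (a surface
density; the volumetric figure sometimes quoted for this protocol is not
dimensionally meaningful on a 2-manifold).  Because reconstruction preserves
the region's triangulation, the pipeline samples *corresponding* points — one
set of seeded barycentric draws evaluated on both meshes, plus both vertex
sets — so the metric measures true surface deviation; two independent random
clouds at this density have a mutual coverage radius of ~0.5 mm that would
otherwise dominate.  Nearest neighbours use exact dense distances for small
sets and a KD-tree for large ones; both equal the brute-force double loop
exactly.  Summary statistics over design groups report mean, sample SD
(ddof = 1) and CV = 100·SD/mean.

On the fine (3 mm) synthetic fixture with default coefficients and the
group-1 design row the end-to-end Hausdorff distance is ≈0.34 mm, below the
0.5 mm micromotion threshold used as the clinical benchmark; the coarse
(8 mm) fixture gives ≈0.8 mm, and the projected-contour curvature SD likewise
drops with refinement — the precision–efficiency tradeoff the two-tier
(coarse calibration / fine evaluation) workflow exploits.

## Coefficient calibration

The six offset coefficients cannot be derived from first principles and are
calibrated on a cohort: minimize the mean Hausdorff distance between the
candidate design's projected contour feature lines and each case's reference
feature lines, averaged over cases, sides and fingers.  Keeping sides and
fingers as separate Hausdorff problems is essential for identifiability: a
pooled point set lets the worse side mask the better side's signal inside the
max, and lets finger *i* alias onto reference finger *j* at rational offset
ratios, producing spurious optima.

Optimization is Nelder-Mead, bounded to (0.1, 2.0) by clipping, from an
all-1.0 start with initial simplex step 0.15.  Two structural aids are used:
(1) the objective is additively separable (deltas only enter the medial side,
epsilons the lateral), so the 6-D problem is solved as two independent 3-D
simplex runs — the same minimizer, far better conditioned; (2) each block is
restarted from its best point with shrinking initial steps (0.15/0.05/0.02,
`adaptive=True`), the standard remedy for simplex stagnation on
minimax-type landscapes.  Candidates whose contours leave the bone entirely
clamp to the silhouette rim and score poorly rather than erroring, so the
search box contains no failure walls.  The best-objective trace is monotone
non-increasing by construction.  Function tolerance is 1e−3 mm — the
objective's resolution is bounded by mesh granularity, so tighter tolerances
buy nothing.

On seeded 5-case synthetic cohorts whose references are generated with all
six coefficients planted at 0.76, calibration from the all-1.0 start recovers
every coefficient within 0.01 (well inside the 0.1 acceptance band), in
≈400–450 objective evaluations (~2 minutes at the 3 mm cohort resolution).

## Synthetic anatomy

Patient CT is not available to this package's tests, so a parametric implicit
fixture stands in: two ellipsoidal condylar lobes (default coronal × AP ×
vertical half-extents 10.6 × 28 × 20 mm medial, 11.4 × 27 × 18 mm lateral)
separated by a 20 mm intercondylar fossa and joined by a smaller proximal
blending ellipsoid, meshed by marching cubes at a pitch equal to the
requested edge length (8 mm "coarse" to 3 mm "fine").  The coronal
half-extents keep the condylar width parameters near the reference design
values (W ≈ 21–23 mm); the AP half-extents are sized so that finger offsets
up to coefficient ≈1.3 remain on the bone, which keeps the calibration search
region feasible and matches adult condylar AP dimensions.  Face regions are
tagged by the component with the largest gradient-normalized implicit value
(a first-order signed distance; raw quadratic values of differently sized
ellipsoids are not comparable near blend creases).

All landmarks have closed forms on the generating ellipsoids.  Extremal
detection on the mesh recovers each landmark's defining coordinate within one
edge length at every resolution; Euclidean agreement also holds for the
default shape but is ill-posed in general (an elongated lobe is nearly flat
around its extreme, so the winning vertex may sit anywhere in a flat band).
Cohorts draw independent log-normal factors (σ = `variation`) for the seven
shape parameters, so linear dimensions vary with CV ≈ `variation`;
generation is deterministic per seed.

The fixture reproduces what drives the pipeline — convex lobes, fossa gap,
extremal landmarks, resolution effects — and omits trochlear groove
geometry, asymmetric posterior condylar flare, cartilage, osteophytes and CT
segmentation noise.  Passing tests therefore demonstrate correctness of the
geometric machinery and calibration identifiability under controlled
conditions, not clinical fit on real femora; the published sub-millimetre fit
on patient data depends on anatomy this generator does not emulate.

## Numerical choices and limitations

* Ray casting and closest-point queries are dense vectorized primitives
  (Möller–Trumbore; Ericson's point-triangle regions) — exact, and faster
  than spatial indexing at the few-thousand-face meshes this pipeline uses.
* Quad meshes are triangulated on load; lofted quads split along shortest
  diagonals.
* Angles are degrees at every file/API boundary, radians internally; all
  coordinates mm.
* Boundary snapping quantizes the attachment rim to mesh vertices (≤ half an
  edge length); a sub-edge-accurate mesh cut is out of scope.
* The segmentation assumes the projected boundary separates the side submesh
  into exactly two components; pathological self-crossing boundaries raise
  rather than guess.
* Calibration recovers the planted truth on synthetic cohorts; on real
  cohorts the objective floor is nonzero and coefficient identifiability will
  degrade gracefully toward the population mean.
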