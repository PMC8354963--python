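# Methods

This note documents the models and numerical choices behind `sinusid`: the
superimposition pipeline itself, the synthetic cohort that stands in for
the CT data, and what the replicated study does and does not demonstrate.

## Coordinate conventions and measurements

All meshes are triangulated surfaces in millimetres, in a canonical
anatomical frame: x = left-right, y = posterior-anterior, z =
inferior-superior. Maximum breadth and height are axis-aligned vertex
extents (max − min along x and z respectively) — the "outermost borders"
reading of the classical definitions — so real meshes must be pre-oriented
into this frame before the measurements mean anything; synthetic meshes
are generated in it. Volume is the divergence-theorem (signed-tetrahedra)
volume of a watertight, consistently oriented surface, computed in mm³ and
reported in cm³. Non-watertight meshes are accepted for registration and
distance work but rejected for volume, with the open-edge count in the
error.

## Point-to-surface distances

The identification statistic is directional: the RMS of Euclidean
distances from each vertex of a query mesh to the *nearest point on any
triangle* of a reference mesh (not the nearest vertex — nearest-vertex
correspondence would couple the statistic to tessellation density, which
differs between independent segmentations). Query points are the query
mesh's vertices; no resampling.

Exactness matters because the whole study lives in the 0.01 mm regime, so
the engine is exact, not approximate: a uniform grid over triangle
bounding boxes is searched in expanding Chebyshev rings, stopping when the
nearest possible point of the next ring is provably farther than the
incumbent ((R−1)·cell bound, with every triangle registered in every cell
its AABB overlaps). The point-triangle projection is the standard
barycentric region analysis. A numba-compiled kernel does this at a few
microseconds per query; without numba an equivalent (exact, slower)
k-d-tree candidate-escalation path is used. The test suite pins both paths
to an exhaustive all-triangles scan at 1e-9.

Signed distances (used only for the chromatic maps) take their sign from
the angle-weighted pseudo-normal at the closest point: face normal on
triangle interiors, adjacent-face sums on edges, angle-weighted vertex
normals at vertices — the convention that makes inside/outside well
defined on watertight surfaces. Chromatic maps colour vertices green
within ±0.5 mm (default band), red outward, blue inward; the band is a
display parameter only and never enters statistics.

## Registration

Rigid, whole-surface, point-to-point ICP:

1. nearest-surface correspondences for the moving mesh's vertices (or a
   seeded random subsample, a speed knob only);
2. least-squares rigid update (Kabsch/SVD with reflection correction);
3. stop when the correspondence RMS changes by less than `tolerance_mm` or
   at `max_iterations` (non-convergence is a flagged result, not an
   error). The recorded objective trace is non-increasing by construction
   of the alternation; the suite asserts this on 100 random pairs.

No outlier trimming and no scale estimation: identification compares
true-scale models and the described objective is the whole surface.

Initialisation must be deterministic and pose-free (synthetic pairs arrive
in random poses): centroids plus principal axes, which leaves a four-fold
proper-rotation sign ambiguity. Each of the four candidates is refined by
ten coarse ICP iterations on a ~600-point probe before the best basin is
kept — for dissimilar shapes the statically best-looking candidate is
sometimes a flipped basin that full ICP cannot leave.

Two tolerance regimes are used deliberately. `icp_register` defaults to
1e-6 mm (the geometric contract: a displaced copy registers back to
RMS < 1e-6). The *study* runs at `tolerance_mm = 3e-3` with a 2000-vertex
subsample: the quantities under study are 0.01 mm-resolution RMS values,
and stopping at a millimetre-scale rule is what any practical comparison
software does; chasing micrometre optima only manufactures deterministic
micro-differences between protocols that the real instrument could never
resolve.

## The four protocols

Within a quartet the registration onto a given reference is computed once
and shared by the two groups that use it ({A,B} and {C,D}); this isolates
the two factors cleanly (and is switchable with
`share_registration=False`). The distance query mesh is always the model
that is not the distance reference, after registration. Distances to a
*moved* reference surface are evaluated by inverse-transforming the query
points instead, so one spatial index per mesh serves all four groups.

Protocol RMS values are reported at 0.01 mm resolution — the granularity
at which 3D comparison software prints RMS and at which the replicated
tables are stated. Full precision is available via
`rms_resolution_mm=None`.

## Statistics

Two-sided paired Student's t-tests (t = d̄/(s_d/√n), df = n−1) compare the
reference-swapped groups: {B,C} and {A,D} for the registration swap, {A,B}
and {C,D} for the calculation swap, separately in matches and mismatches.
Pearson correlations relate each |RMS difference| to each |size
difference|, with p-values from t = r√((n−2)/(1−r²)). Raw p-values are
reported against 0.05/0.001 flags with no multiple-testing correction,
matching practice in this literature. All-zero paired differences are the
degenerate identical-samples case (t = 0, p = 1, flagged); correlations on
degenerate columns are recorded as NaN rather than raised when assembling
tables. Separability reports the match maximum, mismatch minimum, overlap
flag and classification accuracy at the 0.96 mm threshold (match iff
RMS < threshold).

## Synthetic cohort

Each subject is an implicit surface meshed by marching cubes at
`voxel_pitch` (default 1.0 mm, ≈ CT resolution; the fidelity/speed knob):

* 2–5 Gaussian lobes per side, anisotropically elongated, placed along a
  frontal-bone arc (per-subject radius ≈ N(80, 6) mm) so every subject
  shares the gross cranial curvature;
* 8–13 small signed satellite blobs — scalloped lobulations and carved
  recesses, the fine structure that makes sinus outlines individual;
* the left side mirrors the right with per-lobe perturbations
  (left-right asymmetry factor drawn per subject);
* the mesh is rescaled so breadth and height hit per-subject targets drawn
  from N(56.9, 11.2) and N(32.0, 7.0) mm, while antero-posterior depth is
  an *independent* target ≈ N(10.6, 2.0) mm — sinus depth does not scale
  with frontal size, and this independence is what keeps size-matched
  subjects geometrically distinct. Volume is not targeted directly; the
  lobe geometry and depth calibration land its mean near 8.9 cm³.

Both cohort samples are *independent re-segmentations* of one base mesh
per subject, so the two segmentation processes are exchangeable — as they
are when one CT scan is segmented twice. Each re-segmentation applies:

* white Gaussian vertex displacement along normals (sd 0.21 mm) followed
  by one volume-preserving Laplacian smoothing pass — the surviving
  correlated field reproduces the ≈ 0.16–0.18 mm match-RMS regime;
* a small inferior-border (ostium crop) shift, sd 0.12 mm;
* a pose jitter of up to 14° / 2 mm. Registration removes the pose again,
  but the axis-aligned size measurements are taken in each model's stored
  frame, so pose differences reproduce the reported match-pair size
  variability (|Δbreadth| ≈ 0.4, |Δheight| ≈ 1.1 mm) without touching any
  RMS quantity;
* optional global threshold-offset and local patch channels
  (`threshold_offset_sd`, `patch_noise_sd`, both default 0 — see
  Limitations).

Mismatch pairs follow a uniform random derangement of the subjects
(rejection-sampled; no subject is ever paired with itself). The master
seed is split into per-subject, per-stage child seeds, so any single pair
is reproducible in isolation and the full cohort is a pure function of its
seed.

Default study size is the original design (50 subjects, so 50 matches and
50 mismatches, four protocols each); the `--quick` CLI profile (10
subjects, 1.5 mm pitch) exists for smoke runs. A full default replication
is a few minutes of one CPU; unit tests run on coarser, smaller cohorts.

## What the replication shows — and does not

On the default seeded cohort the pipeline reproduces the study's
qualitative findings: no match/mismatch RMS overlap at 0.96 mm; match
results insensitive to every reference choice; registration-reference
swaps significant only in mismatches (the RMS measured in the ICP-minimised
direction is systematically the smaller one); calculation-reference swaps
non-significant but strongly correlated with breadth and volume
differences in mismatches.

Known deviations, all consequences of the pipeline being deterministic
where the original measurements were not:

* Match |Δvolume| is ≈ 0.02 cm³ against the reported ≈ 0.5 cm³. Any
  geometric channel strong enough to move volume by half a cm³ between two
  segmentations acts as a net surface offset, whose directional-RMS
  asymmetry then correlates with |Δvolume| across matches — a correlation
  the published matches column does not show. The generator therefore
  keeps geometric volume noise below the 0.01 mm reporting quantum; the
  `threshold_offset_sd` / `patch_noise_sd` knobs restore larger volume
  differences at the cost of that correlation.
* Match registration-swap deltas correlate weakly with breadth (r ≈ 0.3)
  through pose-magnitude → registration-path coupling; the published
  matches column is non-significant there.
* The mismatch minimum RMS sits just above the threshold (as in the
  original cohort), but this is a property of one cohort draw: across
  other master seeds roughly one cohort in four contains a pair of
  genuinely similar subjects that dips below 0.96 mm — a caveat that
  applies to the identification threshold itself, not to this
  implementation.

The noise model is a statistical surrogate for segmentation
repeatability, not a physical model of partial-volume or ostium-cropping
effects, and the shape family is calibrated for distinctiveness, not
anatomical validity. Passing tests therefore demonstrate the behaviour of
the *procedure* under controlled conditions; they are not evidence about
real CT cohorts.
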