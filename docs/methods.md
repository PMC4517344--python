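# Methods

## The measurement problem

When a rotary NiTi file separates in the mesiobuccal (MB) canal of a
maxillary first molar, retrieval requires cutting dentin: a staging
platform down to the fragment and an ultrasonic trough around it.  The
decision to attempt retrieval hinges on the **minimum remaining dentin
thickness (RDT)** after that removal space is cut — too little wall and
the root strips or fractures.  Clinically the RDT is estimated on
periapical radiographs; this package quantifies, in a fully controlled
voxel simulation, how the radiographic estimate relates to the true 3D
minimum.

Three estimates are compared on every tooth:

* **3D-RDT** — minimum wall thickness measured on the 3D volume (gold
  standard);
* **Pa-RDT** — measured on the 0° buccolingual (paralleling) projection;
* **An-RDT** — measured on a projection at the horizontal *parallax* angle
  that just frees the MB root from palatal-root overlap.

## Coordinate and label conventions

Volumes are `uint8` label grids (background / dentin / canal / metal /
removed) with isotropic voxels; world coordinates in μm; grid axis 2 is the
tooth long axis (apex low, orifice high).  Horizontal rotation is about
this axis with the convention `x′ = x cosθ + y sinθ`: positive angles move
the palatal root distally (+x in the image).  All thickness assertions in
the tests carry a ±1-voxel tolerance.

## Synthetic phantom

No public micro-CT archive of the study anatomy exists, so the pipeline
runs on parametric phantoms that reproduce the three structural features
the comparison depends on.  Defaults (all configurable; chosen once at
literature scale for a maxillary first molar):

| parameter | default | rationale |
|---|---|---|
| voxel size | 30 μm (params), 60 μm in the population runs | 30 μm mirrors common micro-CT practice; 60 μm keeps a 36-tooth run on one CPU in minutes and stays ≪ the effects measured |
| MB canal centreline | cubic through (0,0,11.5), (0,0.15,9.0), (0,0.6,5.5), (0,1.1,1.5) mm | gentle palatal-ward curvature typical of MB canals; ~10 mm canal arc |
| canal radius profile | 350 → 140 μm (orifice → apex) | a prepared/patent MB canal that accommodates the 430 μm fragment |
| outer wall radius | 1600 → 700 μm | MB root tapering towards the apex |
| furcal concavity | spherical-cap indentation, depth 300 μm, arc extent 2–7 mm, azimuth 40° (between distal and palatal) | the furcation-facing groove of the MB root; its depth is the hidden wall loss |
| palatal root | radius 2 mm, offset (1.2, 7.0, 0) mm | overlaps the MB root at 0° and separates near 20° of horizontal rotation |
| attenuation (mm⁻¹) | dentin 0.07, metal 1.5, spaces 0 | only ratios matter for silhouettes; metal ≫ dentin |

The concavity azimuth sits between the distal (+x) and palatal (+y)
directions, so at 0° the indentation lies essentially along the ray and
leaves the silhouette almost unchanged (the tests bound the silhouette
loss at <3 %), while the parallax rotation swings it partly into profile.
This is the entire mechanism of the paralleling overestimate in the model.

A crown-level dentin slab joins the two roots (one connected tooth); the
apical 1 mm of each root is closed with a rounded cap so the canal is
enclosed except at the orifice.  Generation is deterministic given
(params, seed); the seed only feeds an optional surface-roughness term
that defaults to off.

**Population sampling** multiplies each varied field by `1 + spread·N(0,1)`
(independent per field, resampled on invariant violation, max 100 tries).
Default spreads: 5 % on radii profiles and palatal offset, 25 % on
concavity depth, 15 % on its azimuth, 20 % on centreline curvature —
inter-tooth variability large enough that the method-agreement ICCs are
informative, small enough that no phantom perforates.  The study
population is n = 36 phantoms, both fragment depths measured on each tooth
(each tooth its own control).

### What the generator does *not* emulate

Real enamel/pulp-chamber anatomy, MB2 canals, isthmuses, apical deltas,
oval canal cross-sections, scanner noise and beam hardening, and the
zygomatic-process shadow.  Passing tests therefore demonstrate the
*mechanism* (concealed furcal wall loss biases paralleling radiographs
upward) and the correctness of the numeric kernels — not the magnitudes to
be expected in extracted teeth, which depend on anatomy the phantom only
sketches.

## Removal simulation

* Fragment: truncated cone swept along the canal centreline from arc
  length `depth` (coronal end, Db = 0.43 mm) to `depth + 3 mm`; depth is
  measured as *arc length* below the orifice (the canal is curved), and
  the coronal end — not the centre — sits at the stated depth.  Metal only
  ever replaces canal space: a file conforms to the canal, it does not cut.
* Staging platform: cylinder of the Gates-Glidden #4 nominal diameter
  (1.1 mm, configurable) along the straight-line access direction — the
  canal tangent at the fragment's coronal end extended coronally — from
  the orifice to the fragment.  Dentin/canal → removed; idempotent.
* Trough: cylinder of diameter `D = Db + 2·0.40 mm = 1.23 mm`, coaxial
  with the fragment's coronal tangent, 1.5 mm apically.  Metal is never
  removed.  If the freshly carved space touches exterior air the volume is
  flagged perforated (reported as RDT = 0) rather than raising — a
  perforated attempt is a legitimate outcome of the simulated procedure.

## 3D thickness mapping

"Exterior" is background connected to the grid boundary (flood fill), so
the canal and enclosed voids never terminate a distance ray.  The
per-voxel distance field to the exterior is a Euclidean distance transform
(anisotropy-aware, voxel-centre to voxel-centre); the thickness map reads
it at cavity-wall surface voxels (canal/removed voxels 6-adjacent to
dentin).  Because carving only relabels interior voxels, the distance
field is computed once per phantom and reused across depth groups.

The ROI defaults to the trough's axial span — the danger zone.  The access
corridor's own coronal opening is deliberately excluded: distance through
the orifice to open air is not a wall thickness.  Ties for the minimum are
broken by lowest voxel index (C order) for determinism.  Centre-to-centre
distances carry a systematic +½…+1 voxel offset versus the continuous
geometry; all oracle comparisons allow ±1 voxel.

## Projection and parallax

Parallel-beam (orthographic) geometry: the attenuation field is rotated
about the long axis (trilinear interpolation, symmetric padding so no mass
leaves the grid and the pivot is preserved) and summed along the fixed ray
axis.  Orthographic rays make the analytic chord-length and mass-
conservation oracles exact and remove magnification from the 2D
measurement.  Binary structure silhouettes are rotated with
nearest-neighbour sampling to avoid partial-volume leakage.

The parallax angle is the smallest rotation (scanned in 0.5° steps,
configurable, positive = palatal root moves distally) at which the MB and
palatal silhouettes share no image pixel.  For speed, a per-slice interval
bound on rotated boundary-voxel extents first discards angles that are
certainly still overlapping; candidate angles are then verified on the
rasterised silhouettes themselves, and a brute-force fine-step rotated-mask
scan serves as the independent oracle in the tests.  If no angle separates
the roots, the minimum-overlap angle is reported with the full profile.
Zero-pixel overlap is an exposed threshold parameter; the default (0) is
the strictest reading of "unimpeded view".

## 2D measurement

The access rectangle (width `D`, height `depth + trough depth`) is centred
on the projected access-corridor axis — the canal axis at the fragment's
coronal end — with its top edge at orifice level.  Anchoring on the
corridor rather than the orifice mirrors where the operator draws the
rectangle and keeps the measurement of a curved root honest at oblique
angles.  The RDT is the minimum horizontal distance (per image row, over
the rectangle's vertical extent) from the rectangle's side to the root
silhouette edge on that side; horizontal distances match a ruler
measurement on a film, and a point-to-nearest-edge variant is available.
The distal (furcal) side is the primary reading — the danger zone — with
the mesial side also recorded.  The silhouette threshold is 5 % of the
peak pixel value.

Measurements are taken on the MB-root-only projection (palatal root masked
out).  On a real paralleling film the palatal shadow overlies the MB root,
yet the observer still traces the MB outline; a plain threshold of the
full-tooth image cannot do that (its distal edge would be the palatal
root's), so the isolated projection stands in for outline identification.
At the parallax angle the roots are separated and the distinction
disappears.

A rectangle side falling outside the root silhouette reads 0 — the
radiographic analogue of perforation.

## Statistics

* Two-way fixed-effects balanced ANOVA (method × depth) with interaction,
  computed from sums of squares in-package and cross-checked against
  statsmodels in the tests.  Tooth is not modelled as a random factor; a
  random-intercept extension would be natural but is out of scope.
* Dunnett many-to-one comparisons (Pa vs 3D, An vs 3D) within each depth
  group at α = 0.05, via scipy's multivariate-t implementation;
  the single-comparison case reduces to the two-sided t-test (tested).
* ICC: two-way single measures from the ANOVA mean squares.  Both
  consistency — ICC(3,1) — and absolute agreement — ICC(2,1) — are
  reported; consistency is primary since the question is whether the
  radiograph *tracks* the true thickness.  Zero total variance is an
  error, not a value.
* Coefficient of variation: sample SD / mean of the 3D values per depth
  group.

## Problem sizes and determinism

Population runs use 36 phantoms at 60 μm voxels (~3 M voxels each); a full
run with both depth groups takes a few minutes on one CPU.  Analytic
fixtures in the tests use 30–100 μm voxels.  Everything downstream of the
configuration seed is deterministic: rerunning a configuration yields
byte-identical CSV outputs, and the log records the seed and a hash of the
scientific configuration.

## Known limitations

* Per-slice disc rasterisation approximates the swept tube; for strongly
  curved canals the cross-section perpendicular to the tangent is slightly
  elliptical in the slice plane.  The same applies to the tilted trough
  cylinder.
* Parallel-beam geometry ignores cone-beam divergence and magnification;
  clinical films would add a scale factor and blur.
* The 2D observer is idealised (exact thresholding, exact rectangle
  placement); human measurement variability is not modelled.
* Structure masks are not serialised by the MHD/NIfTI writer (labels,
  geometry, centreline and perforation flag are); volumes re-read from
  disk support 3D measurement but not the root-separation search.
* Magnitudes of the Pa/An/3D differences are phantom-dependent; only their
  directions and orderings are claimed.
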