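# Methods

This note documents the models, numerical choices and limitations behind
`fetalfold`, in the order the pipeline runs.

## Mesh model and differential geometry

Surfaces are closed, edge-manifold triangle meshes in millimetre world
coordinates, counter-clockwise winding viewed from outside (signed volume
positive). Loading merges duplicate vertices at 1e-6 mm, drops zero-area
faces and unreferenced vertices, audits every edge (exactly two incident
faces when closed; any other valence is an error), and supports OFF,
Wavefront OBJ (`v`/`f` records, 1-based indices) and legacy ASCII VTK
polydata.

Per-vertex areas use the Meyer *mixed Voronoi* rule: the Voronoi cell
inside non-obtuse triangles, a T/2 : T/4 : T/4 split inside obtuse ones.
The rule partitions total surface area exactly, which downstream
area-weighted means rely on.

Signed mean curvature `H` uses the cotangent mean-curvature normal
normalised by the mixed area, with sign from the projection onto the
outward vertex normal: positive on gyral crowns, negative in sulcal pits;
a positively-oriented sphere of radius `r` gives `H = +1/r` (within
0.001% at icosphere subdivision 4). The estimator was chosen as the
standard convergent discretisation and is validated in the test suite
against an independent quadric-fitting oracle (2-ring least-squares Monge
patch) on spheres and ellipsoids, agreeing in sign everywhere and within
5% in magnitude.

Field smoothing is iterative 1-ring averaging,
`x ← ½x + ½·mean(neighbours)`; zero iterations is the identity.

The half-sample mode (for aggregating ensembles of continuous
predictions) recursively keeps the shortest interval containing ⌈n/2⌉
sorted values; terminal rules: 1 value → itself, 2 → mean, 3 → midpoint of
the closer pair; interval-length ties break to the lower interval. Its
error decreases like n^(−1/3); at n = 10⁴ standard-normal samples the
mean absolute error is ≈ 0.1 SD, which is what the Monte-Carlo test
asserts.

## Voxelisation and morphology

`voxelize` marks every voxel whose centre lies inside the mesh by
ray-crossing parity along z, evaluated vectorised over all
(triangle, column) candidates. Two numerical safeguards matter:

- parity rays are offset from voxel centres by 0.0137 of a voxel, and
  vertices receive a deterministic ±1e-7-voxel jitter, so rays never pass
  exactly through vertices or edges — marching-cubes meshes otherwise
  have vertices *exactly on grid planes* and adjacent triangles would
  double-count shared-edge crossings;
- exact surface/centre-plane ties resolve consistently downward (an
  axis-aligned unit box voxelises to exactly its volume).

Closing with a spherical kernel (default diameter 15 mm) is computed via
two exact Euclidean distance transforms (dilation: distance-to-occupied ≤
r; erosion: distance-to-background > r), which is mathematically identical
to dilation+erosion with the discrete Euclidean ball but linear-time; the
test suite checks exact equality against the explicit-footprint scipy
oracle. Grids carry padding of at least kernel radius + 1 voxel;
insufficient padding is an error, never silent truncation.

## Hull, gyrification index, sulcal depth

The outer hull is the marching-cubes isosurface (level 0.5) of the closed
volume after Gaussian smoothing with σ = 0.8 voxel — smoothing suppresses
the voxel staircase that would otherwise inflate hull area by several
percent. Because a Gaussian level set retreats by ≈ σ²·H on curved
interfaces, hull vertices are pushed back out along their normals by
σ²·H (clamped to half a voxel); with this compensation a sphere's hull
area is within ~2.5% of analytic and re-hulling a hull changes its area
by < 0.5%. GI = cortical area / hull area, the universal orientation
(≥ 1 up to discretisation).

Sulcal depth voxelises the *given* hull mesh onto the brain's grid and
runs multi-source Dijkstra over the 26-connected graph of the region
inside the hull but outside the brain interior (the brain's one-voxel
surface shell is kept so every vertex is reachable). Seed voxels at the
hull boundary are initialised with their sub-voxel distance to the hull
surface, and vertex sampling adds the final segment from the voxel centre
to the vertex — without these two corrections the measured depth of a
4 mm phantom pit is biased low by ~1.5 voxels. Depth phantoms use a
steep-walled quartic pit profile (`exp(−(s/σ)⁴/2)`, σ = 0.8 mm): a 7.5 mm
ball cannot descend into a ~3 mm-wide well, so the analytic pit depth is
recovered within two voxels. On convex surfaces depth is ≤ 2 voxels
everywhere.

Regional measures are per-label sums of vertex areas and vertex-area-
weighted means of |H| and depth, so they are tessellation-independent and
the area-weighted regional means reconstruct the global means exactly.

## Sulcal pattern analysis

Basins are catchments of the smoothed curvature map (default 10
iterations) over the sulcal set {H < 0}, flooded in ascending order with
union-find; a vertex touching several basins is a ridge, and two basins
merge when the ridge height above the shallower minimum is below
`merge_ridge` (default 0.02 mm⁻¹; 0 keeps every catchment, ∞ reduces to
connected components). Basin features are scale-free: area-weighted
centroid in a normalised frame (surface centroid at origin, unit RMS
vertex radius), mean depth / max surface depth, area / total area.

Matching embeds each basin graph in the k = min(5, n−1) smallest
non-trivial eigenvectors of its feature-weighted normalised Laplacian
(edge weights `exp(−‖Δf‖²/σ²)`, σ = 0.5). The eigen-basis is ambiguous up
to sign, order, and — for repeated eigenvalues — rotation inside each
degenerate eigenspace, so the subject embedding is aligned to the
template's by an orthogonal Procrustes rotation over a raw-feature
Hungarian pre-match; per-axis sign/order fixing alone demonstrably fails
on degenerate spectra. The assignment cost is Euclidean distance in
[aligned embedding ⊕ raw features], solved by the Hungarian algorithm;
pairs costlier than 1.0 stay unmatched.

Similarity per matched pair and feature is `exp(−d/τ)` with fixed scales
τ_pos = τ_depth = 0.2 and τ_area = 0.05 (normalised units; exposed in the
pipeline config). The corresponding-regions SI averages over pairs; the
inter-sulcal SI compares within-brain feature *differences* across brains
(translation-invariant by construction); the whole-pattern SI is the mean
of the two multiplied by 2·|matched| / (n_subject + n_template), so extra
or missing folds reduce it. "Combined" uses equal feature weights by
default. These concrete formulas are this package's definitions — their
behaviour is pinned by the property suite (SI ∈ [0,1], SI(A,A)=1,
symmetry, monotone decrease under growing perturbation), not by any
external reference values.

## PAD statistics

For each measure X the model is `PAD = β0 + β1·GW + β2·X`, ordinary least
squares, two-sided t-test on β2 with n−3 df. Predictors are z-scored by
default so β2 is comparable across measures with incommensurable units;
raw-scale fitting is a flag. The sex-moderation test adds sex (F = 1) and
X·sex to the design and tests the interaction coefficient; unknown-sex
subjects are retained in main models and dropped only here. BH-FDR at
q = 0.05 is applied within each measure family. Rank-deficient designs
raise an error naming the offending column.

## Synthetic cohort generator

The generator is the package's test substrate: it reproduces the
*statistical structure* of a fetal cohort, not anatomy.

- **Growth**: radius r(GA) = 2.0 + 0.7·GA mm (≈16 mm at 20 GW to ≈29 mm
  at 38 GW, hemispheric scale); fold RMS amplitude a(GA) = 0.25·(GA − 22)
  mm past a 22 GW onset. Volume, area, GI and depth all increase with GA.
- **Folding**: an icosphere (subdivision 4, 2562 vertices) displaced
  radially by a random spherical-harmonic field. The spectrum is a
  log-normal envelope over degree wavelength 2πr/ℓ centred at 14 mm
  (bandwidth 0.25 in log-wavelength, degrees 4–30): sulcal spacing in
  real fetal cortex is approximately size-invariant in millimetres —
  new folds appear as the brain grows — and the continuous envelope keeps
  GI smooth in, and essentially independent of, brain size at fixed GA.
  Purely radial displacement is embedded whenever the radius stays
  positive, which is checked with a safety margin; exceeding it is an
  error. Discrete Gaussian/quartic pits provide exact-depth and
  watershed phantoms.
- **Cohort**: n = 115, GA ~ N(29.4, 4.4²) truncated to [19.9, 38.7] GW,
  sex ratio 57:42:16 (M:F:unknown). Per-subject geometry varies through a
  1.5 mm radius jitter; fold amplitude is treated as fully age-determined
  by default (`amp_jitter = 0`, a parameter). This choice reflects the
  tight developmental regulation of sulcation stage at fixed GA in
  typically developing fetuses, and it is what makes the default study
  condition exact: amplitude jitter feeds surface area (a signal carrier)
  and GI simultaneously, which would place folding-borne signal in PAD.
- **PAD model**: PAD = Σ_m γ_m·z̃(X_m) + γ_int·z̃(X)·male + ε with
  σ_ε = 0.6 wk and default γ_volume = γ_area = 0.6, where z̃ is the
  *cubic-in-GA-detrended* z-score of the measured column. Detrending
  matters: volume is exactly cubic in r(GA), so injecting raw z(X) would
  put the shared smooth GA trend into PAD and a linear GW adjustment
  would flag every age-trended measure. With these defaults the total PAD
  SD is ≈ 1.3 wk, matching the residual scale a well-fitting brain-age
  model leaves on a cohort with a 4.4-wk age SD.
- The 29 GW template and controlled perturbations of its harmonic
  coefficients provide a deviation dial for the similarity analysis;
  subjects outside the 23–32 GW template band can be excluded with
  `pattern_age_filter`.

Everything is a pure function of (spec, model, seed).

**What passing tests do and do not show.** The generator has genus-0
single-hemisphere surfaces, band-limited isotropic folding, no named
sulci, no measurement noise beyond discretisation, and linear generating
models. Results on it validate the *implementation* (geometry, morphology,
matching, inference calibration) — they do not certify effect sizes or
significance patterns on real fetal MRI cohorts, whose measures carry
segmentation error, anatomical asymmetry and nonlinear couplings the
generator deliberately omits.

## Problem sizes and runtime

Defaults were chosen so the full test suite runs in minutes on one CPU:
measurement voxel spacing 1.5 mm for cohort-scale simulation (0.75 mm —
the typical super-resolution reconstruction spacing of fetal MRI — is the
single-surface default and a parameter everywhere), icosphere
subdivision 4, statistical calibrations at 1000
table-level replicates, end-to-end checks over 20 mesh-level cohorts of
n = 115. The acceptance script reports the sizes it used alongside each
value.

## Known limitations

- The hull is the closing-derived wrap, not the true convex hull; at
  coarse voxels the closing dimples slightly (~1 voxel) over narrow pits,
  which the depth tolerances absorb.
- `merge_ridge` is in curvature units (mm⁻¹) and is therefore not
  scale-free; only the unmerged watershed commutes with uniform scaling.
- Spectral matching assumes mostly-overlapping basin sets; with fewer
  than two basins on either side it degrades to nearest-feature matching
  (with a warning).
- The τ similarity scales and the assignment cost cutoff are conventions;
  SI values are comparable only across runs with identical constants.
- One hemisphere per synthetic subject; bilateral cohorts are two
  independent draws.
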