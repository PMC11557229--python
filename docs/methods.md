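# Methods

This note records the models, conventions and numerical choices behind
fibromorph, and what the phantom-driven validation does and does not show.

## Signed distance transform and filtration

The SEDT is defined centre-to-centre: each voxel's value is the exact
Euclidean distance (voxel units) from its centre to the nearest voxel centre
of the opposite phase, negative for the phase under analysis.  Two
conventions deserve note:

* **Sign.** The analysed ("foreground") phase is negative, so the sublevel
  filtration grows from deep inside that phase outward and inscribed-sphere
  births are negative.  Conventions that instead sign the pore positive
  appear in the literature; only the sign of births/deaths flips.
* **Centre-to-centre vs interface.** Some tools measure distance to a
  half-voxel interface rather than to the opposite voxel centre.  The two
  differ by up to 0.5 voxel; reported radii inherit the centre-to-centre
  definition.  The minimum magnitude on either side of an interface is 1.

`scipy.ndimage.distance_transform_edt` supplies the exact (lower-envelope)
transform; a vectorised all-pairs oracle (`brute_force_sedt`) checks it to
1e-9 on random volumes.  Voxels must be isotropic; anisotropic inputs are
rejected rather than silently rescaled.

Voxel subdivision (`subdivide_and_sedt`) replicates each voxel into a
`factor**3` block before the transform and divides values by `factor`.  It
refines the radius quantisation — important for fibres a few voxels thick —
at the cost of `factor**3` memory.  Default factor 2; the sensitivity gain
beyond 2 is marginal for radius-3-voxel fibres.

## Cubical persistence

The complex is the V-construction (voxels = vertices; edges, squares and
cubes between axis-adjacent voxels; cell value = max of its vertices), with
the total order (value, dimension, lexicographic cell coordinate on the
doubled lattice).  The order makes birth locations deterministic run to run.

Dimension 0 is paired by union-find with the elder rule; dimension 1 by
GF(2) boundary-matrix reduction (columns as big-integer bitmasks) with the
clearing optimisation, which cannot change the pairing.  Dimension 2 is
outside the analysis path.  `brute_force_persistence` reduces the boundary
matrix of the *entire* complex (dimensions 0–3, same order) with none of the
shortcuts and is the equivalence oracle in tests; it is guarded to 1000
voxels.

Raw diagrams keep zero-persistence pairs (death = birth), which arise
whenever cells share values (integer-valued SEDT fields produce many).
`simplify(threshold)` removes finite points with persistence ≤ threshold, so
threshold 0 strips exactly the diagonal.  Defaults: 0.5 voxel units for pore
analysis (robust to small changes), 0 for fibre analysis (keep every
measurement of the fine structure).  The essential dimension-0 point (one
per connected grid box) is kept as a sphere — it is the deepest pocket — and
can be excluded by flag.

## Morphometry

Sphere radius = |birth| × voxel size (µm); layer = wall layer of the birth
voxel (points on a boundary go to the lower layer; on subdivided grids the
birth voxel is mapped back to the original lattice).  Per-layer
distributions use a Gaussian KDE with Scott's bandwidth on a 512-point grid
over [0, 1.1 × max radius]; layers with fewer than two spheres are reported
with a warning, and all-equal radii collapse to a point mass.  The reported
"second moment" is the second *central* moment in µm²; layer spreads for
cocoon walls quoted in the literature use ambiguous units, so no numerical
comparison is attempted.  Fibre cross-sections are not circular: inscribed
spheres measure the smallest thickness across the cross-section, which is
why fibre-thickness peaks sit below micrograph diameter ranges.

## Cleanup filters

Thinning artefacts are minimised before fibre analysis by (1) filling pore
cavities enclosed inside fibres — pore components, 6-connected, that do not
reach any volume face; the pore space of a real wall percolates, so enclosed
components are segmentation noise — and (2) removing 26-connected fibre
clusters of ≤ 100 voxels ("more than 100 voxels" is a strict threshold).
The 6/26 connectivity pair for pore/fibre is the standard complementary
choice that avoids digital-topology paradoxes.  Both filters are idempotent
and one-sided.

## Skeleton

Lee-style 3D thinning (`skimage.morphology.skeletonize`) is raster-order
dependent, so the medial axis is computed for the volume and its three 90°
rotations about z (the only axis that preserves the layered structure), the
back-rotated results are unioned, and the union is thinned once more.  The
union stage is exactly rot90-equivariant by construction; the final thinning
pass is not guaranteed bit-equivariant.  One degenerate case is handled
explicitly: thinning a perfectly even-symmetric structure (no unique centre
plane, e.g. a tube centred between lattice planes) can annihilate it
entirely; if the final pass empties a non-empty union, the union itself
(≤ 2 voxels wide) is returned and junction pruning removes the redundancy.

Graph conversion adds an edge for every 26-neighbour pair.  At junctions
(degree > 2) the incident edge whose best angle with any other incident edge
is smallest — the edge least alignable into a straight through-path — is
removed, one at a time, with lexicographic tie-breaks; "remove the edge with
the smaller incidence angle" admits several readings, and this
operationalisation keeps the most collinear through-pair.  Laplacian
smoothing moves each degree-2 vertex to (1 − λ)·p + λ·mean(neighbours) for
10 rounds with λ = 0.5; endpoints are anchored so open fibres do not shrink
(λ and boundary handling are free choices of this implementation).  Components with fewer
than 20 edges are removed, then 10 more rounds of smoothing.

## Orientation and the discretization band

θ is folded to [0°, 90°] and φ taken mod 180° because edges are undirected;
exactly vertical edges have undefined φ and are excluded from azimuth
statistics only (near-vertical edges, which arise at stacked-fibre contacts,
are kept).  Histograms use 1° bins, equal weight per edge, normalized to
mean density 1; a 5-bin circular moving average is applied before any
verdict.  Azimuths are collated inside the largest XY-inscribed circle.

Even a perfectly uniform fibre network yields a fluctuating azimuth curve
after rasterisation, thinning and smoothing — most visibly an excess at
exactly 0° and 90°, where near-axis-aligned polylines snap to the lattice.
The discretization band is the global min/max of the smoothed curve obtained
by running the identical pipeline on a uniform-azimuth phantom of the same
geometry; a distribution "deviates" only where its smoothed curve exits the
band.  A planted wrapped-normal azimuth peak (centre 30°, spread 20°, 30
lines per layer) is detected in ≥ 95% of seeds, with the offending region
intersecting the peak's inner half-width.

A note on window shape: for an edge-weighted histogram, the total clipped
fibre length per azimuth of a uniform line process is proportional to the
window area for *any* window shape, so square windows do not bias this
statistic toward 45°/135°; that bias affects fibre-count statistics, whose
per-angle counts scale with the window's projection width (|cos φ| + |sin φ|
for a square, constant for a circle).  The circular window is retained as
the conservative choice and because the band is calibrated with it.

## Phantoms

Phantoms define the study conditions and export their ground truth (line
endpoints and angles; sphere centres and radii) for recovery scoring.

* **Fibre phantom.**  Straight chords inflated to tubes of radius 3 voxels
  (a typical silk-fibre half-width at 2 µm voxels), drawn through a
  uniformly sampled interior point with azimuth from the configured law and
  clipped to the window.  Chord-through-a-point sampling is azimuth-exact
  and window-spanning; endpoint-on-face sampling was rejected because it
  couples direction to offset and measurably biases the azimuth density.
  Lines are laid in thin laminar sub-mats (default five 8-voxel slabs of 12
  lines in a 96 × 96 × 40 grid, solid fraction ≈ 0.32): a spun filament
  stays at nearly constant height and crossing fibres touch rather than
  interpenetrate, and thick generation slabs — which let tubes merge at
  arbitrary depth — produce a z-meandering skeleton unlike real mats.  The
  line count per layer is a free parameter of the material, not fixed by
  any published value.
* **Pore phantom.**  A solid block with spherical cavities (voxel centre
  strictly inside), either explicit or by a per-layer radius rule with
  uniformly placed centres; integer radii at integer centres are recovered
  exactly by the SEDT.
* **Primitives.**  Ball, cylinder, solid torus and dumbbell with known
  homology, used as oracle fixtures.

What passing phantom tests does *not* show: phantoms have straight fibres,
perfect binarisation and no greyscale noise, partial-volume effects, sericin
matrix or curved trajectories.  Recovery accuracies quoted here are
therefore upper bounds on what identically configured analyses achieve on
real scans.  Real volumes must be pre-aligned (inner wall parallel to the
XY plane at z = 0) before analysis; curvature correction and subdivision of
large scans into flat patches are upstream of this package.

## Problem sizes and determinism

Validation uses grids between 6³ (oracle equivalence) and 128 × 128 × 24
(orientation power), chosen so the full suite and the acceptance script each
complete in minutes on one CPU while keeping every phantom in the regime the
defaults describe.  All randomness flows through a single seeded generator
per phantom; identical spec + seed reproduces volumes, ground truth, bands
and manifests bit for bit (manifests differ only in their timestamp).
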