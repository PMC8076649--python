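# Methods

## The corridor model

A surgical access corridor is modeled as a cone with an irregular base.
The apex is the surgical target structure (the point the instrument's
distal tip rests on); the base is the ordered ring of extrema points — the
maximal positions of the instrument's proximal end around the corridor
perimeter, captured with a navigation probe.  The model assumes the
corridor narrows monotonically from the entry to the target, which holds
for transcranial approaches converging on a deep target but not for
approaches that open a large deep cavity; comparisons are only meaningful
between corridors that share this apex assumption.

Coordinates are millimeters in an arbitrary fixed Cartesian frame (e.g.
neuronavigation stereotactic coordinates).  No anatomical axis convention
is imposed: every derived scalar is invariant under rigid motions of the
frame, and meshes are emitted in the input frame.

## Pipeline

For one measurement (apex + `n ≥ 3` ordered extrema, 8 by default):

1. **Average plane** — for every non-collinear 3-point subset, the plane
   through the triple is computed from the cross product of two edge
   vectors.  Triple planes are unit-normalized (the raw cross-product
   magnitude scales with triangle size and would weight triples
   arbitrarily) and orientation-aligned before averaging (normals are
   sign-ambiguous; each is flipped to point from the apex toward the
   extrema centroid, or to agree with the first triple when no apex is
   supplied).  The averaged coefficients, renormalized, seed the fit.
2. **Total-least-squares plane** — the plane minimizing the sum of squared
   perpendicular distances.  The optimizer works on a 3-parameter chart
   (spherical angles of the unit normal plus the offset) in a rotated frame
   that places the initial normal at the chart's equator, with an analytic
   Jacobian and a polish restart; the result is accepted only if its
   objective matches the closed-form solution (centroid plus smallest
   principal direction of the centered scatter) within 1e−9 relative,
   otherwise a `ConvergenceError` is raised.  The closed form is also
   exported directly (`fit_plane_tls`) and serves as the independent
   cross-check in the tests.
3. **Height normalization** — the base plane is translated parallel to
   itself so its perpendicular distance from the apex equals
   `h_norm` (default 10 mm), staying on the same side of the apex as the
   measured points.
4. **Apex-ray translation** — each extremum is moved onto the target plane
   along the ray from the apex through it
   (`s = −(n·apex + D)/(n·(P − apex))`, `P′ = apex + s(P − apex)`).
   Central projection preserves the cross-sectional profile, which is what
   makes the normalized volume probe-length independent.
5. **Planar chart and area** — the translated ring is charted on the plane
   using the centroid as origin and two orthonormalized in-plane axes
   built from the first two points (`v = P₁′ − O`, `w = u × v`,
   `u′ = v × w`).  The chart is an isometry, so the enclosed area is
   basis-independent.  The area is the absolute shoelace sum, correct for
   any simple polygon; vertex order is trusted (the collection protocol is
   sequential around the perimeter), with an optional strict mode that
   rejects self-intersecting rings.
6. **Volume** — `V = A·h/3`, reported both at the measured height
   (`raw_volume`) and at the normalized height (`normalized_vsf`).

Angles of attack are the full 3D apex angles between the directions to
protocol points 1 & 5 (craniocaudal) and 3 & 7 (mediolateral).  They are
computed from the raw extrema; apex-ray translation preserves them exactly.
For protocols where those indices do not exist the angles are reported as
NaN rather than silently substituting other pairs.

### Legacy surgical freedom

The historical metric — a fan of triangles over the raw 3D points with
areas from Heron's formula — is reproduced deliberately, biases included:
non-coplanar vertices tilt the triangles so the sum exceeds the
perpendicular cross-section, and on a non-convex outline a fan anchored
across the notch counts area outside the polygon twice.  Because the
historical triangle division was a per-study choice, the anchor vertex is
a parameter rather than a constant.  A warning is logged whenever the fan
is evaluated on points that are non-coplanar beyond tolerance.

## Synthetic measurements

The generator emulates the laboratory measurement regime: a fixed-length
probe of nominally 190 mm read with Gaussian error of SD 5 mm along the
probe axis.  These are the `SimulationConfig` defaults:

| parameter | default | meaning |
|---|---|---|
| `n_points` | 8 | extrema per measurement (protocol order) |
| `probe_length` | 190 mm | noise-free apex-to-extremum distance |
| `base_radius` | 45 mm | corridor aperture at the probe's proximal end |
| `noise_sd_along` | 5 mm | capture error along the apex ray |
| `noise_sd_transverse` | 0 mm | capture error perpendicular to the ray |
| `base_irregularity` | 0 | radial modulation amplitude, fraction of radius |
| `concavity` | off | pull one vertex inside the hull (notched base) |

The cone height follows from `sqrt(probe_length² − base_radius²)`
(≈ 184.6 mm at the defaults), so noise-free probe lengths are exactly the
nominal value.  The 45 mm aperture was chosen as a realistic transcranial
corridor half-width at that depth; no transverse error is applied by
default because only the along-probe component has a measured magnitude,
and the parameter is exposed rather than guessed.

Base irregularity is a low-order Fourier modulation (harmonics 2 and 3) of
the ring radii, scaled to stay within ±the requested fraction.  Because
vertices keep their angular order, the base is star-shaped and hence always
a simple polygon; arbitrary vertex jitter could self-intersect and silently
violate the protocol-order assumption.  The concave variant sets one
random vertex to 30 % of its neighbors' mean radius, producing a reflex
vertex while remaining simple.

Every generator call draws from a fresh `numpy` generator seeded from the
configuration (or an explicit per-call seed); no global random state is
used, and identical configurations are bit-identical.

What the generator does **not** emulate: correlated rater bias, tissue
deformation or retraction, pathology mass effect, and anatomically shaped
(as opposed to smoothly irregular) corridor outlines.  Passing tests on
synthetic data therefore validate the geometry and the error-propagation
claims, not anatomical fidelity.

### Probe-length experiment

`probe_length_experiment` re-cuts a measured cone at a plane `delta_h`
farther from the apex — the same corridor as measured by a longer probe.
For exact conical data the volume ratio follows the similar-cone cube law
`(1 + delta_h/h)³`; at the reference height of 183.6 mm a 5 mm error
(+2.7 % height) inflates the volume by 8.4 %, which is the quantitative
argument for height normalization.

## 3D corridor meshes

The visual model smooths the base boundary with a closed periodic cubic
spline through the translated extrema, parameterized by cumulative chord
length, computed in the 2D plane chart and mapped back to 3D so the ring
stays exactly on the base plane.  Sample parameters always include the
knots, so the extrema are mesh vertices.  The side surface fans from the
apex; an optional centroid fan caps the base, giving a watertight mesh
with `m + 2` vertices and `2m` faces for `m` ring samples (64 by default).
The spline is visualization only: the numeric VSF always uses straight
segments between extrema and is never computed from the mesh.  Export
formats are binary/ascii STL, OBJ (1-based indices), and ascii PLY.

## Numerical choices

- **Collinearity**: a triple is degenerate when its cross-product norm is
  ≤ 1e−9 × the product of the edge lengths (scale-aware).  A cloud is
  degenerate for fitting when its second singular value is ≤ 1e−9 × the
  first.
- **Coplanarity**: points are "on" a plane within 1e−6 mm.  Projection is
  float-exact to ~1e−12, so the margin flags real geometry errors without
  masking bugs.
- **Side conventions**: the normalized plane keeps the base plane's side
  of the apex; a plane through the apex raises `AmbiguousSideError`
  because the corridor then has no height.
- **Shoelace sign**: the absolute value is taken, so clockwise and
  counter-clockwise vertex orders give the same positive area.
- **Heron degeneracy**: side lengths violating the triangle inequality
  within 1e−9 × perimeter give area 0; beyond that they raise.
- **Aggregation**: sample standard deviation (n−1), the replicate
  convention; SD is 0 for singleton groups.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
generated at call time: 1,000 random clouds for the fit-equivalence check,
1,000 polygon comparisons against an independent area oracle, 200 noisy
replicates for the Heron-bias experiment, 500 for the variance-reduction
experiment, 1,000 probe-length draws for the distribution check, and
256-sample rings for mesh-volume accuracy.  The whole suite completes in
well under a minute on a single core.

## Known limitations

- The best-fit plane is unweighted and not robust to outliers; a grossly
  misplaced extremum will tilt the base plane.
- Vertex order is trusted from the protocol; no automatic re-ordering is
  attempted, since reordering would silently change the corridor shape.
- Angles of attack are full 3D apex angles; studies that project angles
  into a canonical anatomical plane before reporting will differ.
- The spline family used by CAD tools in prior visualizations is
  unspecified; rendered outlines may differ from other software even
  though all numeric results are spline-independent.
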