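# Methods

This note documents the models, conventions and numerical choices behind
`paramhip`, and what its tests do and do not demonstrate.

## Geometry model

The acetabular side of the hip is described by five free parameters — the
acetabular depth `d`, the anterior edge cut `(o1, r1)` and the cartilage
fossa `(o2, r2)` — on top of controlled quantities: cavity radius `R`,
uniform cartilage thickness `t = 2 mm`, radial clearance `c = 0.5 mm`, cup
inclination 63° and anteversion 15°. Generation is constructive: a
70 × 85 × 80 mm cuboid bone block; a spherical cavity cut of radius `R`; a
posterior rim plane cut; an anterior cylinder cut; cartilage extruded
radially inward by `t`; a fossa cylinder cut and an inferior notch cut of
the cartilage. The femoral side is a sphere: articular radius
`(R − t) − c`, bone radius one thickness smaller again.

### Coordinate frame and orientation conventions

Anatomical planes alone do not fix a numeric frame, so the package defines
one: origin at the cavity centre, `x` anterior, `y` superior, `z` lateral
for a right hip; coronal plane `x = 0`, sagittal plane `z = 0`. Left hips
are generated in this canonical frame and mirrored through the sagittal
plane, vertex for vertex, so left/right symmetry is exact by construction.

Cup orientation uses the radiographic (Murray) convention: anteversion is
the angle between the cup axis and the coronal plane, inclination the angle
between the superior axis and the axis's coronal projection. The axis (the
outward normal of the acetabular opening) is
`n = (sin AV, −cos AV · cos RI, cos AV · sin RI)`, pointing
anterior–inferior–lateral; the mapping is inverted exactly by
`angles_from_axis` for angles in (0°, 90°).

Further conventions the source description leaves open, fixed here once:

* `o1` is a (y, z) offset from the cavity centre in the coronal plane (the
  anterior cylinder runs along x); `o2` is an (x, y) offset in the sagittal
  plane (fossa cylinder along z). Material *outside* the anterior cylinder
  is removed; cartilage *inside* the fossa cylinder is removed.
* `d` is signed along the cup axis; positive depth means cavity coverage
  exceeds a hemisphere. The zero-depth cavity is exactly a hemisphere.
* The notch is a planar cut tangent to the fossa cylinder on its inferior
  side (`y = o2_y − r2`), joining the fossa opening to the inferior rim. It
  is configurable (`notch=False` skips it); all bundled activity runs show
  zero contact pressure on notch-adjacent vertices, consistent with
  treating its exact shape as mechanically irrelevant in this model.

### Meshing

Patches are triangulated directly in spherical coordinates (polar grids
about the cup axis with per-ring vertex counts proportional to sin θ), and
every cut is applied by a marching-triangle clipper on an analytic signed
field. Newly created boundary vertices are snapped exactly onto the
analytic cut curve (sphere–plane or sphere–cylinder intersection), so
labelled edge rings lie on their defining primitives to ~1e−12 mm. There is
no boolean CSG engine; this is why noiseless parameter round-trips are
machine-exact rather than mesh-tolerance-limited.

Cartilage is a radial extrusion of the articular patch; radial scaling maps
cylinder/plane cuts at radius `R` to scaled cuts at `R − t`, so the
articular surface is itself an exactly-cut cap. The shell (inner + outer
surface + radial walls) is watertight with consistent winding; its volume
matches the analytic spherical-shell value `Ω(R³ − (R−t)³)/3` to the area
discretisation error (<0.1% at default density). The cuboid block is
export-only cosmetics: the contact model treats bone as rigid backing.

Default density targets ~13,000 facets on the lunate articular surface
(n_rings = 58), mirroring the converged cartilage meshes of the modelling
practice this package follows; `rings_for_facets` maps a target facet count
to a ring count via one coarse probe build.

## Parameter fitting

* **Sphere**: algebraic linear initialiser, then Gauss–Newton on the
  geometric residual `|p − c| − R` (scipy `least_squares`, tolerances
  1e−12). Coplanar inputs raise a singular-configuration error.
* **Plane**: exact total least squares via SVD (smallest principal
  direction); the normal is oriented toward a caller-supplied hemisphere
  (extraction orients it away from the articular centroid, giving the cup
  axis).
* **Circle**: orthogonal projection onto the named anatomical plane
  (coronal for the anterior edge, sagittal for the fossa), Kåsa algebraic
  initialiser, geometric Gauss–Newton refinement.

`extract_parameters` composes these: cavity centre and radius from the
articular sphere fit (+ known thickness), depth and cup angles from the rim
plane, `(o1, r1)` and `(o2, r2)` from the edge circle fits, with per-fit RMS
residuals attached. Thickness and clearance are controlled inputs, not
measured. The fossa measurement is interpreted as a circle-on-plane fit of
the fossa edge ring (the fossa is generated by a cylinder cut, so its edge
projects to an exact circle in the sagittal plane).

### Identifiability limit of the anterior cut

For the bundled parameter values, the surviving anterior edge arc subtends
only ~40–70° (the rest of the cylinder curve is removed by the rim cut
under any convention that keeps the cavity pole and superior roof).
Unconstrained circle fitting on such a short arc amplifies noise roughly
30–100×: at 0.2 mm point noise the fitted `r1` is already ~1.4 mm off, and
with 1 mm correlated edge irregularity the fit can diverge entirely. Depth,
fossa circle (a full ring) and cavity radius recover to <0.1 mm under the
same conditions. This is an information limit of the measurement geometry,
not of the estimator; the acceptance suite exercises it at full synthetic
severity and reports the failure honestly, while unit tests cover the
well-conditioned parameters.

## Activity loading

Profiles are CSV tables of `(cycle_pct, fx, fy, fz)` in percent body
weight, scaled to newtons with g = 9.81 m/s² and the subject mass.
`to_model_frame` applies an orthonormal rotation (magnitude-preserving to
1e−9 N) and negates the lateral component for left hips. `discretise`
samples `n` equally spaced cycle fractions including both endpoints
(default 13) with linear interpolation per component; rotational loading is
excluded (the femoral centre is rotationally constrained).

The seven bundled profiles (walking, ascending/descending stairs, standing
up, sitting down, one-legged standing, knee bending) are synthetic
representative curves constructed for this package: smooth Gaussian-bump
magnitude shapes with peak resultants of 233 / 252 / 260 / 190 / 156 /
231 / 143 %BW respectively, taken from the instrumented-prosthesis
literature, directed into the acetabular roof (toward the lunate centroid)
with a small cyclic wobble. They emulate the magnitude envelope and smooth
directional variation of measured hip forces; they do **not** reproduce any
subject's measured waveform, inter-subject variability, or out-of-plane
moment content. Results on them demonstrate solver behaviour under
physiological load magnitudes, not subject-specific predictions; user CSVs
with the same schema are accepted for real datasets.

## Elastic-foundation contact model

The solver is a deliberate stand-in for a deformable-bone finite-element
contact solve — the package's largest modelling departure from FE practice.
Cartilage is a thin linear-elastic layer on rigid backing; both layers act
in series, so `t_total = 4 mm` and

    K = E(1−ν) / [(1+ν)(1−2ν) t_total] = 11.379 MPa/mm

for E = 12 MPa, ν = 0.45 (cortical/cancellous constants are stored for
provenance but unused — rigid backing). Contact is frictionless: pressure
`p = K·max(0, −gap)` acts along the local normal, with
`gap(v) = |v − u − head_centre| − r_fem` on lunate vertices. Per step the
three-component femoral translation `u` solves `F + ∮ p n dA = 0` by Newton
iteration with the analytic Jacobian, damped 0.5 on residual growth,
initialised at `u = (c + 0.05)·F̂` (or warm-started from the previous
step), converged when the force residual is ≤ max(0.1%·|F|, 1e−3 N) and
bounded at 100 iterations. If `|u|` exceeds the clearance plus the full
cartilage thickness, the load direction has no cartilage support and a
no-equilibrium (dislocation) error is raised with diagnostics.

Two independent analytic references validate the solver for centred loads:
the small-angle closed form `p0 = sqrt(F c K / (π R²))` (valid while the
patch is far from edges and the penetration is small against the clearance
— in practice F ≲ 100 N here, where agreement is ~4–5%), and the exact 1-D
foundation integral solved by bracketing (agreement ~1–5% at 100–2000 N,
the residual coming from pressure-direction tilt and patch/edge
interaction). Peak pressures scale as √K for centred loads, a closed-form
consequence the tests assert.

At 80 kg body weight the bundled activities give all-cycle peak pressures
of ~2.0–3.0 MPa and peak contact areas of ~1100–1420 mm² on both presets —
within the low-megapascal range expected for a spherical, uniform-thickness
cartilage model, and below the 3.5 MPa upper bound the package asserts.
Magnitudes from a rigid-backing foundation model are systematically
interpreted as lower bounds on FE values with deformable bone and
near-incompressible continuum cartilage.

### Contact area and its mesh bias

Contact area follows a threshold rule: facet areas are summed for facets
whose vertex pressures all exceed 0.1 MPa (the conservative "all-vertex"
default; an "any-vertex" variant is configurable). This estimator is
first-order in mesh edge length: facets straddling the threshold contour
are excluded, giving a systematic deficit of roughly (edge length ×
contour length) — about 6% of the patch area at 2,000 facets, 2% at
13,000, 1% at 107,000. Consequently, while peak *pressure* converges to
≤0.1% between the two finest density levels, thresholded *area*
differences remain at ~2% between 13k and 107k facets; a 1% area-refinement
bound is not attainable with this rule at these densities, and the
acceptance suite records that outcome honestly rather than switching
estimators. Percent-difference *comparisons* between two models at equal
density are largely insensitive to the bias, which cancels to first order.

## Comparison metrics

`percent_difference_series` reports `100·|test − ref|/ref` per step for
peak pressure and contact area (reference in the denominator; the metric is
deliberately asymmetric), the maximum and the cycle percentage at which it
occurs; steps with a zero reference are flagged undefined and excluded from
maxima. `convergence_study` runs one activity at several density levels and
tabulates successive differences of all-cycle peak pressure and area, with
a converged flag at the (3%, 1%) thresholds.

## Synthetic segmentation-like surfaces

`make_segmentation_like` perturbs the exact geometry with (i) smooth
periodic radial displacement of the fossa and anterior edge rings
(amplitude default 1 mm, wavelength default 10 mm, two incommensurate
harmonics, random phase) re-projected onto the articular sphere, and (ii)
isotropic Gaussian vertex noise (default SD 0.074 mm, the order of a
micro-CT voxel). All randomness flows from the single recorded seed. The
generator emulates edge irregularity and point noise of segmentation-based
surfaces; it does not emulate segmentation topology defects, smoothing
artefacts, non-spherical articular surfaces or cartilage thickness
variation — so recovery results bound performance under the modelled
perturbations only.

## Numerical choices

* Geometric predicates and edge labelling: 1e−9 mm; snapped cut vertices
  are exact to ~1e−12 mm.
* Fit refinement tolerances: 1e−12 (xtol/ftol/gtol); singular
  configurations detected at a 1e−9 relative singular-value threshold.
* Degenerate cuts: a cylinder that misses the mesh is a warned no-op; a cut
  that would remove everything raises a domain error; `r2 = 0` is an empty
  cut.
* Plane-normal sign tie-break: toward the caller-supplied hemisphere;
  extraction uses the anti-articular direction.
* Newton damping factor 0.5, up to 12 halvings per step; convergence on
  force residual, not displacement.
* Problem sizes in the shipped tests: default density (~13k lunate facets)
  for contact and round-trip checks, ~2k/13k/107k for the convergence
  study, 50 seeds × ~6k-point surfaces for the recovery experiment — sizes
  chosen to match the modelling practice the package mirrors while keeping
  the suite runnable in minutes.

## Known limitations

* Rigid bone backing and a rigid femoral sphere; no deformable-bone FE, no
  cortical/cancellous compliance (their constants are stored only).
* Homogeneous isotropic elastic cartilage of uniform thickness; no biphasic
  behaviour, so only instantaneous contact mechanics are meaningful.
* No labrum; no load sharing at the acetabular rim.
* Spherical articular surfaces only; the femur beyond a sphere is out of
  scope.
* The anterior-edge parameter pair is weakly identifiable from realistic
  noisy surfaces (short arc), as quantified above.
* The thresholded-area estimator carries a first-order mesh bias, as
  quantified above.
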