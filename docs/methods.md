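# Methods

`colomech` simulates how a diverticulum-like pouch changes the mechanical
stress carried by the colon wall. This note records the model, its
assumptions, the numerical choices, and what the package's synthetic
experiments can and cannot say about real tissue.

## Constitutive model

The colon wall is treated as a homogeneous, incompressible, anisotropic
hyperelastic material. The strain energy density is

    W = C10 (I1 - 3)
      + (k1l/k2l) [exp(k2l (I4l - 1)^2) - 1]
      + (k1s/k2s) [exp(k2s (I4s - 1)^2) - 1]

with `I1 = λz² + λθ² + 1/(λz² λθ²)` (incompressibility eliminates the
radial stretch), `I4l = λz²` for the longitudinal collagen family, and
`I4s = λθ² cos²γ + λz² sin²γ` for the two families inclined at ±γ from
the circumferential direction. The two symmetric families share one
energy term: their structure tensors average to
`diag(cos²γ, sin²γ)` in the (circumferential, longitudinal) frame, and
that generalized structure tensor is what the membrane solver contracts
with the full in-plane Cauchy–Green tensor, so the formulation stays
frame-indifferent under in-plane shear.

Five parameter sets for swine descending colon ship with the package
(`colomech/data/material_params.txt`); they span C10 from 411 to 1873 Pa
and fiber exponents k2 from ~1 to ~917. The exponents near 10² make the
fiber response a near-wall: a fraction of a percent of stretch changes
stress by tens of percent. Several numerical choices below exist solely
to cope with that stiffness. Fiber terms with `k1 = 0` evaluate to exactly
zero (limit convention), which enables the Neo-Hookean reduction tests.
Tension–compression switching of the fibers is available behind a flag but
OFF by default: the energy above has no switch.

Units: geometry in mm and pressures in kPa at the API boundary (the
tissue literature's units); the solver converts to SI internally and all
stresses are reported in Pa.

## Closed-form tube mechanics

A straight incompressible tube under luminal pressure P and prescribed
axial stretch λz has the thin-wall (Laplace, midsurface) solution

    P = σθ(λθ, λz) · T / (λθ² λz Rm),    T = Ro − Ri,  Rm = (Ri + Ro)/2,

with `σθ = λθ ∂W/∂λθ` the circumferential Cauchy stress under the
plane-stress condition σr = 0. A thick-wall variant integrates
`∫ σθ(r)/r dr` over the deformed wall with the incompressible map
`r(R) = sqrt(ri² + (R² − Ri²)/λz)` (adaptive quadrature, relative
tolerance 1e-10). Inversion of the pressure–stretch relation uses
bracketed Brent iteration on λθ ∈ [0.5, 3]; trial stretches that overflow
the fiber exponentials are treated as lying above the root, and the
bracket is shrunk to a finite edge before the root polish.

A caution discovered while testing: thin- and thick-wall pressures agree
to a few percent only while the through-wall stress gradient is mild.
With fiber exponents k2 ~ 10²–10³, the ~2.5% stretch difference across
this wall produces order-one (up to several-fold) stress differences, so
geometric thinness alone does not make the fidelities agree for the
stiffest parameter sets. What does hold, and is what the tests assert, is
convergence of thick to thin as the wall thickness shrinks, plus
few-percent agreement for the gently exponential sets across the study
range.

Agreement between the finite-element solver and the closed form is scored
with a deviation-based coefficient of determination,
`R² = 1 − Σ(m−a)² / Σ(ā−a)²`, evaluated per stress component over the
pressure sweep. This is not the squared Pearson coefficient: it penalizes
offsets, not just scatter.

## Geometry generation

The quarter model (symmetry planes x = 0 and z = 0) is a structured grid
in the (circumferential arc, axial) parameter plane mapped onto the
midsurface cylinder of radius Rm. A pouch is a sphere of diameter D whose
cap rises H above the midsurface (center on the +y axis at Rm + H − D/2);
the crease where cap meets cylinder is rounded with a rolling-ball fillet
of radius 2 mm realized on signed distance fields:

    F = max(r, min(a, b)) − hypot(max(r−a, 0), max(r−b, 0))

which is an exact circular fillet for planar creases and a good rolling-
ball approximation here. Grid nodes inside the pre-fillet neck footprint
are lifted onto the spherical cap by a polar map whose radial grading
keeps a near-unit metric at the apex, then every node near the pouch is
projected onto the implicit surface by damped Newton steps along the SDF
gradient; the packaged meshes sit on the surface to ~1e-5 mm. The grid is
refined by a factor 2 inside the pouch footprint.

Every mesh of a study shares one grid grading (the largest pouch's
footprint): faceting error of a polygonal cylinder depends on the local
element width, and matching the gradings makes that bias cancel in every
diseased-to-normal comparison.

Pouch descriptors are measured on the pre-fillet sphere–cylinder
intersection (the fillet being a smoothing device): Dz = 2√(H(D−H))
(exact: the cylinder is straight along z), Dx = straight-line x-extent of
the intersection curve, Ab = cylinder-surface area enclosed by the curve,
Sp = sphere-surface area outside the cylinder (both by quadrature to
~1e-9 relative). Note that neck measures are not monotone in H: the neck
is widest for a hemispherical cap (H = D/2) and narrows again for taller
caps, which matters for two of the nine study geometries.

Fiber frames are per element: longitudinal = unit projection of the
global z axis onto the element plane, circumferential = normal ×
longitudinal.

## Membrane finite elements

Flat 3-node constant-strain membrane triangles in a total-Lagrangian
setting. Per element, the 3×2 surface deformation gradient maps the
reference fiber frame to 3-space; `C = FᵀF` feeds the plane-stress
condensed 2nd Piola–Kirchhoff stress

    S = 2 C10 (I − C⁻¹/det C) + 2 ψl Hl + 2 ψs Hs,

whose through-thickness stress is identically zero with the thickness
stretch fixed to `1/√(det C)` by incompressibility. The in-plane Cauchy
stress reported per element is `F₂ S F₂ᵀ` in an orthonormal basis of the
deformed tangent plane (J = 1). Luminal pressure is a follower load along
the current element normal; its (unsymmetric) load stiffness is kept in
the Newton matrix. The analytic consistent tangent is verified against
finite differences of the residual in the test suite.

The membrane replaces a solid-element discretization on the strength of
the thin wall (diameter-to-thickness ratio near 20). What a membrane
cannot represent: bending boundary layers at the fillet, through-wall
stress gradients, and a stable unloaded pouch state (see below).

### Wrinkling and stabilization

A compressed membrane wrinkles; the discrete operator loses rank along
those modes. A small compression floor — quadratic energy with modulus
1e-3·C10 on the Green strain, i.e. a floor stress of order 1 Pa against
reported stresses of 10⁴–10⁵ Pa — keeps the static problem solvable in
mildly compressed zones. For the stiffest circumferential-fiber sets the
10% axial prestretch forces ~13% radial contraction and the pouch cap
wrinkles over a broad region; there the study escalates the floor
through (1e-3, 3e-3, 1e-2)·C10 and uses the smallest value that
converges, recording it per case. Peak stresses live in strongly
tensioned neck material and are insensitive to the floor.

At exactly P = 0 the pouch membrane is degenerate: the wrinkling modes
carry no stiffness at all, and downward pressure continuation converges
to 0.5 Pa but not to zero. The unloaded level is therefore recorded only
for the normal cylinder (where it is a well-posed homogeneous state) and
explicitly listed as skipped for pouch models; all derived quantities use
P ≥ 0.25 kPa.

### Load stepping

Loading order in the physical protocol is prestretch first, then
pressure. Hyperelastic statics is path-independent, so the solver is free
to choose a stabler continuation with identical recorded states: the
prestretch is ramped jointly with the first 0.25 kPa increment (keeping
the cap tensioned), the grid is then marched upward in the stated
0.25 kPa steps with a secant predictor, and the pressure-free record is
attempted by downward continuation. Each increment is solved by damped
Newton with backtracking line search to a relative residual of 1e-8, with
a Levenberg-style diagonal regularization engaged when the line search
collapses (indefinite tangents near wrinkling), and increment bisection
on failure. Trial states beyond a stretch of 4 are rejected outright —
the fiber exponentials make them meaningless. Everything is
deterministic; reruns are bit-identical.

A rigid-body zero mode remains in the quarter model (translation along
y; the net follower force along y vanishes identically on this
geometry). It is removed by pinning one far-end node's y component; the
pin is consistent with a translated equilibrium, carries no reaction, and
only selects the rigid representative.

### Mesh convergence

Following the study protocol, the element size is halved from 1.3 mm
until the peak max-principal stress at the final load level changes by
less than 10% between successive meshes; the chosen size is the coarser
member of the converged pair. For the homogeneous cylinder the membrane
is already converged at 1.3 mm (faceting error ~5e-4), so the rule stops
immediately — the situation differs from a solid model, where through-
wall resolution drives the refinement.

## Derived metrics

* **Peak stress curves.** σ_MPS is the largest principal value of the
  plane-stress state including the zero through-thickness value (relevant
  only if both in-plane principals are negative). Per model the peak over
  element centroids is averaged over the five parameter sets and
  normalized by the normal model at the same pressure.
* **Pressure factor.** For reference pressures Pn ∈ {2,3,4,5} kPa, the
  diseased pressure is decremented in 0.25 kPa grid steps until the
  diseased peak no longer exceeds the normal peak at Pn;
  f = (Pn − Pd)/Pn × 100. Ties resolve toward the larger Pd.
* **Zone of influence.** Stress profiles along the lumen paths through
  the pouch center (the structured grid's first cell column/row), with
  reference arc-length distances from the pouch center and the normal
  model's profile interpolated position-wise as reference. The zone
  distance is the farthest point where the profile is still *elevated*
  more than 10% above normal, located by linear interpolation between
  samples. The elevation-only (one-sided) criterion is the study default:
  under displacement-controlled prestretch the meridian strip through the
  pouch is effectively lengthened and carries a persistent axial-tension
  deficit of order 10% (a 0.3% stretch deficit amplified by the fiber
  exponential), so a two-sided band never closes along the longitudinal
  path of a membrane; a two-sided flag is available.
* **Correlations.** Squared Pearson correlation of the per-model response
  against each pouch descriptor across the nine models, with the exact
  two-tailed t-transform p-value (7 degrees of freedom); stress
  correlations are averaged over pressures 1–5 kPa on the 0.25 kPa grid,
  zone-of-influence correlations use the 5 kPa plateau. No
  multiple-testing correction is applied.

## Resolution profiles and problem sizes

The `coarse` profile (default) uses a 1.6 mm far-field element size
refined to 0.8 mm around the pouch — about 2.5k triangles and 7.5k
degrees of freedom per quarter model — chosen so the full 50-case study
with all metrics completes in minutes on one CPU. The `paper-like`
profile (0.65 mm far field) exists for higher-fidelity runs. Validation
and acceptance quantities are computed on the coarse profile; the
convergence study demonstrates that the homogeneous-cylinder quantities
are mesh-insensitive well below these sizes.

## What the synthetic experiments do and do not show

The geometry factory generates every input the study needs; there is no
external data. Passing tests therefore demonstrate: correctness of the
constitutive mathematics against symbolic and finite-difference oracles;
correctness of the membrane solver against the closed-form tube; and
reproduction of the study-level patterns (neck stress concentration,
elevation growing with pouch size, pressure factors, zones of influence
and their geometry correlations) on an idealized, single-pouch, straight,
residual-stress-free colon segment with pouch tissue identical to the
wall. They do not validate the model against diseased human tissue, they
inherit the membrane simplification at the fillet, and absolute stress
values carry the coarse-profile discretization error; the comparative,
correlation-level conclusions are the robust outputs.

## Where the membrane departs from a solid-wall model

Two systematic membrane-specific behaviors, both verified to be mesh
converged, shape the study outputs and should be kept in mind when
comparing against solid-element results:

1. **Neck-crease concentration of the prestretch tension.** Under
   displacement-controlled axial stretch, the meridional tension must
   cross the crease where cap meets cylinder. A membrane has no bending
   stiffness to spread that redirection, so the concentration grows as
   the crease sharpens — i.e. as the sphere diameter *shrinks* at fixed
   height, the tall-narrow "mushroom" pouches being the extreme. Peak
   stress in this model therefore increases with pouch height but
   *decreases* with sphere diameter, and correlates best with the pouch
   surface area Sp rather than with the neck widths; a solid wall, whose
   bending regularizes the crease and whose pressure-driven neck loads
   grow with diameter, can show the opposite diameter trend. The
   correlation tables should be read with this in mind.
2. **Weak path elevation for shallow pouches.** The lumen-side stress
   rings a solid model develops around a shallow pouch live in a bending
   boundary layer (decay length ~ sqrt(R t) ≈ 4 mm) that a membrane does
   not possess; the zone-of-influence distances of the flattest (H = 2 mm)
   pouches are accordingly small (~2–5 mm) while the taller pouches reach
   9–16 mm.

## Known limitations

* No bending stiffness: fillet boundary layers and the unloaded pouch
  state are outside the model class.
* Wrinkled zones are stabilized, not resolved; local stresses inside
  broadly wrinkled caps (stiffest parameter sets at low pressure) are
  regularization-dependent, while neck peaks are not.
* Single pouch, straight tube, uniform thickness, no residual stress, no
  viscoelasticity or damage; pouch material identical to the wall.
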