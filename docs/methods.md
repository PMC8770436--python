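# Methods

## Model

The probe–tissue interface is modelled as static, small-strain, isotropic
linear elasticity. Units are self-consistent: lengths in µm, moduli in MPa,
so stresses come out in MPa and strains dimensionless. Coordinates: origin
at the centre of the tissue top surface, +y downward along the probe axis,
+x the tangential loading direction (across the probe width), +z the probe
thickness direction.

Geometry: a rectangular shank of 1125 × 125 × t µm (t = 25 µm for silicon,
polyimide and the thin compliant variant; t = 63 µm for the thick compliant
variant, the manufacturing limit for the PVAc-NC composite) fully embedded
in a 1500 × 1500 µm (lateral) × 1500 µm (deep) block of cortical grey
matter, its top face flush with the tissue surface. The tissue depth and
embedment are not uniquely determined by the published record and are
configurable (`DomainSpec`); the default leaves 375 µm of tissue below the
tip. The probe tip is square-cut: tapered tips are out of scope, which
matters for absolute corner maxima (see Limitations).

Assumptions inherited from the modelling tradition for this problem:
grey matter treated as isotropic linear elastic (the error of a linear
versus hyperelastic description is small at these strain magnitudes near
the probe, and the comparisons are ratios in any case); perfect bonded
contact (realised exactly by a conforming shared-node mesh, so no contact
algorithm is involved); statics (micromotion frequencies are far below any
structural resonance of a 1 mm shank).

## Materials

| name | E (MPa) | ν | role |
|---|---|---|---|
| silicon | 2·10⁵ | 0.278 | stiff probe |
| polyimide | 2.7·10³ | 0.33 | polymer probe |
| pvac_nc | 12.7 | 0.30 | compliant probe (post-insertion) |
| pvac_nc_pre | 5.2·10³ | 0.38 | catalogued only, never simulated |
| hypothetical | = brain E | 0.33 | modulus-matched probe |
| brain | 6·10⁻³ (default) | 0.45 | tissue |

**Tissue modulus.** The published record for this study states the brain
modulus inconsistently — 6·10⁻³ MPa in its case table and one figure
caption, 6,000 kPa (= 6 MPa) twice in its text. The package defaults to
**6 kPa**, for two reasons. First, it is the standard grey-matter value in
the micromotion-FEM literature this study builds on. Second, the physics
discriminates sharply between the readings: a laterally driven shank in an
elastic foundation has a decay length λ = (4EI/k)^¼. At E_brain = 6 kPa,
λ ≈ 4.8 mm ≫ 1.125 mm for silicon — the shank translates rigidly and the
strain maximum lands at the tip, with the 63 µm compliant probe's tip
response suppressed to ~10% of the stiff baseline — exactly the reported
behaviour. At E_brain = 6 MPa, λ ≈ 0.86 mm < L for silicon: every probe's
tip stays put, every maximum lands at the top, and the compliant/stiff
ratios exceed 100%, contradicting all of the reported locations and ratios.
Both readings run via the `brain_E` override; only the default is defended.

## Boundary conditions

The four perimeter edges of the tissue bottom face are fixed in all
components (the restraint that prevents large-scale translation of the
block while leaving the field near the implant local). The micromotion load
is a prescribed displacement of the probe top face: **u** = (d, 0, 0) on
every node of the 125 × t µm patch.

Prescribing the full vector — not just u_x — is deliberate. The tethering
scenario is a probe whose platform is grounded in the cranium; the skull
moves tangentially by d and carries the probe mount with it, rotation
included. If only u_x is prescribed, a probe that is rigid relative to
6 kPa tissue is free to rock about a pivot near its tip (rigid-body
rotation costs almost no tissue energy, and u_x on the y = 0 plane does not
constrain rotations about z), the tip never displaces, and the tip strain
field vanishes — verified here with direct-solver cross-checks: the rocking
solution has probe-interior Von Mises ~10⁻⁹. The welded reading
(`clamp_top=True`, default) restores the documented mechanics; the
x-only reading remains available as `clamp_top=False`.

Displacements outside 0–60 µm trigger a warning (beyond the physiological
micromotion range).

## Discretisation and solvers

Eight-node trilinear hexahedra on a graded tensor-product grid. The grid
conforms exactly to the six probe faces, so probe/tissue element tagging
and bonded contact are unambiguous; meshing is deterministic (identical
parameters give bit-identical meshes). Grading: edges start at `near_size`
at the interfaces and grow geometrically (`grading`, capped at `far_size`);
the probe thickness is always crossed by `n_through_thickness ≥ 3`
elements. Defaults (7 µm near size, ratio 1.4, 130 µm cap, 4 through the
thickness) give ~48k elements for the thin probe — the scale used by the
reproduction script; tests use coarser grids (~4k–25k).

Near-incompressibility (ν = 0.45) locks plain trilinear elements, so the
stiffness uses the mean-dilatation B-bar construction: full 2×2×2 Gauss
quadrature with the dilatational part of B replaced by its element average.
The element passes the constant-strain patch test on deliberately distorted
meshes to 10⁻¹⁰ and annihilates all six rigid-body modes.

Solvers: sparse LU for systems up to ~60k free dofs (deterministic,
bit-reproducible reruns); above that, conjugate gradients preconditioned by
a zero-fill incomplete Cholesky factor built with numba kernels, applied to
the Jacobi-scaled operator. The symmetric diagonal scaling is what makes
the preconditioner survive the 3·10⁷ modulus contrast between silicon and
tissue; IC(0) breakdown, if it occurs, is retried with a growing diagonal
shift. Convergence is declared on the true relative residual of the reduced
system (default 10⁻⁸, checked after the solve and enforced at 10⁻⁹ inside
CG). Displacement-controlled linearity is exact, so solutions at other
magnitudes of the same load pattern are obtained by rescaling
(`results.rescaled(d)`), equivalent to a second right-hand-side solve.

## Reported quantities

* **Von Mises (equivalent) strain** per element at the centroid:
  ε_eq = 1/(1+ν′)·√(½ Σ(εᵢ−εⱼ)²) over principal strains, evaluated through
  the identity ε_eq = √(3/2)·‖dev ε‖/(1+ν′). ν′ defaults to the element
  material's ratio (0.45 in tissue), configurable (`nu_eff`), since solver
  conventions for ν′ differ and absolute magnitudes depend on it.
* **Maximum tissue strain**: maximum over tissue-tagged elements only
  (probe interior excluded), reported with the argmax element centroid.
  Centroid values, never nodal-averaged or nodal-extrapolated — maxima are
  then smoothing-independent, but systematically lower than extrapolated
  nodal maxima near corners.
* **Location class**: thirds of the embedded length by axial coordinate —
  top (y ≤ L/3), mid, tip (y ≥ 2L/3). The rule is a deliberate
  operationalisation of qualitative "tip/top" language; coordinates are
  always reported alongside.
* **Decay profiles**: at a section height (tip y = L, mid y = L/2, top
  y = 0), tissue elements intersecting the section plane and lying within
  the probe width are grouped by centroid distance from the probe thickness
  face along z; the profile is the per-distance maximum. Mid/top sections
  start 62.5 µm from the probe axis. `decay_span` reports where the profile
  first falls below a fraction (default 1%) of its probe-adjacent value.
* **Normalisations**: compliant maxima as fractions of the stiff baseline,
  and percent reductions, both requiring a positive baseline.

## Mesh sensitivity

`run_sensitivity` re-solves a case at 1 µm across a ladder of refinement
factors and tabulates the strain at four monitoring points — two ~10 µm off
the tip interface, two ~10 µm off the top interface (points configurable) —
plus the global maximum. `converged_at` returns the smallest element count
whose monitor strains are all within a tolerance (default 5% stiff, 2%
compliant in the shipped protocol) of the finest ladder rung. Convergence
is judged at the monitoring points only: they sit in smooth parts of the
field and converge, whereas the global maximum sits against re-entrant
90° corners of the probe, where linear elasticity has a strain singularity
and the discrete maximum grows without bound under refinement. The table
records the global-max trend but never gates on it.

## Verification fixtures

Analytic problems gate the solver before any probe case is reported:
homogeneous uniaxial extension (exact to machine precision, including
ν = 0.45), the constant-strain patch test on a sinusoidally distorted mesh
(exact), a slender cantilever with prescribed tip deflection against the
Timoshenko tip stiffness with rectangular shear factor κ = 10(1+ν)/(12+11ν)
(within 5% at six elements through the thickness — trilinear elements
retain parasitic shear, so coarse bending meshes sit a few percent stiff),
and a two-material series bar at ν = 0 whose strain partition ε₁/ε₂ = E₂/E₁
is exact (the 1D archetype of the probe–tissue mismatch; ν = 0 makes the
spring oracle exact rather than approximate). These are synthetic
verification problems, not tissue data: passing them demonstrates the
elasticity solver is correct, not that linear elasticity describes brain
tissue.

## What reproduces robustly and what does not

Ratio-type results — compliant maxima as percentages of the stiff baseline,
profile comparisons, locations, linear displacement scaling — are stable
across meshes because the corner-singularity amplification cancels.
Absolute corner maxima are not: with a square-cut tip, centroid sampling
and this mesh family, the computed stiff-probe maximum at 1 µm is ~0.011 at
48k elements and grows like ~h^(−1/2) under refinement, so published
absolute maxima obtained with other element types, tapered tip geometry
and extrapolated nodal sampling are not recovered at any practical
resolution (the published record itself prints two values 2.4× apart for
the same quantity). The package therefore treats absolute maxima as
convention-bound diagnostics and ratios as the scientifically portable
output.

## Known limitations

* Strains of order 1–5 under 10–20 µm loading are far outside small-strain
  validity; the model is linear by construction, as in the tradition it
  follows, and its large-displacement numbers are linear extrapolations.
* Fixed supports along bottom *edges* are lines, which have vanishing
  capacity in 3D elasticity: the anchoring they provide is mesh-dependent
  in principle. The clamped top face, not the edge support, carries the
  load path here, which keeps reported quantities stable.
* No viscoelasticity, no insertion mechanics, no frictional or cohesive
  interface laws, no tapered tips, no electrical modelling.
* The polyimide probe (E = 2.7 GPa, ~4.5·10⁵ × brain) is mechanically
  near-rigid at shank scale in this model, so its tissue strain relief
  relative to silicon is ~10–20%, at odds with much larger published
  reduction claims that are themselves mutually inconsistent; the
  discrepancy is inherent to any single-modulus linear model of this
  geometry.
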