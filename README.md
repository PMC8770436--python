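# micromotion-fem

Finite-element analysis of micromotion-induced strain in brain tissue around
intracortical probes.

Chronically implanted microelectrodes (Michigan-style silicon shanks and
their flexible successors) sit in cortical tissue that moves by 1–25 µm with
respiration, vascular pulsation and head motion while the probe itself is
tethered to the skull. The resulting interfacial strain is a mechanical
precursor of the glial scar that degrades recordings. This package models
that interaction as a static, small-strain, isotropic linear-elasticity
problem: a rectangular probe shank (1125 × 125 × 25 or 63 µm) bonded inside a
1500 × 1500 × 1500 µm block of grey matter (E = 6 kPa, ν = 0.45), with the
probe's top face — welded to the displaced cranium — driven tangentially by
d = 1–20 µm while the perimeter edges of the tissue base are fixed.

For displacement **u**, strain ε = sym(∇**u**) and isotropic stiffness
(λ, µ), the solver assembles K u = f on a graded, conforming hexahedral mesh
(trilinear elements with B-bar mean-dilatation treatment of the volumetric
term, which the ν = 0.45 tissue requires) and reports the Von Mises
(equivalent) strain

  ε_eq = 1/(1+ν′) · √(½[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²]),

computed per element at the centroid, with ν′ the element material's Poisson
ratio. Comparisons across probe materials (silicon 200 GPa, polyimide
2.7 GPa, post-insertion PVAc-NC 12.7 MPa, and a probe modulus-matched to
brain) use the maximum ε_eq over *tissue* elements, its location class
(tip/mid/top third of the shank), strain-versus-distance decay profiles, and
a four-point mesh-sensitivity protocol.

## Worked example

```python
from micromotion_fem import MicromotionModel, MeshParams

mesh = MeshParams(n_through_thickness=3, near_size=25.0,
                  grading=1.8, far_size=320.0)   # quick demo mesh
res = MicromotionModel.from_case(1, mesh=mesh).fit()
print(res.summary())
```

```
Micromotion strain results
============================================
case:                case1
probe material:      silicon (E = 200000 MPa, nu = 0.278)
probe dims (um):     1125 x 125 x 25
displacement (um):   1 (x direction)
mesh:                4335 hex elements, 5184 nodes
solver:              direct, residual 1.30e-13
--------------------------------------------
max tissue strain:   0.00669922
  at (x, y, z) um:   (50.0, 1133.4, -8.3)
  location class:    tip
monitor strains (tip 1-2, top 3-4): 0.005374, 0.004185, 3.718e-05, 0.0001899
```

The stiff probe translates essentially rigidly with the skull, so the
largest tissue strain appears just below the probe tip (`location class:
tip`, y ≈ 1133 µm for a 1125 µm shank) and scales exactly linearly with the
applied displacement — `res.rescaled(20.0)` gives the 20 µm solution without
re-solving. The tip-section decay profile falls roughly exponentially with
distance from the probe face:

```python
p = res.strain_profile("tip")   # distance (um), max Von Mises per distance
#   10.48  0.00541
#   39.84  0.00241
#   92.69  0.00091
#  187.81  0.00039
```

Compliant probes flex along the shank instead of carrying the motion to the
tip: at production meshes the 63 µm PVAc-NC probe's maximum tissue strain is
~11% of the silicon baseline, and for the 25 µm PVAc-NC probe the maximum
relocates to the top of the shank.

A CLI wraps the same pipeline:

```sh
micromotion-fem verify                 # analytic solver gates
micromotion-fem run --case 1 --out out # one case: results.csv, profiles.csv, VTU
micromotion-fem run-all                # the full case table, normalised
micromotion-fem converge --case 1 --ladder 1.6,1.3,1.0
micromotion-fem profile --case 3 --section tip
```

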