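# Methods

## Model overview

The package implements harmonic-field-driven orthotropic material assignment
for curved bone, with a dental-implant use case: a tet4 linear-elastic model
of a mandible-like body in which every cortical and cancellous element
carries its own right-handed material triad (e1 radial, e2 tangential, e3
axial) derived from two volumetric harmonic fields, and in which three
material models are compared on identical geometry, loads and restraints:

1. **isotropic** — effectively isotropic bone (E, ν per region);
2. **orthotropic** — nine-constant orthotropy rotated per element into the
   harmonic frames;
3. **zoned** — the simplified comparator: the bone is split into `n` equal
   intervals of the longitudinal field value and every element of a zone
   shares the single frame of the zone's representative element.

Assumptions: linear elasticity, small strains, perfect bonding everywhere
(implant–bone osseointegration realized by shared mesh nodes), static
loading, homogeneous constants per region (no CT-density mapping).  Contact,
viscoelastic soft tissues (periodontal ligament, TMJ disc) and implant
microgeometry (threads, abutment, screw) are out of scope; the implant is a
plain bonded cylinder because interface mechanics, not implant CAD, is the
subject.

## Harmonic fields

Both fields solve the discrete Laplace equation with the standard P1
stiffness (`K_ab = Σ_e V_e ∇N_a·∇N_b`, unit conductivity) and Dirichlet
seeds imposed by elimination, so seed values are met exactly.  Solves use a
direct sparse factorization for determinism; a conjugate-gradient option
(relative tolerance 1e-10) exists for larger meshes.

* `φ_long`: end caps seeded 0 and 1.  With `use_virtual=True` the solve
  domain is bone ∪ virtual fill; the fill lets the field cross the
  alveolar-ridge notch instead of bending around it.  The radial field is
  solved on bone only: ridge bending is a longitudinal-field problem, and
  re-routing the shell-to-shell radial field through the fill has no
  mechanical meaning.  Both seed specifications are overridable.
* `φ_rad`: cortical–cancellous interface 0, periosteal surface 1.

On the proxy this radial seeding makes `φ_rad` identically zero inside the
cancellous core (the core's entire lateral boundary carries the same seed
value), so core elements have a degenerate radial gradient.  This is handled
by the declared fallback policy — copy the frame of the nearest
non-degenerate element (centroid distance, KD-tree) and flag it — which in
practice gives the core the frame of the adjacent shell element above it.
Flags are exported so the fallback fraction is always visible.

Degeneracy thresholds: |∇φ_long| < 1e-12, or gradients within 1° of
parallel.  Axis signs are fixed by orienting e3 along the analytic reference
tangent where one exists (else toward increasing `φ_long`); elastic response
is sign-blind, stable signs just make runs comparable.

## Elasticity

Voigt order is (11, 22, 33, 23, 13, 12) with engineering shear strains, so
S44 pairs with G23 under the radial/tangential/axial axis naming.  The
Poisson convention is `S_ij = −ν_ij/E_i`; it renders both bone rows
positive definite and reproduces the published cortical effective modulus,
which is how the otherwise-unstated convention was pinned down.  Rotation
uses a constructively built Bond matrix (each Voigt basis tensor is rotated
as a 3×3 tensor and re-read in Voigt components), verified in tests against
the brute-force fourth-order rotation.

Voigt–Reuss–Hill reduction: K and G bounds from the standard stiffness /
compliance averages, Hill = arithmetic mean of the bounds, then conversion
to (E, ν).  For the cortical row this gives E=16.422 GPa, ν=0.320.  For the
cancellous row it gives E=1.611 GPa, ν=0.446 — *not* the 0.482/0.26 in
circulation for mandibular cancellous bone.  No Voigt/Reuss/Reuss-only/
alternative-convention combination of the nine cancellous constants yields
those numbers; they evidently originate from a different dataset.  The
material database therefore carries both: `bone_cancellous_iso`
(0.482, 0.26) as the literature value used by the isotropic baseline, and
the nine-constant row whose faithful reduction is reported by
`voigt_reuss_hill`.

Equivalent strain uses the commercial-solver convention
`ε_eq = √(½Σ(ε_i−ε_j)²)/(1+ν_eff)` with ν_eff = 0.3 by default
(configurable).  Compressive statistics are signed third-principal values;
"maximum compressive" is the most negative, with magnitude columns for
display.

## FE solver

Constant-strain tet4 with per-element stiffness `K_e = V_e Bᵀ C B`; units mm
/ GPa / kN internally, loads accepted in N, tractions in MPa, stresses
reported in MPa.  Restraints are zero-displacement on named node sets
(arbitrary prescribed values are available through `solve_prescribed`, used
by the patch tests).  The direct solve's free-equation residual is checked
to 1e-8 and a failure is classified as missing restraints.  Stresses are
per-element (not nodal-averaged): the reported maxima are element-set
statistics, and averaging would dilute them.

## The synthetic proxy

`generate_proxy` builds a circular-arc tube (default: arc radius 25 mm over
120°, outer radius 10 mm, 2 mm cortical shell) meshed by Kuhn subdivision of
a structured hex grid in arc-parameter × cross-section coordinates (6 tets
per cell, conforming, deterministic).  The outer radius corresponds to a
~20 mm body height, molar-region scale, which leaves the anatomically
expected ~8 mm of cancellous bone plus inferior cortex below the 10 mm
implant apex.  A notch (default 5 mm deep over 35° of arc) is carved into
the superior surface and re-tagged as `virtual` rather than removed, so the
fill is flush with the unnotched tube by construction.  A vertical implant
cylinder (10.0 × 4.8 mm, the fixture dimensions) is embedded at 70% of the
arc; the notch sits at 30%, so ridge and implant do not interact.  Named
sets (`end_cap_*`, `outer_surface`, `inner_interface`, `implant_surface`,
`crest_ring`, `implant_top`; element bands `ridge_band`, `crest_band`,
`apical_band`) are derived from the same analytic geometry.  An optional
jitter (≤ 25% of edge length, seeded, default off) perturbs interior
single-region nodes for robustness testing; default meshes are exactly
reproducible.

What the proxy does *not* emulate: anatomic cross-section shape, teeth /
periodontal ligament, TMJ structures, muscle attachment sites, CT-derived
heterogeneity, implant threads.  Passing the qualitative checks on the proxy
therefore shows that the *method* behaves as described on curved geometry —
not that patient-specific magnitudes are reproduced.

## Default load case and reporting

Bite-like case: both end caps fully fixed, 150 N vertical (−z) load divided
over the implant platform nodes (molar-bite scale).  Peri-implant ROIs are
the cortical and cancellous element bands whose centroids lie within a
configurable distance of the bone–implant interface nodes; `select_roi`
defaults to 1.0 mm, while the pipeline default is 2.0 mm because the default
edge length is 1.5 mm and a 1.0 mm centroid band is thinner than one element
layer.  The comparison table reports max and volume-weighted average of the
six measures per region and model, with percent changes against the
isotropic baseline computed from unrounded values.

On the default proxy the run reproduces the expected pattern: cortical peak
equivalent stress in the crest band for every model; cancellous peak
equivalent strain under the apex for the isotropic and orthotropic models
(the zoned comparator relocates it crestally — its hallmark irregularity);
cancellous strains above cortical strains; cortical peak stress an order of
magnitude above cancellous in the isotropic model.  Under true orthotropy
the cancellous peak stresses rise by several hundred percent, which narrows
the cortical-to-cancellous stress gap to a factor of ~2 — a stronger
expression of the known cancellous sensitivity to orthotropy than in
anatomic models, amplified here by the idealized geometry and by
constant-strain elements at the implant material corner.

## Numerical choices and limitations

* Direct sparse solves everywhere: desk-scale meshes, bit-stable results.
* Tet orientation canonicalized on construction (swap last two nodes).
* ROI anchor distances are measured to interface *nodes*, not to the true
  surface — consistent and deterministic, biased by at most one edge length.
* Zone partition of the comparator uses equal-width `φ_long` bins, a
  geometry-free analog of anatomic zoning; anatomic landmark zones are not
  reproducible on a proxy.
* Maxima at the implant rim/apex are mesh-sensitive (material-corner
  singularity under constant-strain elements); comparisons between models on
  the *same* mesh remain meaningful, absolute peaks are not convergent.
* Problem sizes: default proxy ~5.9 k nodes / 29 k tets; the full
  three-variant comparison runs in well under a minute on one core.
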