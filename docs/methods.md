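# Methods

## Model

The package treats an anteroposterior radiograph of an implant-stabilised
proximal femur as a plane linear-elasticity problem.  Each pixel of the
8-bit image becomes one square finite element whose material constants
are looked up from its gray value; the slab has unit thickness (1 mm), so
a 1 N/mm² edge traction integrates to 1 N per loaded millimetre.  The
model is static, geometrically and materially linear, and strictly 2D in
the frontal plane: out-of-plane bending and torsion are outside its
scope.  Plane stress is the default idealisation (a thin unit-thickness
slab); plane strain is available behind a flag and changes both the
constitutive matrix and the von Mises expression (σ_zz = ν(σ_xx + σ_yy)
enters the triaxial form).

### Materials

Five tissue classes own contiguous gray bands:

| class        | gray band | E (MPa) | ν    |
|--------------|-----------|---------|------|
| soft tissue  | 0–49      | 0.6     | 0.42 |
| cartilage    | 50–99     | 600     | 0.42 |
| spongy bone  | 100–169   | 3 000   | 0.32 |
| compact bone | 170–229   | 5 000   | 0.32 |
| implant      | 230–255   | 210 000 | 0.30 |

The band thresholds are implementation choices (config-exposed); the
(E, ν) pairs are the homogeneous tissue description the analysis is built
on.  Two assignment modes exist because a 256-level mapping and a
five-class homogeneous description are both defensible readings of
image-based FEM practice: `discrete` (default) bins to class constants,
`continuous256` interpolates log10(E) linearly within each band between
edge anchors (geometric means of neighbouring class moduli at interior
boundaries, the class modulus at gray 0 and 255).  The log scale is
forced by the six-decade span of E; linear interpolation would be
meaningless below the implant band.  Air/background is mapped to soft
tissue so the stiffness matrix has no zero blocks; an element-deactivation
utility (with a base-connectivity check) exists for workflows that prefer
voids.

### Boundary conditions and load

Both displacement components are fixed at every node of the bottom image
edge (clamped base).  A uniform traction of 1 N/mm² acts along the
gravity/limb axis on the top edge — by default only on segments whose
element is not soft tissue, i.e. on the articular surface of the femoral
head, which the phantom places across the top edge.  The 1 N/mm² figure
is the modelling input; the nominal 70 kg patient weight behind it is
recorded as metadata only, since 70 kg ≈ 687 N cannot equal 1 N per
loaded mm² for any plausible loaded width and the per-area load is the
quantity the model actually needs.  A roller base (vertical support, one
lateral pin) is provided for verification problems whose closed forms
require free lateral contraction.

### Elements and solver

Q4 bilinear (default) and Q8 serendipity quadrilaterals are both
supported; the "eight-node" and "linear" element descriptions in
image-based FEM practice conflict, so the order is a config switch and
all verification properties are tested for both.  Stiffness uses 2×2
(Q4) / 3×3 (Q8) Gauss quadrature — full integration, exact for the
affine element geometry the pixel lattice produces.  Edge tractions are
converted to work-equivalent nodal loads (½, ½ per linear edge;
1/6, 1/6, 2/3 per quadratic edge).  Constraints are applied by
row/column elimination so the reduced matrix stays symmetric positive
definite; the solve is a sparse direct factorisation, and every solve
checks a relative residual ≤ 1e-8 and recovers reactions as K u − f on
the fixed rows.  Global equilibrium (Σ reactions + Σ loads = 0 to 1e-8
relative) is asserted on every model the test suite and pipeline touch.

Verification: the uniform-compression patch column reproduces
σ_yy = −1 MPa and the closed-form tip displacement to 1e-8 relative for
all four order/plane combinations; the Kirsch plate-with-hole problem
(boundary-fitted transfinite mesh, geometric radial grading, hole radius
10 mm in a 100 mm quarter plate) yields a stress-concentration factor of
3.03 with Q8 (infinite-plate value 3.0, finite width raises it
slightly); strain energy increases monotonically under h-refinement; an
end-loaded cantilever matches the Timoshenko closed form
PL³/3EI + PL/(κGA), κ = 5/6, to 0.1 %.

### Stress summaries

Stresses are element means over Gauss points — no nodal smoothing, so
values never average across bone/implant interfaces.  The scalar effort
measure per region (BONE = spongy + compact, FIXATION, CARTILAGE,
SOFT_TISSUE) is the **95th percentile** of element von Mises stress.
The choice is deliberate: the extreme tail (99th percentile and max) of
the bone distribution sits in the distal shaft and at implant-tip
concentrations, where the *entire* applied load funnels through one
cortical cross-section — a quantity invariant to fracture morphology by
statics — while the peri-implant and peri-fracture band that
distinguishes fracture grades lives slightly lower in the distribution.
p95 is high enough to act as a robust regional peak (it ignores the
handful of near-singular clamped-corner elements) and low enough to read
the fracture-sensitive band.  Max, median, mean and arbitrary
percentiles remain available per call and per study config.

## Phantom generator

Real pre-operative radiographs are not shipped; the generator renders a
stylised proximal femur with pixel ground truth: femoral head with an
articular cartilage cap crossing the top edge (the load surface), neck
at a configurable neck-shaft angle (default 130°), greater-trochanter
region, and a shaft with compact cortex (6 mm), spongy interior and a
soft-tissue medullary canal, reaching the clamped bottom edge.  The
default canvas is 120 × 220 px at 1 mm/px (26 400 elements, ~1.5 s per
Q4 solve), chosen so a full factorial study runs in minutes.

Fracture severity is encoded through calcar (medial cortex) continuity,
which is the clinical criterion separating stable from unstable
pertrochanteric fractures:

* **A1** — simple oblique whose gap starts inside the bone, leaving the
  medial cortical buttress intact (2 mm gap);
* **A2** — full oblique plus a lesser-trochanter fragment line severing
  the calcar (3 mm gaps);
* **A3** — reverse oblique exiting the medial cortex below the
  trochanter plus a medial wedge line (4 mm gap, 1.4× for the wedge).

Gap pixels are labelled soft tissue (no fracture-gap material exists in
the five-class description; configurable).  Implants are filled
polygons bonded pixel-wise to bone — no contact, friction or sliding.
Gray values are band centre ± 10 uniform jitter, which never leaves the
band, so discrete-mode mapping recovers the ground-truth labels exactly.

Cohorts draw one geometry jitter per replicate (shaft width ±2 mm,
neck-shaft angle ±4°, head radius ±2 mm, gap scale 0.9–1.1) shared
across all type × implant cells of that replicate, so matched replicates
differ only in fracture morphology and hardware.  Everything is
deterministic in the base seed; per-model seeds derive from it.

What the phantom does **not** emulate: beam hardening, scatter, soft
tissue projection shadows, osteoporotic density gradients,
patient-to-patient anatomy beyond the jittered parameters, lateral
projections.  A pipeline property that passes on phantoms (e.g. the
severity-ordered bone stress) demonstrates that the mechanical chain
responds to fracture morphology as expected, not that the effect size
matches any patient population.

Known divergence: on phantoms the fixation/bone stress ratio is ~4–10
(clinically reported ratios for these systems are nearer 2–3), and the
DHS fixation stresses exceed the GNF ones for unstable types, because
the idealised perfectly-bonded hardware attracts more load than hardware
in real bone.  Both quantities are reported, not asserted, beyond the
ratio > 1 property.

## Statistics

Rank tests are implemented in-package (scipy is used only as a
cross-check oracle in the tests):

* **Mann–Whitney U**: midranks for ties; U = min(U_a, U_b).  Exact
  two-tailed p by full enumeration of the null U distribution (dynamic
  programme) when n₁ + n₂ ≤ 12 and the data are tie-free; otherwise a
  normal approximation with tie-corrected variance and a 0.5 continuity
  correction.  The Z-score always comes from the corrected normal
  deviate, signed by the rank-mean comparison — with U = 0 at n = 5, 5
  this gives Z = 2.51 and p = 0.012, matching the convention of standard
  statistical packages.
* **Kruskal–Wallis**: tie-corrected H, chi-square tail with k − 1 df,
  effect size η² = (H − k + 1)/(n − k) floored at zero.  The chi-square
  tail is an approximation: at n = 15 it deviates from the exact
  permutation distribution by up to a few hundredths in p, which is
  inherent to the approximation (not to this implementation) and is
  documented rather than hidden.
* **Pairwise comparisons**: Mann–Whitney over all unordered pairs,
  flagged at the Bonferroni level α/n_pairs (α = 0.05).  Dunn's test was
  considered and not adopted: the between-system comparisons already use
  Mann–Whitney machinery, and keeping one two-sample test makes the
  pairwise column directly comparable to it.
* **Shapiro–Wilk** normality is delegated to `scipy.stats.shapiro`.

## Study pipeline

`run_study` executes generation → mapping → meshing → solve → summary per
model and the statistics per cell, writing per-model CSV (fixed float
formatting, so reruns are byte-identical), report tables shaped as
median (min–max) per fracture type with KW p, η² and significant pairs,
and between-system Mann–Whitney rows.  All report statistics are
recomputable from the per-model CSV alone (`compute_report`), which the
tests exercise as a round trip.  Stage failures are reported with model
id and stage name.  Per-model caching was considered and rejected: at
~1.5 s per model a cache adds staleness failure modes without meaningful
benefit; determinism makes reruns equivalent.

Default study sizes: 5 models per cell (the conventional per-group size
for this design) in the acceptance script; the severity-trend test uses
10 per cell because median trends at n = 5 are noise-prone.

## Limitations

2D frontal-plane only; perfect implant–bone bonding; homogeneous tissue
classes (no densitometric calibration); phantom geometry is stylised;
the load model is a single static axial traction (no gait, impact or
torsion).  The statistics module assumes independent samples and
two-tailed hypotheses throughout.
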