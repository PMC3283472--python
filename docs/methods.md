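# Methods

This note documents the model behind `spondylofem`: its assumptions,
its parameters and defaults, what the synthetic anatomy does and does
not emulate, the numerical choices, and the known limitations.

## Coordinate conventions

Global frame: x anterior, y to the patient's left, z superior; gravity
along −z; mm / N / MPa units; sagittal angles in degrees. The analysis
frame is anchored at the middle of the L5 growth plate: z′ is the plate
normal opposed to gravity, y′ the in-plane sagittal anterior direction,
x′ = y′ × z′ (patient's right). σ_n = σ′_z′z′ (negative = compression
of the plate); τ_slip = σ′_z′y′ (positive = the traction on the cranial
face points anteriorly, i.e. promotes slippage).

## Spino-pelvic geometry

PI is the angle between the perpendicular to the S1 superior endplate
at its midpoint and the line to the bicoxofemoral axis midpoint; SS the
endplate inclination to the horizontal; PT = PI − SS. Slip percentage
follows the Taillard convention: posteroanterior displacement of the L5
inferior endplate over S1, projected on the S1 endplate AP axis and
normalized by its AP width. The paper trail for this disease never
fixes a measurement convention, so Taillard-at-endplate-level was
chosen for consistency with Meyerding grading (standard 25 % bands);
both the grading thresholds and the classification cutoffs
(shear: PI ≥ 60° and SS ≥ 50°; retroverted: PT ≥ 25°) are configurable.

Two operators parameterize a study case:

- `apply_slip` translates sacrum + pelvis rigidly along the L5
  inferior-plate in-plane PA axis. Because the measured slip projects
  on the S1 plate axis, the translation magnitude is solved in closed
  form so the measured value hits the target exactly even when a prior
  pelvic rotation has wedged the two plates (round trip within 0.1 %).
- `apply_pelvic_rotation` composes two sagittal rotations about the S1
  plate center: sacrum + pelvis (sets SS; PI is intrinsic to the pelvis
  and unaffected by a rigid rotation of the whole ring) and pelvis
  alone relative to the sacrum (sets PT, hence PI). Targets verified to
  0.1°.

Template personalization to landmark sets uses dual kriging with a
cubic radial kernel φ(r) = r³ and an affine drift; control nets are
normalized to a unit box before the solve (pure conditioning), the
drift reproduces any affine relation exactly, and coplanar or duplicate
controls raise a dedicated error.

## Synthetic anatomy

The template emulates the output of a multi-view radiographic
reconstruction: 17 named points per vertebra, 11 per rib, 23 on the
pelvis, with isotropic Gaussian noise of 3.3 mm (the technique's
published average accuracy) available for data-model studies. The
campaign itself runs on the noiseless template.

Defaults are the reference adolescent patient: age 14 y, height
157.2 cm, weight 45.5 kg, PI 61°, SS 52°, slip 30 % (Grade II). The
sagittal profile uses a lumbar lordosis of 65° distributed caudally
(30/25/20/15/10 % per junction from S1–L5 up; most curvature sits at
L4–S1) and a uniform 40° thoracic kyphosis — adolescent normative
ranges; the source patient's own curvature is not published. Vertebral
body dimensions scale linearly with stature.

The detailed L4–pelvis mesh is a structured loft through the endplate
quadrilaterals: vertebral bodies (3 element layers, cortical boundary /
trabecular core), discs (nucleus core within 45 % of the normalized
radius, annulus ring), and three-layer growth plates on both sides of
the L5–S1 disc (newly formed bone against the metaphysis, sensitive
zone, transition zone toward the disc). The L5–S1 gap decomposes per
corner into a through-thickness part (along the mean plate normal) and
a tangential part (slip offset + wedge): each growth plate extrudes
cleanly from its own vertebra and the disc absorbs the entire
tangential offset — growth plates are bonded to bone; the disc is the
compliant structure. The sacral dome is a spherical-cap bulge of the S1
interface (default 3 mm; 0 disables it, as in the validation
configuration), decaying through the disc above and into the sacrum
below. T1–L3 and the rib cage are beams; the L5 posterior arch hangs on
two pars beams (removed under the default bilateral lysis) and
articulates with the sacrum through short facet beams; anterior /
posterior longitudinal and interspinous ligaments are tension-only
springs.

Beam-to-solid attachments deserve a note: solid nodes carry no
rotational stiffness, so a beam assembly anchored at collinear points
can spin freely about the line through them. Every tie (chain→L4,
facets→sacrum, acetabula→pelvis block) therefore fans out to the k ≥ 4
nearest anchor nodes including distance ties — the tie is guaranteed
non-collinear and preserves the model's mirror symmetry exactly.
Facet anchors sit two element layers below the S1 endplate so
concentrated tie forces stay away from the growth plate being measured.

What the synthetic model does **not** emulate: patient-specific cortical
geometry, facet articular surfaces and contact, ligament prestrain and
nonlinearity, muscle lines of action, and a physiologically remodeled
(dome-conformed) high-grade junction. Passing tests therefore validate
the pipeline's mechanics and statistics on a controlled anatomy, not
the absolute stress levels of any real patient.

## Materials

Linear elastic throughout; defaults from the spine-FEM literature
(cortical 12 000 MPa / ν 0.30, trabecular 100 / 0.20, annulus 4.2 /
0.45, nucleus 1.0 / 0.499, growth-plate sensitive 12 / 0.45, transition
50 / 0.40, newly formed bone 350 / 0.30, pelvis bone 5 000 / 0.30;
ligament 20 N/mm, interspinous 10 N/mm; beam sections per structure).
Every value is overridable through the YAML `materials` block, and the
assembled stiffness scales exactly linearly in any single region's
modulus (verified by test).

## Loading and boundary conditions

Trunk weight is distributed per vertebra (defaults: T1 16.1 % lumping
head/neck/shoulders, T2–T12 2.3 % each, L1–L5 3.1 % each; ≈ 57 % of
body weight above the lumbosacral junction), fully overridable. The
follower load redirects each segmental force along the local tangent of
the deformed centroid chain (central differences, one-sided at the
ends) and iterates solve → re-tangent until the largest direction
change is below 10⁻³ rad (max 25 passes; a single-pass variant is a
flag). Magnitudes are preserved exactly by redirection. At L4 and L5
the force is spread over the mid-body cross-section rather than one
node, to keep point-load artifacts away from the growth plate. Standing
posture: both acetabula fixed in translation with rotational springs,
T1 blocked transversally (x, y), vertical free. The rotational spring
default is 5·10⁶ N·mm/rad per acetabulum: against the ≈ 2·10⁴ N·mm
body-weight moment about the bicoxofemoral axis this permits millirad
postural sway; values orders of magnitude softer let the whole model
pivot about the hip axis and are not usable for a standing analysis.

## Numerics

Trilinear hexahedra with 2×2×2 Gauss quadrature (exact for the
constant-strain patch test, verified to machine precision on distorted
elements); Euler-Bernoulli beams (nodally exact for tip loads); sparse
LU with symmetric Jacobi scaling and one step of iterative refinement,
residual enforced below 10⁻⁸ (the material contrast nucleus/cortical is
~10⁴). Tension-only springs are resolved by an active-set loop;
a spring oscillating at zero force between iterations is removed for
good (the conservative unilateral resolution). Stresses are
Gauss-averaged element-centroid tensors — the paper trail does not say
whether published maxima are nodal or element values, and the centroid
convention avoids extrapolation noise. Region partition: dome = top
20 % elevation quantile, lateral bands = top 30 % |x′| quantile,
remainder split anterior/posterior by the sign of y′, all computed
about the structure's own centroid so labels stay anatomical after the
structure is displaced by slip.

## Simulation campaign

The default campaign holds ten cases reconstructed from the published
study narrative: four low-grade cases at 30 % slip spanning nutcracker
(52/45) to shear (75/60) with the reference patient (61/52) and a
(75/52) interpolate between them, and six high-grade cases at 60 / 80 %
slip over PI ∈ {60, 75} and SS ∈ {45, 60}. The original constraint
equations that reduced the 2³ factorial are not recoverable
(supplementary material unavailable), so constraints are exposed as
user predicates and the table is overridable. Each case applies the
pelvic rotation and slip operators to the baseline template, meshes at
resolution 12 (~3 300 hexahedra — a deliberate desk-scale size; the
per-case solve takes seconds), runs the follower equilibrium, and
summarizes σ_n / τ_slip per region for the S1 growth plate and the
L5–S1 disc. Statistics: stresses grouped by one factor's levels at a
time for one-way ANOVA (singleton levels dropped; α = 0.05, no
multiple-testing correction by default, Bonferroni optional) and
Pearson correlations of |stress| against each factor.

The per-case scalar responses are the signed peak σ_n (max by
magnitude), the signed peak τ_slip, and the anteriority of the most
compressed decile of the S1 growth plate (mean y′ of those elements
relative to the structure mean). The compressed decile — not the
absolute-value decile — is used because growth-plate loading relevant
to growth modulation is compressive, and at high slip the plate also
develops a posterior tensile peel peak that would otherwise dominate
the metric.

## Behavior at high slip, and limitations

Two qualitative findings of the source study are reproduced by the
default model: the shear-type pelvis produces a larger peak
growth-plate compression than the nutcracker-type, and the most
compressed region of the S1 plate sits more anteriorly in high-grade
than in low-grade configurations. Two are not, for reasons that follow
from the stated parameterization rather than from numerics:

- Pure translation of the pelvis leaves the in-plane shear force
  transmitted across the junction unchanged (it is fixed by the free
  body above), while stretching the disc into an ever longer oblique
  band; element-level shear stress in the disc therefore *dilutes* as
  slip grows, at every resolution tried.
- Rotating sacrum + pelvis under a fixed L5 changes SS by opening the
  L5–S1 wedge rather than by re-orienting the load relative to the
  junction; the compressive state across a larger wedge contributes
  negatively to the L5-frame slip-shear component, so the shear-type
  case shows a *smaller* peak growth-plate shear than the nutcracker
  case here.

Both behaviors are documented honestly and asserted as-is in the test
suite; reproducing the original signs would require the
patient-specific, dome-conformed high-grade geometry that is outside
this package's scope. Further limitations: small-strain linear
elasticity only (no contact, no geometric nonlinearity — an 80 % slip
held in a linear configuration is a strong idealization), no growth
simulation (stress maps are inputs to growth-modulation reasoning, not
growth predictions), and ANOVA on ten deterministic cases is
descriptive rather than inferential.
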