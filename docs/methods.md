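# Methods

`kneesim` simulates a cruciate-retaining total knee arthroplasty (CR-TKA) as
a three-rigid-body quasi-static mechanism and reproduces a classic surgical
study design: changing the posterior tibial slope with two referencing
techniques and measuring the consequences for joint laxity and for knee
forces during a squat.  This note records the model, its assumptions, the
parameters that matter, and what the synthetic test bed can and cannot show.

## The mechanical model

**Bodies and frames.** Femur (ground), tibia and patella are rigid.  The
tibia frame has its origin at the midpoint of the medial and lateral plateau
centres, +x anterior, +y proximal (the tibial mechanical axis), +z lateral
(right knee).  The femur frame sits on the flexion axis at the midpoint of
the condylar centres and coincides with the tibia frame at full extension.

**Force-dependent kinematics.** Knee flexion is prescribed; the remaining
five tibiofemoral coordinates (AP/ML/PD translation, varus-valgus,
internal-external rotation) and all six patellar coordinates settle where
the generalized forces from ligaments, articular contact, the quadriceps
tendon and external loads vanish.  Convergence means every generalized force
component is below 0.5 N and every moment below 0.01 N·m (configurable).
Clinical angles and translations are reported in the floating-axis joint
coordinate system (flexion about the femoral medial-lateral axis,
internal-external rotation about the tibial long axis, varus-valgus about
the mutually perpendicular floating axis); its decomposition and composition
are exact inverses, verified to 1e-6 over the full motion range.

**Implants.** The femoral component is two spheres (radius 22 mm, centres
44 mm apart on the flexion axis) plus a grooved trochlear cylinder (radius
28 mm, shallow parabolic flanges) that serves both patellar contact and
quadriceps-tendon wrapping.  The tibial insert is a conforming lipped
bearing: per compartment a toroidal dish (sagittal radius 30 mm, coronal
25 mm) whose anterior and posterior lips (8 mm) bound the bearing surface.
The insert's built-in slope (default 3°) tilts the articular surface inside
the component frame; the neutral baseline sets the bone-cut (resection)
angle so that built-in plus resection slope is zero.  Dimensions follow
published component size charts for a mid-size knee; the commercial insert
this emulates is proprietary, so analytic primitives are used deliberately.

**Slope referencing.** A slope case rotates the tibial component in the
sagittal plane about a pivot: the anterior tibial cortex (ACR; pivot 25 mm
anterior of the plateau-centre midpoint, configurable since the anatomical
distance is not standardized) or the plateau-centre midpoint (CPR).  ACR
with posterior slope lowers every plateau point distally; CPR preserves the
joint line at the pivot.  Both are exact rigid rotations; their composition
algebra (ACR followed by inverse CPR is a pure translation) is tested.

**Ligaments.** Eight bundles: MCL, LCL, two-bundle PCL (anterolateral /
posteromedial), antero-lateral complex, posterior capsule, MPFL and the
patellar ligament, each a tension-only piecewise quadratic-linear spring
(toe region up to twice the toe strain, then linear; C1-continuous,
conservative).  Stiffnesses (1.2–40 kN per unit strain) and reference
strains at full extension are standard knee-spring-model values; the PCL is
deliberately on the lax side (reference strains −0.15/−0.10), engaging only
past mid-flexion, as appropriate for a lax-PCL CR-TKA.  Slack lengths are
calibrated so each bundle carries exactly its reference strain at the
full-extension seating pose.  The generator perturbs attachments (SD
0.5 mm), stiffnesses (SD 5%) and reference strains (SD 0.003), Gaussian
truncated at ±3 SD, deterministically per seed.

**Contact.** Elastic foundation: local pressure `p = k_c δ` with penetration
δ measured along the insert vertical on a fixed 40×40 grid per compartment.
`k_c = 1.2e11 N/m³` puts ~0.15 mm of penetration under a 2000 N axial load,
the standard desk-scale choice for conforming polyethylene.  Cell forces are
taken along the gradient of the gap with respect to the condyle centre — a
line of action through the spherical condyle's centre — which makes the
residual exactly the negative gradient of the foundation energy (verified
against central differences to 1e-4 relative).  The pressure-weighted mean
contact location (centre of pressure) is the reported contact point.
Patellofemoral contact uses the same foundation law sampled on the button
dome against the grooved trochlea.

**Quadriceps path.** A single equivalent actuator from a femoral origin to
the superior patellar pole, wrapping the trochlear cylinder as a frictionless
taut string (straight–arc–straight geodesic).  The wrap force on the femur is
`2T sin(γ/2)` toward the axis; engagement flexion emerges from geometry
(clear in extension, wrapped in deep flexion).

**Patellar soft-tissue envelope.** The line elements above leave patellar
spin nearly unrestrained and give the patella no home when the quadriceps
and patellar ligament are slack, so the envelope is completed by a lumped
retinaculum (torsional, 5 N·m/rad toward an orientation that flexes at half
the knee angle) and a weak positional tether (500 N/m toward the trochlear
track, whose angular position runs at ~1.1× flexion, matching the model's
own solved path).  Both are soft against every tendon and contact force.

## Protocols

**Laxity battery.** At 0/30/60/90° of flexion: anterior and posterior 70 N
forces along the tibia-frame AP axis at the joint-line level, and 15 N·m
varus/valgus moments built the way a physical rig builds them — a 50 N
transverse force 30 cm distal to the joint line.  Laxity is the change of
the respective joint coordinate versus the unloaded equilibrium at the same
angle, positive along the load.  Every case (including "unloaded") carries a
150 N compressive preload along the tibial axis: the original protocol's
unloaded equilibrium lives inside a full-body model that transmits limb
weight and muscle tone through the joint, and at desk scale that compression
is what keeps the most slackened variants located on the bearing (the 70 N
drawer exceeds the dish restraint `N·tan(lip angle)` for preloads much below
~100 N).  The full design is 2 techniques × 5 slopes (−3/0/+3/+6/+9°) × 4
tests × 4 angles = 160 measurements.

**Squat.** The source task's full-body drive (ground reactions, marker
kinematics, a 166-muscle lower limb) is out of scope; it is replaced by a
reduced planar loading model, the package's largest deliberate
simplification.  Flexion runs 0→90→0° in 2° steps (cosine-timed over 8 s;
the solution is quasi-static, time only labels samples).  At each sample the
external knee flexion moment is `M(φ) = W_leg·L_max·sin φ` with
`W_leg = body weight × per-leg share` (750 N × 0.5) and `L_max = 0.12 m`,
the shank transmits `W_leg` up the tibial axis, and the quadriceps tension
is an additional unknown solved simultaneously with the equilibrium so that
the net extension moment of the tibia+patella subsystem balances `M(φ)`
(the actuator is one-sided; surplus passive extension moment is carried by
the prescribed-flexion constraint).  Outcomes: quadriceps, quadriceps–femur
(wrap) and patellofemoral forces in % body weight, PCL/MCL/LCL tensions,
medial and lateral contact-point tracks and their travelled arc length, and
patellar height (superior offset of the button centre in the femur frame,
reported relative to the same-technique neutral-slope baseline at matched
flexion, so the baseline reads zero).

## Numerics

The equilibrium root-find is a scaled Powell hybrid iteration with a bounded
initial trust-region step, a Levenberg-Marquardt polish when the iterate is
near the solution, load-magnitude continuation, and (for cold starts in deep
flexion) continuation in flexion from full extension.  Warm starts across
flexion angles transport the previous solution as a deviation from a
geometric seed that is re-seated against the (slope-case-transformed) insert
by bisection on contact force; without the re-seating, seeds can carry a
contact gap in which the residual is flat and the Jacobian singular.  Loaded
laxity tests ramp the test load up from the unloaded equilibrium in four
steps; because the restoring moment of a dished insert saturates before a
slack ligament re-engages, the loaded branch can be separated by a fold, and
a failed ramp falls back to displaced, re-seated jump seeds on the far
branch.

The piecewise-spring tissue model never ruptures, so mathematically valid
but physically impossible equilibria exist (a patella dislocated behind the
femur with its ligament stretched 90%, a tibia wedged 17 mm laterally, poses
at the ±90° Cardan singularity where one torque direction escapes the
residual projection).  Quartic barrier "guards" on the rotational
coordinates (engaging beyond ~57°), on medial-lateral tibial translation
(beyond 8 mm) and on patellar distance from the trochlear track (beyond
20 mm) exclude these branches.  All guards are conservative potentials and
are identically zero throughout the physiological range, so they do not
alter physical solutions; they are part of the residual and of the energy,
preserving the gradient identity.

The solver contains no randomness: a model plus loads determines the result
bit-for-bit, and the generator is deterministic per seed, so the entire
study is reproducible from one integer.

## What the synthetic test bed shows — and what it does not

The generator emulates the *class* of knee the study used: a conforming
lipped CR insert, spherical condyles, a lax PCL, a native slope of about 7°
removed by a neutral resection.  Passing tests therefore demonstrate that
the mechanisms the study describes follow from this class of geometry and
tissue model: joint-line lowering under ACR slackens the whole envelope and
inflates every laxity; CPR's joint-line preservation leaves laxity nearly
unchanged (and slightly *tightens* anterior laxity); posterior slope shifts
the tibia anteriorly under load, lengthening the extensor moment arm and
reducing quadriceps demand; under ACR the femur drops relative to the
tibia-anchored patella, so the patella rides high, the tendon unwraps, and
the quadriceps–femur force falls, while CPR preserves patellar height and
load sharing and so converts the quadriceps reduction into a larger
patellofemoral force reduction.

The paper's printed magnitudes (laxity increases "up to 400%" under ACR,
"up to 42%" under CPR, −12 %BW of patellofemoral force per 3° under CPR,
−5.2/−3.5 %BW of quadriceps force per 3°) belong to one proprietary
patient-specific model driven by one subject's recorded squat; they are not
reproducible from the text and are treated as directional claims here, not
as target values.  Likewise absent from the desk model: real muscle
redundancy (166 actuators collapsed to one), femoral roll-back from
multi-radius condyles, viscoelasticity, friction, wear, deep flexion beyond
90°, and any statistics across patients (the study itself is a single-knee
experiment).

## Problem sizes

Default sampling — contact grids 40×40 per compartment, 12×24 dome samples,
laxity continuation in 15° substeps, squat in 2° steps (91 samples per
variant) — runs the complete 10-variant study in roughly ten minutes on one
CPU, with every one of the 160 laxity cells and all squat samples converged.
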