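# Methods

This note documents the models, conventions, numerical choices and known
limitations of `tkaplan`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Coordinate and pose conventions

All lengths are millimetres, all angles degrees at the API surface. The
anatomical frames are right-handed with **+x medial, +y anterior,
+z proximal**. A `RigidPose` carries the six clinical degrees of freedom —
anterior–posterior (AP), proximal–distal (PD) and medial–lateral (ML)
translations; flexion–extension (FE), abduction–adduction (AA, varus
positive) and internal–external (IE) rotations. Rotations compose in a
fixed Grood–Suntay-like order, flexion first:
`R = Rz(IE) · Ry(AA) · Rx(FE)`, translation `(ML, AP, PD) → (x, y, z)`.
The round trip pose → matrix → pose is exact to 1e-9 away from the AA = ±90°
gimbal singularity, which is far outside the physiologic range used here.

Gaps are measured along the tibial resection-plane normal (not the tibial
mechanical axis): the clinically relevant quantity is the shortest distance
from a component condyle to the cut, and the cut is the reference surface the
insert sits on. Signed distances are positive on the normal (proximal)
side; penetration is reported negative, never clamped.

## Synthetic knee generator

The generator replaces CT reconstructions and dual-fluoroscopy registration
with the simplest geometry that preserves the quantities the planners
consume, each with a closed-form oracle:

* **Femoral condyles**: two equal spheres (radius 24 mm, centre spacing
  46 mm) plus a shaft cylinder. The femoral component's articular surface
  is a zero-offset shell of the condyles, so a perfectly executed MB plan
  restores the native surface exactly and the component pose in the femoral
  frame is the identity.
* **Tibia**: an elliptical slab (width 75 mm, depth 50 mm) whose top cap is
  dished 1 mm; an analytic cross-section (π·a·b / cos slope) validates the
  mesh–plane cutter. The baseplate catalog holds four superellipse trays
  (exponent 2.5) at 0.70–0.85 of the plateau half-axes; with the 2 mm
  overhang limit this yields penalized coverage near 77%, in the range
  reported for clinical tray fitting.
* **Kinematics**: a 0°–100° lunge sampled every 10° (configurable), with a
  smooth screw-home IE excursion (2°·sin(πθ/100)), a small posterior AP
  excursion, and proximal translation keeping the lower condyle in plateau
  contact.

### Deformity model

The dynamic coronal deformity of severity α is a **femur-fixed rotation**
`D = Ry(α) · Rz(−β)`, composed into every frame between flexion and the
bone: varus wear narrows the involved compartment in extension, and the
paired rotational component narrows it in flexion. β is set so the
compartment narrowing is equal at both ends of the captured arc
(`sin β = tan 50° · sin α` for a 0°–100° lunge). Consequences, all tested:

* the medial–lateral gap asymmetry equals `spacing · sin α` exactly at 0°
  and 100° and rises to at most 1.56× mid-arc — the small-angle oracle
  46·sin 3° ≈ 2.4 mm used throughout the tests;
* the deformity is cancelled *exactly* by a constant component pose delta
  with AA = −α and IE = +β, which is the configuration gap-balance
  optimization must recover (parameter-recovery slope 1);
* a constant tibial-frame AA offset was rejected as the deformity model: no
  constant femoral-frame pose delta can cancel it (the achievable
  compensation spans {cos FE, sin FE}), so balanced-at-all-angles plans
  would be geometrically impossible, contradicting the behaviour the
  planner is meant to exhibit.

The standing (HKA) deformity is separate: a constant additive offset on the
stored AA coordinate, which the varus–valgus correction removes exactly
(`AA ← AA − HKA`, all other DOFs untouched). Optional zero-mean sinusoidal
kinematic noise (default amplitude 0) is available for robustness studies.

What the generator does **not** emulate: native medial-tight/lateral-lax
laxity (condyles are equal spheres), cartilage and menisci, cruciate
ligaments, condylar asymmetry, soft-tissue releases, and measurement noise
of 2D–3D registration. Passing tests therefore demonstrate correctness of
the planning chain under an idealized, exactly-compensable deformity — not
performance on real patient data, where the residual after gap balancing
would be bounded below by how far the true asymmetry profile lies from the
span of constant pose deltas.

## Tibial planner

Resection plane: through the lateral plateau landmark moved 8 mm distally,
normal `(0, −sin s, cos s)` for posterior slope s (surface drops
posteriorly), no coronal tilt. The implant undersurface footprint is the
mesh cross-section 0.1 mm above its lowest point.

Simulated annealing state is (x, y, rotation-from-Insall, size index):
Gaussian proposals (1 mm / 1° sd), rotation clamped to ±5°, size resampled
with probability 0.1, geometric cooling at 0.97/iteration from T₀ = 5, 200
iterations, Metropolis acceptance on PCI. Overhang is doubly handled, as in
the objective's area penalty *and* as a hard 2 mm boundary-distance
constraint (candidates beyond it score −∞); the best-so-far placement is
returned, so the result never scores below the centred Insall-aligned
start. Overhang distance is measured by sampling the footprint boundary at
0.1 mm and taking the maximum distance of outside points to the resection
region (validated against 0.01 mm brute-force sampling to 0.05 mm).

## Femoral planner

The MB plan aligns the component ML axis with the TEA and its proximal axis
with the HKA-corrected mechanical axis; distal and posterior cuts sit one
component thickness (default 9 mm) above/behind the corresponding native
extremes, and the component is seated so its own extremes restore them.

Gap balancing runs CMA-ES (in-house implementation of the standard
(μ/μ_w, λ) algorithm with step-size and covariance adaptation) from the MB
pose, σ₀ = 1 in natural units (mm / degrees, well-scaled because the
relevant sensitivities are comparable), default population 4+⌊3 ln 6⌋ = 9,
1500 evaluations. Search bounds: ±3 mm per translation, ±3° FE, **±8° AA
and ±8° IE** — symmetric rotational bounds chosen to cover the 0.7°–7.0°
modeled deformity range with margin, since the exact compensation requires
|IE| ≈ |AA|. Out-of-bounds candidates incur a large additive penalty.
Elitism guarantees the returned loss never exceeds the MB baseline. The
full-series loss uses every kinematic frame; the 0°-only and {0°, 90°}
variants resample the series by per-DOF linear interpolation (inter-frame
steps ≤ 10°, where Euler-DOF interpolation is benign).

Insert recommendation: largest catalog thickness not exceeding the smallest
per-frame gap (ties resolved toward the thinner insert to avoid
overstuffing); if even the thinnest overstuffs it is returned with a
warning flag.

Because the injected deformity is exactly two-parameter, the {0°, 90°}
variant pins both parameters and nearly coincides with full-flexion
balancing in this synthetic setting, and the exact compensation includes a
femoral IE rotation comparable to the varus correction. Real kinematics
have richer asymmetry profiles; there the reduced-range variants leave the
mid-flexion residual that motivates full-arc balancing, and rotational
adjustments need not mirror the coronal ones.

## Ligament model

Wrapping paths are computed in two stages: a visibility-graph seed
(obstacle-surface samples offset outward by 4% of obstacle size, edges
admitted when sampled segment points clear all meshes, Dijkstra shortest
path), then a taut-string refinement alternating midpoint smoothing,
projection of penetrating points to the nearest surface point plus a
1e-3 mm clearance, greedy farthest-visible shortcutting and uniform
resampling (100 points), until the length changes by < 3e-6 relative. Two
separate offsets matter: the coarse seeding offset only routes the path on
the correct side, while the refinement clearance bounds the systematic
radius inflation — it must be small relative to obstacle curvature (a
single 0.1 mm clearance would inflate a 1 mm-radius wrap by 10%). On the
unit-sphere tangent–arc–tangent benchmark the computed length agrees with
the closed form to < 0.1%. Containment and closest-point queries use the
package's own winding-number/point–triangle routines (`tkaplan.meshquery`).

Strain is ε = (L − L₀)/L₀ with L₀ the same-mode length at 0° flexion, so
strain and force vanish at extension by construction; native and implanted
sweeps each use their own 0° reference. The force law is evaluated exactly
as written above (continuous and C¹ at ε = 2ε₁ with value k·ε₁ and slope k).
The tension protocol adds bundle forces to per-side baselines (aMCL and
pMCL share the 130 N medial baseline; iLCL the 100 N lateral one) on the
0°–100° by 10° grid. Viscoelasticity is not modeled.

## Statistics

Strategy comparisons use the two-sided paired Wilcoxon signed-rank test per
flexion angle (scipy's exact distribution whenever n ≤ 25 and differences
are untied) with Holm correction across angles, plus paired Cohen's d. A
structural caveat: with 8 subjects the exact two-sided floor is
2/2⁸ = 0.0078125, so Holm across 11 angles (smallest adjusted p 0.0859)
can never reach 0.05 — per-angle corrected significance is unattainable at
this cohort size regardless of effect size, and the comparison tables
faithfully report that. Larger cohorts or a smaller angle family are
required for corrected per-angle claims.

## Determinism and problem sizes

Every stochastic stage (cohort draws, SA, CMA-ES, kinematic noise) is
seeded by SHA-256 hashing of (global seed, subject, stage), so any subject
is reproducible in isolation and full runs are byte-identical. Default
problem sizes — 8 subjects, 11 frames, 200 SA iterations, 1500 CMA-ES
evaluations, 100-point wrapping paths over ~2.5k-face meshes — were chosen
so the planning chain's optima are well-converged relative to the reported
tolerances while a full cohort run stays under a minute; they are
configuration fields, not hard-coded.

## Known limitations

* Gap computation takes vertex-wise minima; icosphere discretization
  contributes ~0.01–0.05 mm of noise to gaps, which is why exact-symmetry
  assertions use a zero-slope configuration.
* The mesh cutter assembles cross-section loops with one nesting level
  (outer boundaries and direct holes), sufficient for solid bones and
  implants but not for arbitrarily nested sections.
* CSG resection of bone fragments is out of scope; only cross-section
  contours are produced.
* The wrapping solver assumes locally convex-ish obstacles of the kind bone
  and implant surfaces present; deep concave mazes would need denser
  visibility seeding.
* The sloped cut plane couples the deformity's rotational component weakly
  into measured gap differences (≈6% at extension for the default 3°
  slope); this is the physics of measuring along the cut normal, not an
  artifact.
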