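# Methods

This note records the model equations, the assumptions behind the desk-scale
reduction, the tunable parameters with their defaults and provenance, what
the synthetic geometry does and does not emulate, and the numerical choices.
Every number quoted here is computed by the test suite or the acceptance
script; nothing is asserted that the code does not reproduce.

## 1. Muscle constitutive law

The muscle is an active, transversely isotropic, hyperelastic solid. With
`C = FᵀF`, `J = det F`, `Ī₁ = J^(−2/3) tr C`, fiber direction `N` (|N| = 1)
and deviatoric fiber stretch `λ̄f = J^(−1/3) √(NᵀCN)`:

    U = G/2 (Ī₁ − 3)  +  K/2 (ln J)²
        + σ₀ ∫₁^λ̄f f_PE(λ) dλ  +  σ₀ ∫₁^λ̄f f_SE(λ, ζ) dλ

    f_PE(λ)   = A (λ − 1)²                          for λ > 1, else 0
    f_SE(λ,ζ) = 0.1 [exp(100 (λ − 1 − ζ)) − 1]      for λ > 1 + ζ, else 0

Both fiber integrals have elementary antiderivatives and are evaluated in
closed form; adaptive quadrature is kept only as a test oracle. The second
Piola–Kirchhoff stress is the exact derivative `S = 2 ∂U/∂C`:

    S = G J^(−2/3) (I − tr(C)/3 · C⁻¹)  +  K ln J · C⁻¹
        + σ₀ (f_PE + f_SE) λ̄f (N⊗N/λ² − C⁻¹/3)

and `σ = J⁻¹ F S Fᵀ`. We derive stresses from the energy rather than
transcribing printed tensor formulas; a central-finite-difference oracle
(100 seeded random states, relative Frobenius tolerance 1e−6) arbitrates,
together with frame-indifference and zero-reference checks.

**Activation without neural input.** The contractile strain is slaved to
the element's engineering strain: `ζ = C_CE1 ε` when shortening (ε < 0),
`ζ = C_CE2 ε` when lengthening (ε > 0). Because `C_CE2 < 1`, a stretched
fascicle always satisfies `λ̄f > 1 + ζ` and produces active stress — this is
the stretch-activation mechanism that couples disk swelling to muscle force.
Contraction velocity enters only through the history of ε along a
simulation; there is no explicit force–velocity curve (two extra parameters
would be needed, with no data for back muscles to set them).

**Parameters** (per muscle group): `G = 16.42·10⁻⁴ MPa` and `K = 1000·G`
(nearly incompressible matrix), `σ₀ = 0.46 MPa` (mean of the reported
0.16–1 MPa skeletal-muscle range, one value for all groups), `A = 4.0`
(frog-muscle fit). Active parameters (concentric/eccentric): MF
0.706/0.465, LTpL and LTpTh 0.718/0.473, ILpL 0.737/0.485, PS 0.967/0.637.
These are a uniform rescaling (ratio constant to <0.1% CV — asserted in the
tests) of the sarcomere-derived values `C_CE = Lˢ/2.8 µm` (0.811, 0.825,
0.846, 1.111), which by themselves would not reach the activation threshold
at physiological strains.

**Uniaxial element contract.** Fascicles are straight force elements. The
element specialization assumes J = 1 (so λ̄f = λ) and a laterally
traction-free matrix: axial Cauchy stress `G (λ² − 1/λ) + σ₀ f_PE + σ₀ f_SE`,
force = stress × current area `csa/λ`, tension positive. Consequence: the
volumetric matrix term never engages in an element, so shortened fascicles
carry only the (tiny) deviatoric matrix compression — elements are
effectively tension-only. Compressive fascicle forces of a 3D volumetric
model are therefore not reproduced.

## 2. Fascicle network and synthetic geometry

23 sagittally symmetric fascicle pairs: multifidus 8 (three anteroposterior
sub-groups: deep laminar, intermediate, superficial spinous), LTpL 3, ILpL 2
(13 local pairs), LTpTh 4 (all reaching one rostral node on a rigid
"thoracic rod"), psoas 6 (all reaching one femoral node) — 10 global pairs,
46 elements. ILpTh is omitted (its standing contribution is about half of
LTpTh's and it has no lumbar attachment).

Published sources give the counts and topology but not the subject-specific
3D insertion coordinates, so the geometry generator synthesizes them from
configurable per-vertebra site offsets (spinous process ≈ 55–58 mm posterior
of the vertebral center — the upper end of lumbar morphometry, giving the
dorsal muscles their anatomical moment-arm advantage over the ligaments —
lamina, transverse/accessory processes, anterolateral vertebral body) on a
lordotic chain (default segmental extension tilts: L4/L5 8°, L5/S1 = 1.4 ×
L4/L5 — the proportion is a config parameter, not a published constant —
L3/L4 6°). The thoracic rod node sits 80 mm posterior of L3 at L3's
cranio-caudal coordinate in the reference pose. Cross-sectional areas are
an explicit config table (equivalent CSA = volume/length, 55–110 mm²);
no force path depends on hidden constants.

The rod node *translates* with L3 (the thorax rides on the uppermost modeled
vertebra) but does not inherit its sagittal tilt — trunk orientation is not
slaved to a single vertebra. Rigidly slaving it makes LTpTh hypersensitive
to L3 rotation (an 80 mm lever) and contradicts both the expected low
thoracic contribution and the requirement that overnight swelling stretch
every fascicle; a space-fixed rod fails the latter too, because L4/L5 rise
toward it. Rod-applied forces transfer to L3 as forces only (no moment),
consistent with the translation-only kinematic map.

What the synthetic geometry does **not** emulate: curved muscle paths and
wrapping, via points, volumetric fascicles with Poisson interactions,
subject-specific insertion scatter, a real ribcage. A green network test
therefore establishes topology, symmetry, and self-consistent kinematics —
not anatomical coordinate accuracy.

## 3. Gravity loads

Segment masses are percent-of-body-mass (head + C1–C7 from inertial
crash-dummy data; T1–L5 from radiographic densitometry), rescaled to the
simulated subject (default 70.8 kg). The percentage column is authoritative:
the published absolute-mass column is internally inconsistent at L4/L5
(0.18 kg vs 2.6% ≈ 1.84 kg, a decimal slip) and only 2.6% reproduces the
documented 18.1 N level loads. Everything above L4 is lumped into one load
at L3/L4 applied at the mass-weighted mean eccentricity
`R_eff = Σ mᵢrᵢ / Σ mᵢ`; the per-segment eccentricities rᵢ are not
published, so the shipped table uses a plausible anterior-offset profile
(peaking mid-thorax) scaled once so the default configuration returns
R_eff = 41.4 mm — labeled as calibration in the CSV header. L4 and L5 load
their own levels at 11 mm and 4 mm. With g = 9.81 m/s²: 239.6 + 18.1 +
18.1 ≈ 276 N. The parallel-axis (Huygens–Steiner) machinery
(`Iz_eff(L3) = Σ_{T1..L2} mᵢdᵢ² + Iz_local`) is implemented and tested;
head/cervical transfer terms are excluded (their d² is second-order small).

## 4. Disk column

The disk is reduced to a laterally confined axial column: cartilage endplate
(0.8 mm) – nucleus (8 mm) – endplate, effective area 1800 mm². Fields:
solid displacement u(z,t) and water chemical potential µ = p − π, with π
fixed in time (Donnan swelling pressure: Δπ = 0.15 MPa in the NP, linear
across the endplates, zero at the drained boundaries where p = 0).
Small-strain equations with incompressible constituents:

    ∂z [H_A ∂z u − (µ + π)] = 0 ,    ∂t(∂z u) = ∂z [k(e) ∂z µ]

Parameters (MPa, mm⁴/(N·s)): NP G 0.47, K 0.16, e₀ 4.9, k₀ 0.0009; CEP
G 8.55, K 10.10, e₀ 4.0, k₀ 0.0025; AF row (0.95, 0.37, 3.0, 0.0002)
shipped for column variants but unused by the default NP–CEP stack; M = 8.5
everywhere. The permeability law is normalized so k(e₀) = k₀ exactly (the
printed form of the exponent's companion factor is typographically garbled;
"initial permeability" forces the normalization). Void ratio updates as
e = e₀ + (1+e₀)ε per element.

A fresh column starts at p = 0 (µ = −π): chemically out of equilibrium, so
water flows in until p → π — free overnight swelling. The 8-h NP-center
rise with default parameters is 0.1499 MPa (acceptance band 0.11–0.15; the
in-vivo overnight window is 0.10–0.24 MPa). Because equilibrium pore
pressure equals π regardless of elastic load sharing, this number is robust
to the skeleton coupling.

**Numerics.** Linear FEM in u and µ (equal order), monolithic backward
Euler, Picard iteration on k(e) to a 1e−10 relative increment. Equal-order
u–p elements develop the classic checkerboard pressure mode for time steps
below the element consolidation time; the mean is exact, reactions (from
the equilibrium residual) are unaffected, and the NP-center IDP readout
applies the standard (¼, ½, ¼) nodal filter, which annihilates the
checkerboard exactly and is the identity on smooth fields. Verified limits:
Terzaghi consolidation series (<1% space-time L2, constant-permeability
limit), undrained step response (filtered IDP = F/A within 2%), drained
tangent stiffness = H_A·A/H within 2%, undrained > drained stiffness, mesh
convergence (<1% on the 8-h pressure when halving spacing). Free swelling
reaches ~19% nucleus strain, stretching the small-strain kinematics; this
is accepted as part of the scaled-down contract and is why the column is a
1D analogue, not a 3D prediction.

**IDP convention:** IDP = total fluid pressure µ + π at the NP mid-node, so
the overnight rise approaches the osmotic gradient and loaded standing
values sit in the measured 0.2–0.4 MPa range.

## 5. Coupled scenario engine

Sagittal-plane reduction: rigid L3, L4, L5 with 3 DOF each (anteroposterior,
axial, rotation about the vertebral center); S1, pelvis/sacrum and the
femoral node fixed. All simulated scenarios are sagittally symmetric, so
left/right fascicle pairs stay exactly mirror-loaded (asserted to 1e−8).

Per level, four parallel load paths: the disk column (driven by the axial
approach of the endplate centers along the reference disk axis), two
tension-only ligament bands at ±30 mm (posterior complex and anterior
longitudinal ligament, 100 N/mm each — published per-ligament stiffnesses
are tens of N/mm), a rotational spring (6.5·10⁴ N·mm/rad ≈ 1.1 N·m/deg,
residual annulus bending), and a shear spring (300 N/mm). Tension-only
bands matter twice: both engage under swelling distraction (no net couple —
overnight rest produces pure distraction and stretches every fascicle), and
only the posterior band engages in flexion, which is the classic mechanism
by which ligament tension compresses the disk and by which the longer-arm
dorsal muscles can *reduce* IDP by restraining flexion. The spring values
are calibration, not prediction: they were fixed once, from the ligament
literature plus the declared calibration target that standing rotations stay
small (<2°; final per-level relative rotations 0.15°/0.66°/1.98°), before
the acceptance quantities were frozen.

**Time integration.** Staggered quasi-static coupling: each step linearizes
every disk (reaction + finite-difference tangent about the current interface
displacement), solves the 9-DOF equilibrium by damped Newton (FD Jacobian,
step caps, backtracking; relative residual < 1e−8), repeats until the
interface displacements settle (<1e−9 mm), then commits the columns.
Activation state ζ is re-evaluated from the current ε each step. Standing:
60 s ramp in 30 steps. Night rest: adaptive steps growing 1.2× from 1 s to
600 s. Runs are bit-deterministic.

**Headline couplings** (defaults, deterministic; all computed by the
acceptance suite): standing IDP 0.244/0.225/0.215 MPa at L3/L4–L5/S1;
rest-then-standing 0.332/0.345/0.350 MPa (+35.9/+53.4/+62.6%); muscles
reduce standing IDP by 0.4/4.5/6.0%; overnight swelling stretches all 46
fascicles (ε up to 1.3%, peak active force 3.4 N) and activates the L3/L4
multifidus more than the L5/S1 one (cumulative height gain below L3);
without rest the peak per-level muscle resultant develops at L3/L4.

**Known limitation (one check left failing by design).** After prior rest,
the peak per-level resultant should migrate to L5/S1. In a 3D disk the 60-s
standing ramp removes most of the overnight height gain by undrained radial
bulging (axial compression at constant volume); the cranial muscle
pre-stretch dissipates and caudal levels dominate. A laterally confined 1D
column with incompressible constituents cannot change height without fluid
exchange, so on a 60-s timescale the overnight distraction — and hence the
cranial-dominant pre-tension — is locked in. The corresponding test is kept
failing as an honest marker; giving the column a radial compliance mode
(the optional annulus constraint, default off) is the natural extension.

## 6. Degenerate inputs and error behavior

ε ≤ −1 annihilates an element (error). J ≤ 0, non-unit fiber directions,
non-positive stretches, void ratios and dimensions raise typed errors.
Missing insertion/csa entries and one-sided overrides raise config errors
naming the offending fascicle. Non-convergence of the column Picard loop or
the equilibrium Newton raises a diagnostic carrying the residual history.

## 7. Out of scope

Full 3D osteoligamentous FE modeling (facet contact, annulus fiber
reinforcement), hypoelastic ligament laws (lumped into the level springs),
muscle viscoelasticity and explicit force–velocity behavior, motor-unit
recruitment, dynamic tasks, and degenerated-disk parameter sets. Absolute
force/pressure magnitudes of 3D models are treated as directional context,
not targets; the quantitative surface of this package is the overnight
swelling rise and the direction/ordering couplings listed above.
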