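# Methods

## Problem and model

A body segment carries N skin markers whose global trajectories are
measured; the segment itself is rigid, but the markers move relative to the
bone (soft tissue artifact, STA). A bone pose estimator maps the noisy
cluster at each time step to a proper rigid pose. All three estimators here
address the *non-rigid* component of STA; a displacement common to the
whole cluster is indistinguishable from bone motion for any of them.

The cluster is treated as a system of point masses with inertia tensor
I = Σⱼ mⱼ(‖rⱼ‖²𝟙 − rⱼrⱼᵀ). For a rigid cluster the centroidal spectrum of
I is constant in time, which is the invariant the PCT family exploits.

### Coordinate convention for the tensor pipeline

The `inertia_tensor` primitive computes moments about the origin of
whatever frame the coordinates are expressed in. Inside the estimators the
tensor is always taken about the cluster centre (classic PCT: the
mass-weighted CM; PCT-PT: the per-frame centroid, i.e. the global frame is
translated to the cluster centre before the tensor is formed). This is
deliberate: the origin-moment spectrum of a *translating* rigid cluster is
not conserved, so only the centred spectrum can serve as the denoising
target, and only with centring is the noise-free trial an exact fixed point
of the whole pipeline.

## PCT-PT

Per time step, the centred noisy tensor is eigendecomposed (ascending
eigenvalues; column signs fixed by continuity against the previous
accepted basis, seeded by the static calibration) and driven toward the
calibration spectrum λ₀:

1. target offset δλ_C = s·(λ₀ − λ_C), step size s initialized to 1;
2. the symmetric perturbation δI is parameterized by its six unique
   entries k = (k₁₁, k₁₂, k₁₃, k₂₂, k₂₃, k₃₃); each eigenvector contributes
   the row (eₓ², 2eₓe_y, 2eₓe_z, e_y², 2e_ye_z, e_z²) of the 3×6 system
   A·k = δλ, solved by the minimum-norm least-squares solution;
3. first-order eigenvector offsets δeⱼ = Σ_{i≠j}(eᵢᵀδI eⱼ)/(λⱼ−λᵢ)·eᵢ are
   screened: the update is accepted only if |eⱼᵀδeⱼ| < 10⁻⁷ and
   |‖eⱼ+δeⱼ‖ − 1| < 10⁻⁴ for all j (i.e. the step stays inside the linear
   regime); otherwise s and δλ_C are halved, aborting once s < 2⁻¹³;
4. on acceptance λ ← λ + δλ_C, the eigenvector columns are incremented and
   re-orthonormalized by Gram–Schmidt in index order, the tensor rebuilt as
   E·diag(λ)·Eᵀ, and s reset to 1;
5. the loop succeeds when ‖λ₀ − λ_C‖ < 10⁻⁷ with pairwise eigenvector dot
   products below 10⁻⁷, and reports failure (rather than raising) when the
   halving budget or an iteration cap (default 500) is exhausted.
   Near-degenerate spectra (relative adjacent gap < 10⁻⁹) raise instead:
   the eigenvector offsets divide by the gap.

Mass recovery stacks the six unique entries of the denoised tensors over
all N_T steps against the mass-weighted tensor of the measured (centred)
positions — 6·N_T equations in N unknown constant masses — and solves with
Levenberg–Marquardt from unit masses. The system is linear in the masses,
so the constant Jacobian is supplied and convergence is immediate;
negative recovered masses are flagged, not clamped.

The unconstrained CM (weighted mean of the *global* positions with the
recovered masses) is blended toward the centroid with a single per-trial
scalar α = min(1, d_max / max_t‖T_UC − c‖), guaranteeing
‖T_C(t) − c(t)‖ ≤ d_max. The projection ΔT(t) = (T_C − c)ᵀe_F1 onto the
first denoised eigenvector decides the reflection: all-negative keeps T_C,
all-positive reflects about the centroid (T = 2c − T_C), and a genuine sign
change is resolved by the sign of ∫ΔT dt and flagged. Samples with
|ΔT| ≤ 10⁻¹² m count as zero so that the noise-free trial (ΔT ≡ 0 to
rounding) is not spuriously reflected.

Orientation is the mean-centred proper-rotation least-squares (Kabsch) fit
between the calibration and observed clusters — by construction the same
rotation SVD-LS produces, which makes the empirically observed
PCT-PT/SVD-LS orientation identity a structural guarantee of this
implementation. The pose translation maps the calibration centroid onto
the final CM estimate.

## Classic PCT

Per step, the masses minimize (‖λ(m,t)‖ − ‖λ₀‖)² (SLSQP, warm-started from
the previous step) under the gauge Σm = N — the objective is homogeneous
in the total mass, so without the gauge the problem has an exact scale
direction — and m ≥ 10⁻⁶. The pose is (E(t)E₀ᵀ, weighted CM). A step is
flagged discontinuous when the CM jumps by more than 5× the 95th-percentile
frame-to-frame marker displacement, or any principal axis rotates more than
30° between adjacent samples, or the spectrum degenerates, or the
eigenvector basis becomes improper; a configuration is "continuous" only
if every step is valid. The jump thresholds are configuration keys — the
method itself defines no validity rule — and the screen *detects* failures
rather than deriving them.

## Simulation study

Thigh and shank are conical frustums (r₁, r₂, h, θ) = (5.5 cm, 9.5 cm,
25 cm, 60°) and (4 cm, 5.5 cm, 17.5 cm, 60°), local Z inferior–superior
(z = 0 distal), X anterior, Y lateral, radius tapering linearly. Markers
may only be placed in four disjoint quadrants: two azimuthal bands of
extent θ (centred at 0° and 75°) × two height bands (5–45 % and 55–95 % of
h). One marker is drawn uniformly per quadrant; a configuration is
rejected and redrawn unless horizontally adjacent markers are ≥ 30° apart
in azimuth and vertically adjacent markers ≥ 20 % of h apart in height
(both configurable — only "adequate spacing" is prescribed by the
tradition, not the thresholds).

Landmark defaults are stylized surface points chosen so that the
anatomical frame built from them coincides with the segment frame on the
untransformed template: epicondyles/malleoli at ±90° azimuth on the distal
rim, femoral head on the axis 7 cm above the proximal face, greater
trochanter on the proximal lateral rim, fibular head posterolateral
(azimuth 150°) on the proximal rim and tibial tuberosity anteromedial
(azimuth −30°, radius r₂) at 85 % height. The exact coordinates only scale
ALRO/AFOO magnitudes; every algorithmic property is independent of them.

The gait driver is a stylized planar treadmill walk: the hip centre is
fixed, hip angle A_hip·cos(2πφ) (default 20°), knee flexion the sum of two
periodic von-Mises bumps (15° loading-response bump at 15 % cycle, 60°
swing bump at 72 %), 1.0 s cycles, three cycles at 240 Hz, toe-off at 60 %.
Planarity makes the commanded knee profile exactly recoverable from the
generated poses, which the tests exploit as a round-trip oracle.

Synthetic STA: per quadrant and axis, a sum of ≤ 3 harmonics of normalized
gait time with seeded random phases and 1/k-decaying weights, scaled to a
per-axis RMS of 12 mm (thigh) and 5 mm (shank) times a random per-axis
factor in [0.5, 1]. The displacement is expressed in the *segment-local*
frame (skin moves relative to bone) and rotated into the global frame by
the true segment rotation; every marker of a quadrant receives the same
displacement. The amplitudes were chosen to match the field's consistent
finding that thigh STA (order 1–2 cm during walking) substantially exceeds
shank STA. What the generator emulates: continuity, gait-phase locking,
quadrant structure, thigh ≫ shank magnitude. What it does not: stochastic
cycle-to-cycle variability, marker-specific (sub-quadrant) trends,
task/subject dependence, and rigid-body STA components — so passing tests
demonstrate correctness of the estimators under phase-locked non-rigid
STA, not field performance on real skin motion. Measured quadrant profiles
can be substituted via a CSV (`quadrant, percent_cycle, dx, dy, dz`),
averaged per quadrant over contributing markers and periodically
interpolated to the trial time base.

## Evaluation

All metrics compare the ground-truth configuration with the
reconstruction: TRO = ‖T^R − T^r‖ and ALRO per landmark (reported in cm),
eRO per eigenvector as the angle between reference and reconstructed
principal directions (sign-aligned; evaluated in the half-chord
2·arcsin(‖a−b‖/2) form, which is mathematically the clipped-arccos of the
dot product but stays accurate to ~10⁻¹² deg for nearly parallel vectors),
AFOO between anatomical-frame origins, and KAO as
reconstructed-minus-true knee angles. Knee angles use the floating-axis
joint coordinate system, implemented as the intrinsic Y–X′–Z″ decomposition
of the femur-to-tibia relative rotation (flexion about the femoral ML
axis, internal–external about the tibial long axis, ab-adduction about the
floating axis); a gimbal flag marks |AA| → 90°. Gait phases: stance from
heel strike to toe-off, swing from toe-off to the next heel strike,
evaluated on the middle of the three cycles. Summary tables pool
(configuration × time-in-phase) samples; the across-configuration envelope
(std of per-configuration phase means) is exported alongside, and PCT rows
pool only configurations that passed the continuity screen.

## Numerical choices and defaults

| Parameter | Default | Notes |
|---|---|---|
| eigenvalue order | ascending | eRO is reported per index, so the order is part of the contract |
| eigenvector signs | continuity (dot ≥ 0 with reference), else largest component positive | the eRO arccos is sign-sensitive |
| degeneracy tolerance | 10⁻⁹ relative adjacent gap | the perturbation formulas divide by gaps |
| denoise tolerances | 10⁻⁷ (λ and orthogonality), 10⁻⁴ (norm), s ≥ 2⁻¹³ | acceptance/step-halving loop |
| d_max | 0.01 m | CM-to-centroid bound; configurable |
| PCT gauge | Σm = N, m ≥ 10⁻⁶ | removes the mass-scale direction |
| PCT screen | 5× p95 frame step, 30° axis jump | configurable validity thresholds |
| units | metres internally | cm only in reports |

Reduced problem sizes (60 Hz instead of 240 Hz, 20 instead of 100
configurations) are used in the test suite; they preserve every structural
property being tested since all gait quantities are closed-form functions
of the cycle phase.

## Known limitations

* The sign-change branch of the CM reflection uses an integral majority
  rule; per-root segment-wise resolution is not implemented.
* PCT's λ₀ is the unit-mass calibration spectrum; re-optimizing the
  calibration masses is not attempted.
* The gait driver is planar; out-of-plane hip motion would exercise the
  gimbal handling of the knee decomposition, which is flagged but not
  specially resolved.
* C3D input is out of scope; TRC and long-format CSV are supported.
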