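# Methods

This note documents the models behind `protoacoustic`, the provenance of
every default parameter, the numerical choices, and what the package does
*not* capture.

## Dose model

The pristine per-proton depth dose follows the Bragg–Kleeman differential
form D(z) ∝ (R−z)^(1/p−1) with range R = aE^p (a = 0.022 mm·MeV⁻ᵖ,
p = 1.77, the standard water parametrisation; R(100 MeV) = 76.3 mm). Range
straggling is a Gaussian convolution of width σ_R = 1% of R (for 100 MeV,
0.76 mm — consistent with the usual σ_R ≈ 0.012·R^0.935 cm rule). The curve
is normalised so its depth integral equals E·(1 − f_nuc) with a nuclear-loss
fraction f_nuc = 0.10; both σ_R and f_nuc are configuration knobs because
they are not observable from the reproduced study.

**Voxelisation.** (R−z)^(1/p−1) has an integrable singularity at z = R;
sampling it pointwise makes the peak voxel value depend on the grid phase
relative to R and never converges. Deposition therefore uses *exact cell
averages*: the analytic primitive of the pristine curve on a fine internal
grid (σ_R/8 resolution), Gaussian-filtered, then integrated into the
requested cells via its cumulative function. The lateral Gaussian
(σ = 1 mm) is likewise cell-averaged with erf differences. With this scheme
the on-axis near-field amplitude changes by <2% between 1 mm and 0.25 mm
voxels.

A bone layer is modelled as a pure water-equivalent range shift
thickness·(RSP−1) applied through the water-equivalent depth map — no
scatter broadening, since the range shift is the dominant effect for the
monitoring question asked here.

## Thermoacoustic model

Separable source: ε(r,t) = ε(r)·S_cum(t), the standard protoacoustic
assumption (deposition pattern fixed, beam current modulates it). The
retarded-potential solution is discretised as: bin ε dV′/|r−r′| into
retarded-time bins at |r−r′|/c_s (bin width dt ≤ min voxel/c_s, enforced),
convolve with the pulse profile S = dS_cum/dt, apply a second-order central
time difference, scale by α/(4πC_p). A single-voxel source reproduces the
closed-form point solution (α ε dV)/(4πC_p d)·S′(t−d/c) to <1% RMS, and a
multi-voxel grid equals the superposition of point solutions — both are
unit tests.

Medium defaults: c_s = 1500 m/s, C_p = 4180 J/(kg·K), ρ = 1003 kg/m³
(water phantom), α = 3.7·10⁻⁴ K⁻¹ — body-temperature water, because the
application is in vivo; 20 °C water (2.1·10⁻⁴) is a config override.
Amplitude propagation beyond the near field uses
P = P_ref·(d_ref/d)·e^(−α′(d−d_ref)) with α′ = 0.95 Np/m (water at
300 kHz), frequency-independent by construction.

**Pulse profile.** Duration 10 μs. The default shape is a Gaussian with
σ = duration/6, baseline-subtracted so it reaches zero continuously at the
support edges (a hard truncation injects spurious derivative spikes an
order of magnitude above the physical signal). A rectangular profile is
available, but note that its spectrum has nulls at multiples of 1/T
= 100 kHz, which is incompatible with the ~110 kHz central frequency the
reference study reports for its 10 μs pulse — the reason the smooth profile
is the default. Whether the quoted near-field amplitude is the positive
peak or peak-to-peak is unstated in the source; the package reports the
absolute peak.

**Central frequency** is the argmax of the Hann-tapered, mean-removed
amplitude spectrum, zero-padded to ≤1 kHz bin width; −6 dB band edges are
available alongside.

## Skull interface

Fluid→solid plane-wave solution in the normal-impedance form
(Z_in = Z_p cos²2θ_s + Z_s sin²2θ_s, pressure reflection
R = (Z_in−Z_f)/(Z_in+Z_f)), with complex cosines beyond the critical
angles; transmitted power splits between the longitudinal and shear
branches in proportion to the real parts of their impedance terms, so
energy conservation T_p + T_s + R = 1 holds identically below both critical
angles and R → 1 under total internal reflection.

TOA correction: Δt(θ) = (L/cos θ_p)(1/c_fluid − 1/c_long) — the time the
refracted bone segment "saves" relative to the all-fluid path the localiser
assumes; it is *added* to the measured (early) arrivals.

**Parameter provenance.** Skull speed and thickness are not printed in the
reproduced study (it cites external literature). The defaults
c_long = 2000 m/s, L = 6.48 mm are reverse-engineered from two printed
anchors: the normal-incidence correction of 1.08 μs
(L(1/1500 − 1/c_long) = 1.08 μs leaves a one-parameter family) and the
~2 mm uncorrected localization bias of the reference scene, which selects
the family member. Both values sit inside the literature spread for
parietal bone (longitudinal speeds ~1900–3100 m/s, thickness ~4–7 mm).
c_shear = 1400 m/s, ρ = 1900 kg/m³ complete the set; all four are
configurable.

## Reference scene

Sensor positions and source position are the published table values,
verbatim. The skull is a spherical shell least-squares fitted through the
six sensors with the centre constrained to the mean sensor z-plane (centre
≈ (−59.5, 6.6, 172.9) mm, outer radius ≈ 50.7 mm). The unconstrained
algebraic sphere fit puts the centre ~63 mm below the sensor ring; that
geometry makes every source→sensor ray hit the shell at ~55°, beyond the
longitudinal critical angle, i.e. the published longitudinal time
correction could never have applied — so the in-plane fit is the physically
admissible reconstruction. Incidence angles are then 10–20° and per-sensor
corrections 1.14–1.43 μs.

The published sensor x-coordinates are strongly asymmetric as printed and
the array is nearly coplanar in z (2.6 mm spread against ~100 mm baselines)
— the out-of-plane coordinate is poorly conditioned, and `SensorArray`
warns accordingly. The fixture nevertheless ships the values verbatim.

## Full chain

Following the reference study's own two-stage procedure, the *propagated*
signals are emitted not by the whole dose track but by a 2 mm-diameter
sphere at the Bragg peak, rescaled so that its on-axis amplitude 2 mm
beyond the peak matches the full-deposition near-field value (2.86 Pa at
0.5 mm voxels). The near-field reference point is 2 mm beyond the
*analytic* depth-dose maximum (the voxel-quantised maximum would alias the
steep near-field 1/d gradient). A full-track source would also radiate the
pre-peak cylindrical wave, whose low-frequency content drags the 20 mm
spectrum down to ~67 kHz — inconsistent with the published ~110 kHz, which
the sphere source reproduces (~98 kHz).

Sensor traces are ray-propagated: each sensor's trace is the sphere-source
retarded-time solution at the sensor position, advanced in time by the
per-sensor layer delay and scaled by the longitudinal power-transmission
coefficient and e^(−α′d). Arrival times come from normalised
cross-correlation against the 20 mm on-axis template with parabolic
sub-sample refinement; corrections use incidence angles evaluated at the
*planned* target (in this scene identical to the true peak, as in the
reference study where the source position is known to the software).
TDOAs are referenced to sensor 1 and solved by damped Gauss–Newton
(Armijo backtracking, 10⁻⁹ mm step tolerance, ≤100 iterations, multistart
from the skull bounding-box corners and centre on non-convergence).

A *constant* correction cancels exactly in the TDOAs (unit-tested): the
published improvement from ~2 mm to ≤1 mm is only explicable with
per-sensor (angle-dependent) corrections, which is therefore the default
mode; constant mode is retained for demonstration.

Problem sizes: 0.5 mm voxels (≈7·10⁴ cells), 10 ns trace sampling, six
sensors; the whole chain runs in well under a second, and the FDTD
validation grids are ~150×150 cells.

## Piezoelectric design

Radial modes scale as f_rn = λ_n·N_p/d·g(th/d) with λ₁ = 1, λ₂ = 2.60 (the
radial Bessel-root ratio) and a monotone aspect-ratio correction
g(τ) = 1/(1+0.2τ²); anti-resonances follow f_a = f_r/√(1−k²). The coupling
of each radial mode is suppressed when it approaches the thickness mode
f_t = N_t/th (mode veering), modelled as a Lorentzian dip (depth 0.7,
fractional width 0.25). This interaction is what makes k₁/k₂ geometry
dependent: the ratio peaks where the second radial overtone crosses the
thickness mode, th ≈ d·N_t/(λ₂N_p) ≈ 0.54·d. With PIC255-like constants
(N_p = 1420 Hz·m, N_t = 2000 Hz·m, k_p = 0.62) the 110 kHz optimisation
returns (14 mm, 8 mm), adjacent to the published FEM optimum (15 mm, 9 mm);
exact coincidence is not expected from a scaling-law stand-in, and the
feasibility-band + argmax-k₁/k₂ search logic is the part preserved exactly.
Ties break toward smaller diameter, then smaller thickness; the search is
deterministic.

## FDTD validator

Second-order leapfrog for (1/ρc²)p_tt = ∇·((1/ρ)∇p) with harmonic-mean
face densities, CFL bound dt ≤ dx/(c_max√2) (enforced), an exponential
sponge boundary (width 20 cells, strength 0.3), and pressure injection
sources. Two-dimensionality means cylindrical spreading and an algebraic
wake, so the module validates *arrival times and transmission* only —
homogeneous and layered first arrivals agree with the ray model within two
grid cells of travel, and source–receiver reciprocity holds to <1% RMS when
both terminals sit in like material.

## What the defaults do and do not show

Passing tests demonstrate internal consistency of the chain (oracle
equivalence, energy bookkeeping, conservation laws, exact noiseless
recovery) and agreement with the published headline numbers under the
documented stand-ins. They do not validate Monte Carlo dose accuracy,
anatomical skull geometry (true skulls vary in thickness and curvature;
the shell is uniform), frequency-dependent bone absorption, shear-wave
propagation through the layer, transducer electronics, or acoustic noise in
a treatment room. The monotone-degradation test (reconstruction error vs
TOA jitter) indicates how measurement noise would erode the millimetre
accuracy, but no claim is made about the jitter level of real hardware.
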