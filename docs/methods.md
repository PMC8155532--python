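# Methods

`magsim` simulates the neural magnetic fields that an in-vitro mouse
brainstem slice would project onto a planar magnetic sensor lying just below
it.  The modelled system is the auditory pathway from the globular bushy
cells (GBCs) of the ventral cochlear nucleus to the principal cells of the
medial nucleus of the trapezoid body (MNTB), coupled one-to-one through the
calyx of Held.  The pipeline has five stages: synthetic slice construction,
conductance-based cable simulation (with electrical or optogenetic
stimulation), calyceal synaptic transmission, the electromagnetic forward
model, and optothermal heating.

## Synthetic slice

The slice is 350 μm thick with 25 μm inactive layers at both faces (cells
there are damaged by the cutting procedure), leaving a 300 μm active span.
Each of the 300 (optionally 1,250) GBC→MNTB pairs is generated from a seeded
`numpy` Generator:

* the calyx centre is drawn uniformly from the MNTB ellipse (semi-axes
  200/100 μm, centred 400 μm lateral of the midline) × the active z span;
* the axon path is a natural cubic spline (chord-length parameterised,
  arc-length resampled to ≤10 μm segments) through one uniform point per
  predefined 25×25 μm² waypoint box plus the calyx waypoint; the waypoint
  boxes trace the trapezoid-body arc from the VCN across the midline and are
  configuration data — the shipped defaults approximate the anatomical
  course and keep the near-midline stretch flat in y, as the fibre tract
  runs mediolaterally there;
* the whole GBC is translated by the calyx centre's (y, z); the principal
  cell is placed at the calyx centre, rotated about z by a uniform angle in
  [-π/2, π/2]; the calyx half ring and the GBC dendrite get independent
  uniform rotations (dendrites have no preferred orientation in the
  population, which matters for the summed dipole — a fixed orientation
  would add an artificial coherent dipole to the population signal).

GBC morphology follows the published description: 20 μm spherical soma
(represented as a cylinder with length = diameter), 50 μm × 3 μm primary
dendrite with two 50 μm × 2 μm secondary branches, 15 μm tapering hillock
(2.5→1 μm), 1 μm initial segment, and a myelinated axon whose internode
diameter tapers 3→3.3 μm, node diameter 1.5→2 μm (nodes 1 μm long), and
whose internode length stays at 200 μm before shrinking to 40 μm over the
final ~800 μm.  Nine constant internodes are used (total axon ≈ 2.5 mm), so
the soma lands in the VCN region at the end of the waypoint arc.  The last
internode is followed by an 8 μm heminode (nodal membrane), a 5 μm
post-heminode (pure capacitor), and the calyx of Held as a half ring of
13 μm diameter and 2 μm thickness in 8 arc segments.  The MNTB principal
cell has a 20 μm soma, a 50 μm × 3 μm dendrite with two 10 μm terminal
branches, and five 100 μm × 2 μm internodes with 1 μm nodes splined toward
the LSO.

**Calyx membrane area.**  The half-ring skeleton has only ~130 μm² of
cylinder surface, an order of magnitude less membrane than the real
cup-shaped terminal.  A per-label area multiplier (default ×12 for the
calyx) folds the missing membrane into the ring compartments: capacitance
and every conductance scale with it while the current-path geometry — and
therefore the field forward model — is untouched.  Without it, the terminal
cannot host enough light-gated or Ca conductance to be more excitable than
the GBC soma, contrary to the observed threshold ordering.

## Membrane model

Channel kinetics use the published type-II VCN bushy-cell complement
(fast inactivating Na, low- and high-threshold K, Ih, leak), expressed at
22 °C and Q10-scaled to the simulation temperature of 34 °C (Q10 = 3 for
rates, 2 for conductances).  The exact density tables of the source model
are not published; shipped densities are calibrated to the printed
behavioural anchors and are all configuration:

* nodes of Ranvier / heminode: Na 3.4, KLT 0.04, KHT 1.0, leak 0.004 S/cm²;
  the strong nodal KHT keeps the nodal depolarization near the 0.1 ms scale;
* axial resistivity 340 Ω·cm with a thin lumped myelin sheath
  (0.009 μF/cm², 10⁻⁵ S/cm²; single-cable representation of the passive
  sheath, no periaxonal space).  Together these set the conduction velocity
  (7.6 m/s, within the published 5-10 m/s) *and* the axial current
  amplitude that determines the peak magnetic field (~120 pT for 300
  synchronized cells).  The resistivity sits at the high end of published
  axoplasm values; it is the one free scale that reconciles both anchors
  under this myelin model;
* MNTB principal soma: a Na variant with the activation curve shifted
  -10 mV plus strong KLT (0.2 S/cm²), so that brief 0.5 nA / 0.25 ms
  injections fire reliably at 100 Hz while sustained input produces a
  single onset spike.  200 Hz following is 4/5 with these defaults — a known
  limitation;
* calyx: KHT, Ih, leak and a fast P/Q-type Ca conductance (reversal +45 mV).

The branched cable equation is integrated with a Crank-Nicolson θ-method on
a Hines-ordered tree solve; gates advance by exponential Euler, staggered
half a step from the voltage grid (measured convergence is second order).
The internal step is 5 μs and all outputs are decimated to 25 μs.  All
cells of one type share an identical one-dimensional electrical structure
(paths only change the 3-D embedding), so whole populations integrate as
one vectorized solve with per-cell stimulus columns; results are invariant
to cell order.

## Synapse

Release: 500 independent zones with at most one releasable vesicle.  An AP
triggers fast (1 ms) and slow (2 ms) calcium transients; release probability
is the product of a fast-gate term (0.5) and a slow gate that increments by
0.35 per AP and decays with τ = 15 ms, giving paired-pulse facilitation;
empty zones refill through background (0.002 ms⁻¹) plus residual-calcium
(0.05 ms⁻¹ for 2 ms) replenishment, producing depression during sustained
trains.  An extracellular-Ca scale factor multiplies the gate amplitudes
(mechanism present, deliberately untuned).  Deterministic (expected-value)
release is the default; a seeded binomial mode agrees with it in mean.

Receptors: a 6-state AMPA scheme (C0-C1-C2, fast/slow open, desensitized),
one patch per released vesicle, driven by a 1 ms transmitter pulse; patches
from different release events are treated as independent (re-release of the
same zone within the desensitization recovery time is rare).  The quantal
conductance (0.26 nS) and rates are calibrated so a single AP yields an
EPSC of ~1.2 nA at a -70 mV holding potential with a calyx-AP-to-EPSC-peak
delay of ~0.64 ms, facilitation at 5 ms intervals, then train depression.
Receptors sit on the principal soma (92%) and the first axonal compartment.

## Optogenetics

The ChR2 photocycle is the standard four-state scheme (C1, O1, O2, C2) with
light-dependent activation rates Ka_i = ε_i φ u(t), where φ is the photon
flux per channel (irradiance × 1.2·10⁻⁸ μm² cross-section / photon energy
at 473 nm) and u(t) is the activation memory (τ rise during light,
exponential decay after light-off, reproducing the printed activation
form and the biexponential tail).  The current is
I = (V−E)·g₁ρ·(O1+γO2)·(1−e^(−U/U₀))/(U/U₁) with γ = 0.05, U₀ = 40 mV,
U₁ = 15 mV, ρ = 1.3·10¹⁰ channels/cm².  With ρ printed, the single-channel
conductance g₁ is the calibration constant: 0.55 pS reproduces the calyx
rheobase (~23 mW/mm² against the printed ~24) with quantum efficiencies
0.25/0.075, τ = 2.0 ms, and closing rates Kd1 = 0.13, Kd2 = 0.025 ms⁻¹.
The calyx chronaxie comes out at 1.6-1.7 ms against the printed ~2.0 — the
strength-duration knee cannot be pushed further right without slowing the
channel closing, which produces an unphysical standing-current tail (see
Limitations).

Light transport offers the Kubelka-Munk closed form
T = G·C·M (source profile × geometric spread × two-flux attenuation, with
b = √(a²−1), the standard hyperbolic solution) and a Monte-Carlo
photon-packet walk (Henyey-Greenstein scattering, absorption-weighted voxel
deposition, roulette termination, exact weight accounting).  The generic
tissue defaults are gray matter at 473 nm (μs = 10.3, μa = 0.125 mm⁻¹,
g = 0.88); the *slice experiments* default to white-matter-like optics
(μs = 80, μa = 0.3 mm⁻¹) because the light path to the calyces crosses the
heavily myelinated trapezoid body — with gray-matter attenuation nearly
every calyx in the MNTB ellipse is suprathreshold at 1 W/mm² and the
activation fraction is ~97%, far from the printed ~19%.  MC predicts higher
near-probe irradiance than KM (the ballistic regime), so MC feeds the
heating model as the worst case while KM drives the excitation runs.

ChR2 expression in the slice covers the PV⁺ somatodendritic membrane and
the calyx terminal; nodal membrane is excluded (the nodal scaffold excludes
most membrane proteins, and nodal illumination cannot trigger APs in any
case — the threshold search reports no spike even above 10 W/mm²).

## Field forward model

Axial currents (between compartment midpoints) are the magnetic sources:
exact finite-segment Biot-Savart, superposed over all segments of all cells
and evaluated on the 50×25 sensor grid (2×1 mm², 40 μm pitch) 25 μm below
the slice.  Transmembrane currents are the electric sources:
φ = Σ I_m/(4πσr) with σ = 0.5 S/m (ACSF-perfused slice; this value also
sets the extracellular stimulation strength and was calibrated against the
printed 82% antidromic activation at 100 μA).  A volume-conductor scaling
factor approximating slab/anisotropy/bath corrections is exposed and
defaults to 1.  The equivalent current dipole is Q(t) = Σ I_k L⃗_k in
nA·mm.  Field maps are evaluated at the frame where the grid maximum of
max(|By|,|Bz|) peaks, chosen among the local maxima of |Q(t)| (the
travelling pathway wave and the delayed MNTB response produce separate
dipole events; evaluating only the global |Q| peak would make the selection
sensitive to which event is marginally larger).

## Heating

The simplified Pennes equation (no perfusion — appropriate for a slice)
is solved by forward Euler with the 7-point Laplacian at Δx = 0.03-0.06 mm,
Δt bounded by Δx²ρc/(6k) (≈1.0 ms at the printed constants and
Δx = 0.03 mm), Dirichlet ΔT = 0 boundaries ≥1 mm beyond the illuminated
volume, and the MC absorbed-power map as source.  Pulsed protocols gate the
source with the exact per-step on-fraction; for 3 ms pulses the solver is
run with Δt = 1 ms so the within-pulse temperature ripple is resolved.
Continuous 1 W/mm² illumination saturates by ~10 s at ~2.6 °C (printed
range 2.5-3.5); 3 ms / 20 Hz pulsing reduces heating by an order of
magnitude, and heating grows proportionally with repetition rate.

## Problem sizes

The shipped analyses use the 300-cell slice at 25 μs output resolution
(2.2 ms windows for electrical, 8 ms for optical protocols), 1.5-4·10⁵
Monte-Carlo photon packets, and 50-100³ thermal grids integrated to 12 s.
These sizes reproduce the headline quantities while keeping a full pipeline
run in minutes on one CPU; cell number, grid sizes, photon counts and
durations are all parameters.

## What the synthetic slice does and does not capture

The generator reproduces the *statistical* geometry of the pathway (cell
counts, calyx placement, path arcs, taper) but not reconstructed anatomy:
real axons fasciculate, deviate in z, and vary in caliber; real calyces are
cups with swellings rather than rings; GBC somata receive converging
endbulb inputs that are not modelled.  Passing tests therefore demonstrate
the forward physics and the population logic under the stated statistical
conditions, not fidelity to any individual slice.

## Known limitations

* With one global ChR2 conductance density the three printed rheobases
  cannot be met simultaneously; defaults privilege the calyx (23.8 vs
  ~24 mW/mm²), leaving the GBC soma high (~490 vs ~140) and the MNTB soma
  high (~5.7 vs ~1).  The printed *ordering* MNTB < calyx < GBC soma holds.
* Near the optical threshold, spike latency grows logarithmically, so cells
  activated near threshold fire late and dispersed: at 1 W/mm² the mean
  firing time is ~3.3 ms (printed 2.18 ± 0.37) and the population ECD peak
  is dominated by the sustained subthreshold calyx photocurrent rather than
  the AP wave (peak at ~5.6 ms versus the printed 1.88 ms; at 4 W/mm² the
  AP wave dominates and the ECD peaks at ~1.7 ms, close to the printed
  value).  Reproducing the printed tight latency distribution together with
  the threshold anchors was not possible with any four-state parameter set
  we explored; the tension is documented rather than hidden.
* The MNTB 200 Hz following is 4/5; the calyx AP is a partial invasion
  (peak ~-10 mV) that reliably crosses the release-detection threshold.
* The pulsed 4 W/mm² / 40 Hz heating peak computes to ~1.35 °C against the
  printed ~2 °C; the discrepancy is consistent with the printed value being
  an upper worst case ("below 2 °C" is the paper-level claim).
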