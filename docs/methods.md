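# Methods

This note records the models, numerical choices and their rationale, what
the synthetic scenarios do and do not emulate, and the package's known
limitations. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Membrane kinetics

Cellular electrophysiology is the Courtemanche–Ramírez–Nattel (CRN) human
atrial model: 21 state variables (V_m, 15 gates, Na⁺/K⁺/Ca²⁺
concentrations, SR Ca²⁺ compartments), with every constant collected in
`crn_constants.py`. Regional heterogeneity enters purely through
dimensionless multipliers on maximal conductances: g_to, g_CaL and g_Kr
define the nine regional variants (the RA/PM row is the unmodified
baseline), and chronic-AF (cAF) remodeling multiplies g_to, g_CaL, g_K1,
g_Kur and g_Ks on top — with distinct right-atrial and left-atrial
profiles, applied by region family. Composition is multiplicative because
remodeling scales whatever channel density a region already has.

**Integration.** Rush–Larsen exponential updates for all gating variables
(exact for frozen rates, unconditionally stable for gates) and forward
Euler for V_m and concentrations; dt = 0.01 ms for single cells and the
conduction-velocity strand, 0.02 ms for the 2-D scenario (halving dt moves
APD₉₅ by < 1 ms, see `test_apd_dt_convergence`).

**Pacing stimulus.** Single-cell APD characterization uses the model's
native pacing pulse, 2 nA over the 100 pF cell = 20 pA/pF for 2 ms.
Stronger pulses excite just as reliably but keep charging the membrane
through the sodium upstroke, pushing the AP peak from its intrinsic
≈ +25 mV to ≈ +36 mV. Because APD thresholds are referenced to the AP
amplitude, and the late repolarization tail is shallow (≈ 0.14 mV/ms near
95% repolarization), that peak inflation alone shortens measured APD₉₅ by
8–15 ms. Tissue pacing uses 28 pA/pF: a stimulated patch must also charge
its downstream neighbors, and the APD-measurement concern does not apply
there.

**APD measurement.** On the last beat of the train, from the time of
maximal dV/dt to the downward crossing of
V_rest + (1 − fraction)·(V_peak − V_rest), with V_rest taken just before
the final stimulus and the crossing linearly interpolated. Per-beat rest
makes the measurement stable under diastolic drift. One caveat the tests
document: CRN intracellular Na⁺ equilibrates over many minutes, so "one
minute of pacing" is only quasi-steady — a second minute still shifts
APD₉₅ by ~3.5 ms. All APD tables in the package specify the one-minute
protocol, not a true limit cycle.

## Tissue model

Monodomain reaction–diffusion, C_m ∂V_m/∂t = ∇·(D∇V_m) − I_ion − I_stim,
with D the equivalent diffusivity in mm²/ms (conductivity over
surface-to-volume ratio and C_m, times λ/(1+λ) under equal anisotropy
ratios; λ defaults to 1). Domains are regular grids — sheets, annuli
(sheets with non-conducting holes standing in for venous/valvar orifices),
cylinders (periodic in x) and 1-D strands — with per-node region labels
and axis-aligned anisotropy. Diffusion uses a face-weighted 5-point
stencil with harmonic-mean face diffusivities; a missing link (boundary or
obstacle) simply carries no flux, which makes the no-flux condition exact
on the stencil and the discrete source field conservative (total source
over any frame sums to zero to round-off). Operator splitting is Godunov
(reaction then diffusion); the reaction step is table-accelerated: every
purely voltage-dependent quantity is pre-tabulated on a 0.02 mV grid and
linearly interpolated, and reversal potentials are refreshed every 16
steps (concentrations drift on a seconds scale). The tabulated tissue path
and the direct single-cell path agree to < 1 mV on a paced beat
(`test_reaction_only_limit_matches_single_cell`).

**Calibration.** The baseline diffusivity 0.1 mm²/ms gives a planar CV of
≈ 44 cm/s at dx = 0.3 mm for the control membrane. Absolute CV is a
documented default, not an anchored quantity: the explicit stencil
under-resolves the stiff CRN upstroke at 300 µm and biases CV low by
≈ 10% (measured 44.3 / 49.6 / 50.9 cm/s at dx = 0.3 / 0.15 / 0.1 mm;
convergent from below, with the 150 → 100 µm step < 3%). What *is*
anchored is the condition ratio: cAF remodeling plus the 15% gap-junction
conductivity reduction slows CV by ≈ 17.6% relative to control on the
same grid, and the identical discretization in both arms makes the ratio
insensitive to the resolution bias.

## Forward electrograms

Under equal anisotropy ratios the extracellular potential obeys a Poisson
equation with source −1/(1+λ)·∇·(D∇V_m). The bounded heterogeneous torso
of a full forward model is replaced by an infinite homogeneous conductor
(σ_b = 1 S/m), so unipolar EGMs are free-space Green's-function sums over
per-node monopole sources (node area × 0.75 mm wall thickness, one
quadrature point per node; first-order). The divergence reuses the
diffusion stencil, keeping sources discretely consistent with propagation.
Distances below dx/2 are clamped to regularize the kernel at contact.
Consequences, verified in tests: exact superposition under source masking,
1/r monopole and 1/r² dipole decay, V_rms ordering by electrode–tissue
distance. Absolute amplitudes depend on the conductor model and are not
interpreted; all EGM-level claims in the package are orderings or ratios.

## Phase mapping

EGMs (and −V_m for the tissue reference, so activation carries the same
phase signature in both) are band-pass filtered with a zero-phase
(forward–backward) 4th-order Butterworth — no group delay, so activation
timing is preserved — then converted to instantaneous phase via the
frequency-domain analytic signal, θ = atan2(HT[x], x) ∈ (−π, π]. The
first and last 500 ms are trimmed against edge artifacts. The default
band is 7–10 Hz; the shipped rotor scenario runs at 6.9 Hz, so its
analyses use 5–9 Hz (the band is an explicit configuration knob tied to
the rhythm under study).

The chart pipeline order is interpolate-EGMs-first, then filter + Hilbert
per grid point. Since filtering, the Hilbert transform and barycentric
interpolation are all linear, the implementation computes analytic
signals at the 64 electrodes and interpolates those — algebraically
identical (asserted to 1e-8 rad in
`test_interpolate_then_transform_equals_transform_then_interpolate`) and
~900× lighter in memory at the 57,600-point grid.

## Phase singularities

Per mesh element (grid quads; chart quads including the periodic seam),
the topological charge is the sum of successive phase differences along
the oriented boundary, each wrapped to (−π, π]. That sum is an exact
multiple of 2π, so detection is integer-valued with no tolerance to tune;
elements with winding ±2π are PSs. Detections are linked greedily
(same-charge nearest neighbor, link radius 6 mm, ≤ 2-frame gaps), and
rotation counts come from the unwrapped phase of four probe channels on a
3 mm ring around the trajectory — robust to EGM morphology because no
activation detection is involved. Tracks with ≥ 1 full rotation count as
rotors. A reentry circulating a non-conducting orifice carries its charge
*inside* the hole where no element can see it; the ground-truth stage
recovers it as the phase winding along a probe ring just outside the rim
and pins the track at the hole center.

## Basket catheter and projection

The basket is a sphere (default 31 mm) with electrodes at equal arc
spacing along meridian splines, symmetric about the equator; the 8×8 /
4.8 mm layout reproduces the characteristic adjacent-spline distances
(11.7 mm at the equator, 5.4 mm at the outer rings). Density variants
(4×6, 16×16) keep the same latitude span with rescaled spacing. The 2-D
projection is a periodic (longitude × arc-latitude) chart, 240 × 240 =
57,600 points by default, strictly between the outer electrode rings (the
pole caps are not interpolated); interpolation is barycentric-linear on a
fixed-diagonal triangulation of the electrode lattice, exact at electrode
sites and constant-preserving. Chart x-distances overestimate
longitudinal separations toward the poles; 3-D statistics always go
through the chart-to-sphere map. Tracks are not stitched across the
periodic seam (a rare fragmentation, not a correctness issue).

## Classification

A basket track is TRUE_ROTOR if its chart position, projected through the
basket center onto the tissue plane, stays within 10 mm (median over the
overlap) of a ground-truth PS track. Otherwise the surrounding-electrode
activation sequence decides: per cycle, activation times (steepest
negative EGM deflection) of the 4 lattice electrodes around the PS are
tested for circular monotonicity — the activation order must be a
rotation of the geometric order, either direction. For 4 electrodes, 8 of
24 orderings qualify (chance 1/3, enumerated in the tests). Sequential
score ≥ 0.8 ⇒ IMPS (far-field phantom); below ⇒ FIPS (interpolation
phantom); fewer than 3 active surrounding electrodes ⇒ FIPS, flagged.
Both thresholds are configuration knobs; a sensitivity test confirms
TRUE_ROTOR counts are monotone in the match threshold. For trajectory-
distance statistics the "detected trajectory" is the matched rotor when
one exists, else the placement's longest-lived detection — the candidate
an operator would act on.

## The shipped scenario

`make_standard_scenario` is a 50 × 50 mm chronic-AF sheet (dx = 0.5 mm,
base diffusivity 0.14 mm²/ms × 0.85 for cAF gap-junction remodeling) with
one 6 mm-radius orifice hosting a sustained reentry, plus an ectopic
focus pacing at 110 ms cycle length in the opposite corner — a two-source
regime whose wavefronts persistently collide. The reentry is initiated by
painting one fast-rate limit cycle of the cAF cell around the orifice
(phase-distribution initialization, deterministic, no S1–S2 timing
search) and runs at 144 ms (≈ 6.9 Hz), stable for the full 6 s and
unperturbed by the pacing train. Run time is about 5 minutes on one CPU.

The rotor is anatomically anchored by design: at this desk scale (slowed
CV, 0.5 mm grid) the cAF membrane cannot sustain a *free* spiral tip —
cross-field S1–S2 and pinwheel initiations both end in tip contraction —
whereas orifice-anchored circulation is robust, and a multi-electrode map
cannot (and need not) distinguish the two; phase maps of anatomical
reentry show the same winding, and its PS is a legitimate detection
target. Basket placements put the pole axis parallel to the sheet: a
pole-aligned basket directly over the rotor sees the rotation at every
latitude and the chart PS position becomes degenerate.

What the scenario does *not* emulate: 3-D wall thickness and scroll-wave
filaments, fiber anisotropy, realistic atrial geometry wrapping around
the basket (a consequence: far placements here lose the rotor entirely
rather than detecting it at reduced rates), rotor meander (the PS is
pinned at the orifice), and torso-mediated amplitude scaling. Passing
tests therefore demonstrate the artifact *mechanisms* — distance
degradation, far-field IMPS, interpolation FIPS and their density
dependence — not clinical detection percentages.

The aliasing fixture is fully analytic: a traveling wave along the
splines whose local wavelength (9.6 mm nominal, ±40% modulated around the
circumference) is under-sampled by the 4×6 and 8×8 layouts but resolved
by 16×16. Where adjacent-ring phase offsets exceed π, linear
interpolation of the oscillating EGMs produces amplitude nulls and PS
pairs — the FIPS mechanism in its purest form — while the underlying
continuous field provably contains no singularity.

## Reproducibility

All generators are deterministic; random quantities in tests use fixed
seeds. `scripts/acceptance.py --seed N --out f.json` recomputes the
single-cell APD tables (nine regions × three protocols, one minute of
pacing each), the regional APD₉₀ dispersions, and the CV-remodeling
ratio, from scratch at run time; the seed only feeds numpy for interface
uniformity.

## Known limitations

- Axis-aligned anisotropy only; no fiber fields.
- First-order monopole quadrature for EGMs; no bounded-torso correction.
- Explicit diffusion stepping (CFL-bound); no implicit option.
- Chart-seam track fragmentation (see above).
- The activation-sequence score needs ≥ 3 active surrounding electrodes;
  sparse or silent neighborhoods default to FIPS with a flag.
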