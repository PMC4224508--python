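# Model and methods

`nodalsim` simulates the electrophysiology of the right-atrial conduction
system — sinoatrial node (SAN), atrial working myocardium, and the
atrioventricular-node (AVN) pathways — at desk scale, with two engines: a
monodomain reaction–diffusion model built on modified FitzHugh–Nagumo
kinetics, and a three-state cellular automaton.  This note records the
model equations, the calibration of the constants that the published
parameter table does not fix, the numerical choices, and the known
limitations.

## Reaction kinetics

All excitable tissues share the cubic excitation non-linearity of the
Rogers–McCulloch variant of the FitzHugh–Nagumo model, in normalized
voltage (u = 0 rest, u = 1 overshoot; time in ms):

**Working myocardium, inferior nodal extension (INE), penetrating bundle
(non-pacemaking form)**

    du/dt = c1 u (u − α)(1 − u) − c2 u v + ∇·(D ∇u)
    dv/dt = b [1 + ρ σ(u) v/(v + 0.1)] (d u − v)

The recovery gain acts on the excitation variable (v relaxes toward d·u).
This placement is forced by the published parameter columns: with the
alternative convention (v → u/d) the atrial column has a stable depolarized
fixed point for every threshold that still supports propagation — the cell
could never repolarize.  With the convention used here the atrial column
reproduces the published strand APD almost exactly with no tuning beyond α.

σ(u) is a logistic switch (centre 0.3, width 0.05) and ρ = 3 a single
global constant: the recovery rate accelerates at sub-threshold voltage in
proportion to the recovery load v (an Aliev–Panfilov-style state-dependent
time scale).  During the plateau (u high) and at the wave foot (v ≈ 0) the
rate is the plain b, so action-potential duration and conduction velocity
are untouched; after repolarization the elevated v decays ~4× faster, which
brings the refractory periods into the measured range (without it the
atrial refractory period is ~50% too long).

**Sinoatrial node (pacemaking form)**

    du/dt = c1 u (u − α)(1 − u) − c2 v + ∇·(D ∇u)
    dv/dt = b [d (u − q) − v]

Linear recovery coupling with an offset recovery nullcline.  The offset
q > 0 moves the unique equilibrium onto the unstable middle branch of the
cubic nullcline, making every isolated element a relaxation oscillator:
hyperpolarized maximum diastolic potential (u ≈ −0.2), slow diastolic
depolarization, regenerative upstroke, long dome-shaped action potential.
A simple negative threshold shift cannot produce pacemaking here: for the
published SAN column the origin-anchored recovery nullcline always
intersects the repolarized or depolarized branch at a stable fixed point
(the required inequality reduces to (α+1)² < 0).

**Passive block zone**

    du/dt = −u / Rb + ∇·(D ∇u),   Rb = 0.5

No recovery variable and no regenerative term; the zone loads its
neighbours diffusively and dissipates any depolarization, which suffices
to block propagation (verified by the strand-interposition test).

**SAN periphery.**  A border band of the SAN (4 elements ≈ 0.24 mm wide)
grades node into atrium.  c1 is blended linearly with the lattice distance
to the nearest atrial voxel, from the SAN core value (band interior) to
the atrial value (atrial edge).  The band uses the non-pacemaking form
with the atrial column for its remaining constants so that it joins the
atrial wall smoothly; blending c1 inside the pacemaking form instead
creates a stable depolarized state once c1 exceeds ≈1.4 — a permanently
depolarized collar — so that variant is excluded.

**Voltage scale.**  Simulations run in normalized u; for display the
affine map Vm = Vr + u (Vos − Vr) with Vr = −80 mV, Vos = +20 mV is
provided.  It affects no dynamics.

## Parameters

The five published columns (D, c1, c2, b, d) are shipped verbatim in
`nodalsim/data/default_params.yaml`.  The remaining constants were fixed
once by calibration on the 50×5×5-element strand protocol
(`scripts/calibrate.py`) and then frozen:

| constant | value | role | calibration anchor |
|---|---|---|---|
| diffusion unit | 0.02343 mm²/ms per table unit | absolute scale of D | atrial strand CV = 0.5333 m/s |
| ρ (recovery boost) | 3.0 (global) | post-repolarization recovery | atrial strand RP ≈ 82 ms |
| α atrial | 0.235 | threshold | atrial APD90 = 75.05 ms |
| α INE | 0.148 | threshold | INE CV = 0.0949 m/s |
| α PB | 0.105 | threshold | PB APD90 = 118.07 ms |
| α SAN | 0.18, q = 0.51 | threshold + nullcline offset | cycle length 330 ms and paced APD90 ≈ 185 ms |

One scalar per tissue cannot fit conduction velocity, APD, refractory
period and upstroke at once, so the remaining strand quantities are a
genuine validation surface.  The calibrated model reproduces, within ±10%:
all four conduction velocities except the penetrating bundle's, all APDs
except the INE's, the SAN/atrial/PB refractory periods, the 330 ms cycle
length (±5%) and the √10 conduction-velocity anisotropy.  Known,
documented misses of this model family:

* **INE APD90** (~20 ms vs 93.7 ms).  With the INE column (c1 = 1.45,
  c2 = 1, b = 0.013, d = 2.5) no member of this kinetics family with a
  stable resting state can hold a plateau longer than ~30 ms: the
  recovery level needed to end the plateau is far below the attainable
  recovery drive, so it is crossed within tens of ms for every admissible
  threshold.
* **PB conduction velocity** (~0.21 vs 0.1413 m/s).  α_PB is anchored to
  the APD; anchoring it to CV instead would put the APD 33% low.  The
  trade-off is one-dimensional and cannot be split within ±10%.

**Anisotropy.**  SAN, crista terminalis, roof bundle and main branch carry
per-voxel unit fibre directions.  The tensor is D = D_t I + (D_l − D_t)
f fᵀ with D_l/D_t = 10 and the geometric mean preserved
(D_l = D√10, D_t = D/√10), giving a conduction-velocity anisotropy of
√10 ≈ 3.2.  Bundle strands are generated with fibres along the strand
axis; the SAN strand is generated with *transverse* fibres, because the
slow nodal velocity that the strand protocol characterizes is the
centre-to-crista (cross-fibre) direction; with the calibrated diffusion
unit this reproduces the published nodal strand velocity within ~4%.

**SAN strand protocol.**  A strand of pacemaking tissue has no resting
state, so paced measurements (CV, APD, S1–S2 refractory period) start
from a holding state: the isolated-cell limit cycle is sampled half-way
through diastole (maximum diastolic potential → next takeoff; fraction
0.5, configurable).  The S1 wave then propagates into partially recovered
tissue, as it does in the intact node.

## Numerics

Finite-volume face fluxes on the voxel lattice (dx = 60 µm), with
face-averaged tensor components and mixed-derivative terms from averaged
tangential gradients; face fluxes are zeroed across non-tissue faces,
which enforces no-flux boundaries and makes total u exactly conserved when
reactions are off (asserted to 10⁻⁸ over 1000 steps in the suite).  Time
stepping is forward Euler with dt chosen automatically from the tensor
field (safety factor 0.85 on the explicit bound, further reduced by the
reaction rate); halving dt changes strand CV by <1%.  An instability guard
aborts with the offending dt when |u| exceeds 10.  Activation is an upward
crossing of u = 0.5 recorded in-kernel; trace measurements interpolate
linearly between samples.

## Cellular automaton

Three states (resting / excited / refractory) with an excitation counter:
a resting node gains (gain × number of excited neighbours) per step and
fires at threshold θ; it excites neighbours for E steps, is refractory for
R steps, then rests (counters reset on firing and on re-entering rest).
Updates are synchronous; the implementation is asserted state-identical to
an independently coded brute-force reference on random lattices.

Conduction velocity is controlled by the firing delay (θ at gain 1) and
the neighbourhood reach (Euclidean radius in nodes); `ca_tune_cv` searches
these integers against measured 1-D fibre velocity and errors with the
achievable range when a target is outside it.  The shipped per-tissue
constants (dt = 1 ms) give 1-D fibre velocities of 0.43 (atrial), 0.114
(INE), 0.158 (transitional zone) and 0.105 m/s (penetrating bundle), and
S1–S2 fibre refractory periods of 81 / 94 / 134 / 154 ms.  The INE
velocity sits at the upper end of its published range so that the
echo-beat circuit closes within the slow pathway's refractory period
(single echo, below).

**Waiting fronts.**  A blocked wavefront keeps its source nodes excited
for their full excited period E, so tissue recovering while the stalled
front is still excited fires upon recovery.  Entrance-block thresholds in
composite preparations therefore sit up to E (of the proximal tissue)
below the isolated-fibre S1–S2 refractory period.  This is intrinsic to
threshold-accumulation automata (the depolarized-but-blocked front is
still a current source) and is accounted for explicitly in the echo-beat
analysis.

## Scenarios

**Idealized right atrium** (2D sheet, default 200×150 voxels = 12×9 mm;
3D variant adds the supra-atrial bundles): SAN ellipse abutting a
fast-conducting crista terminalis with longitudinal fibres, a passive
block zone interposed over the node's full cranio-caudal extent on the
septal side, and an insulated INE→penetrating-bundle chain entered
upstream at the crista end and downstream at the compact-node junction
from the septum.  The node's radii have a generator floor (≈1×2 mm):
smaller nodes are electrotonically silenced by the surrounding sheet.
Both sheet scenarios (sinus and AF) run at a documented desk-scale
coupling of 1/16 of the calibrated diffusion unit: at full coupling the
idealized node, which lacks the exit architecture of the real one
(transitional interdigitations, insulating connective tissue, a crista
border), can fire but cannot drive the sheet.  At the desk-scale coupling
the loaded node paces the sheet at ~285 ms (the resting sheet sits above
the nodal diastolic potential and accelerates diastole slightly).  During
sinus rhythm the septum activates only around the block zone (later than
the crista), the AVN is entered from both ends — the septal entry
directly at the junction — and the two nodal wavefronts collide inside
the slow pathway: the qualitative activation sequence of the full
anatomy.  `run_sinus` discards the first settling beats and returns
activation maps of two steady cycles.

**AF-like reentry.**  The calibrated atrial wavelength (CV × RP ≈ 45 mm)
exceeds any desk-scale sheet, so the arrhythmia scenario runs with the
diffusion unit scaled down by 16 (wavelength ≈ 11 mm), which preserves
all velocity ratios and every refractory period.  S1 is the spontaneous
sinus beat; S2 is a planar premature stimulus along the superior-caval
margin at 170 ms (midpoint of the vulnerable window found by scanning;
the window spans roughly 130–190 ms).  The resulting reentry drives the
atrium at ~60–70 ms cycles; the SAN centre follows only every 3rd–4th
beat (entrance block, its refractory period being ~4× the atrial cycle)
and the distal penetrating bundle at an integer fraction of the atrial
rate (AVN filtering).  The absolute atrial frequency is a property of the
scaled desk-scale preparation and is not treated as a reproduction of the
full-anatomy value.

**Ventricular echo beat** (cellular automaton on the dual-pathway ring).
S1 then S2 are delivered at the penetrating-bundle stub.  The bundle stub
is given a fast-recovering parameter set (E + R = 55 steps) — the
premature ventricular-side activation arises distal to the node, where
recovery is quicker than either nodal pathway — while both limbs keep the
published constants.  Within the vulnerable window the premature beat is
blocked at the fast-pathway (transitional-zone) entrance, conducts
retrogradely up the slow pathway, re-enters the fast pathway from the
atrium and re-activates the bundle anterogradely: a single echo, after
which the next circuit finds the slow pathway refractory (the loop time,
~75 ms, is kept below the slow-pathway refractory period by the slow-limb
geometry).  The echo window is one contiguous coupling-interval band
bounded by the two limbs' entrance-block thresholds; each threshold sits
the waiting-front offset (≈ E of the bundle) below the corresponding
isolated-fibre refractory period, as measured and asserted in the suite.

## Geometry container format

Geometries are stored as compressed NumPy archives (`.npz`) with an
embedded JSON header (array ``header``, UTF-8 bytes) carrying: ``format``
("nodalsim-geometry"), ``version``, ``dims`` (nx, ny, nz), ``dx_um``,
``code_table`` (code → tissue name), ``probes`` (name → voxel index
triple), ``meta`` and ``has_fibers``.  The payload arrays are ``labels``
(int8, shape dims) and, when fibres are present, ``fiber_l`` / ``fiber_m``
/ ``fiber_n`` (float32 direction cosines).  The loader validates codes
against the table and reports voxel counts per code.  A plain-text
importer (`read_s2_ascii`) accepts whitespace-separated integer label
matrices in the supplementary coding (x fastest, z slowest); it is
optional and never required by the test suite.  Snapshot output is an
``.npz`` of frames with a JSON sidecar (dims, dx, dt, frame times), and
fields can be exported as legacy-ASCII VTK structured points for
visualization.

## What the synthetic geometries do and do not show

The strand, slab, sheet and ring are idealized constructs: uniform voxel
size, sharp tissue boundaries, axis-aligned or constant fibre fields, no
wall thickness gradients, no vena-caval orifices, and a block zone whose
real counterpart was drawn from activation maps rather than histology.
Passing the scenario tests shows that the model machinery produces the
classical nodal behaviours (pacemaker hierarchy, detour conduction, dual
AVN entry, entrance block, rate filtering, echo reentry) under controlled
conditions; it does not validate conduction on the real atrial anatomy,
and the AF frequencies reported by full-anatomy simulations are outside
the scope of these reduced geometries.

## Limitations

* Caricature kinetics: no ionic currents, no rate-dependent APD
  restitution beyond what the FitzHugh–Nagumo forms produce.
* The INE action-potential duration and the penetrating-bundle conduction
  velocity cannot be fit simultaneously with their other strand
  quantities in this kinetics family (see Parameters).
* Explicit integration only; no bidomain, no adaptive meshing.
* The cellular automaton's waiting-front behaviour shifts composite-tissue
  block thresholds below isolated-fibre refractory periods.
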