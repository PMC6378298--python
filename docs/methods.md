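# Methods

`crtsim` is a desk-scale, multiscale model of ventricular activation
under cardiac resynchronization therapy (CRT): a synthetic biventricular
anatomy with a Purkinje conduction tree, monodomain reaction–diffusion
propagation with human ventricular membrane kinetics, a precordial
pseudo-ECG, QRS delineation, and the biomarker/correlation analysis that
relates ECG-derived quantities (QRSd, QRSa, t90QRSa) to tissue-level
dyssynchrony (TAT, t90).

## Anatomy (synthetic_geometry)

The biventricle is a pair of truncated ellipsoids voxelised on a regular
hexahedral grid (default 0.8 mm edge): a thick-walled LV half-ellipsoid
(outer semi-axes 30×30×45 mm, 9 mm wall) cut at the base plane, and an
RV crescent (4 mm wall) formed by a second ellipsoid shifted toward +x
whose cavity abuts the LV epicardial surface; that shared wall is the
septum. The base cut is an artificial boundary (no valve anatomy).

The transmural coordinate (0 at endocardium, 1 at epicardium) is
computed analytically from the ellipsoid level sets as
(level−1)/|∇level|, which is sub-voxel accurate and treats the septum as
running LV-endo → RV-endo. Cell types are assigned by half-open,
lower-inclusive depth intervals spanning 17/41/42% of wall thickness
(endo/mid/epi). Because the spans are *thickness* fractions, volume
fractions match them only where the wall is thin or flat: on the septum
the recovered volume fractions are within ±1 pp of 17/41/42, while the
thick curved LV free wall holds more volume in its outer shells (epi
volume fraction ≈ 52%); the layer tests are written accordingly.

Fibers follow a rule-based rotating-helix prescription: the helix angle
interpolates linearly in depth from +60° (endo) to −60° (epi) —
conventional endpoints, configurable — in the local
circumferential/longitudinal frame built from the transmural normal and
the long axis. The transmural angle rule is linear and defaults to zero;
all conduction-velocity calibration assumes in-plane fibers.

The LV free wall is partitioned into 9 segments (posterior/lateral/
anterior × apical/mid/basal) by angular and longitudinal terciles; lead
sites sit at segment centres on the requested surface (epi or endo), or
at the RV septal endocardium (apex, 50% and 85% of apex–base height for
the apex / mid / upper-outflow sites). Electrode cubes are 0.5 mm³,
snapped to the nearest surface node on grids coarser than the cube.
Papillary muscles, trabeculations and the moderator band are omitted.

## Membrane models (cell_models)

Working myocardium uses the O'Hara–Rudy dynamic human ventricular model
(endo/mid/epi variants) with four fast-sodium modifications for
realistic coarse-grid propagation: steady-state activation m_ss replaced
by the ten-Tusscher-type squared sigmoid; steady-state inactivation
h_ss = j_ss = 1/(1+exp((V+78.5)/6.22)) (phosphorylated variant shifted
−6.2 mV); the fast-inactivation and j-gate time constants replaced by
the faster published re-fits; G_Na reduced to 23% of 75 mS/µF; G_NaL
doubled. Each modification is individually switchable. With all four
active, the steady-state paced endocardial cell reaches
dV/dt_max ≈ 275 mV/ms (the design anchor is ≈260 mV/ms; the printed
unit "260 V/ms" in the source literature is read as the
model-conventional mV/ms = V/s); the unmodified transcription reproduces
the published model (dV/dt_max 265 mV/ms, APD90 266 ms, verified against
an independent transcription to 1e-8 relative).

The conduction system uses the Stewart Purkinje-fibre model (TNNP-family
kinetics plus funny current, sustained outward current and reduced
inward rectifier), which is intrinsically automatic (~1 spontaneous AP
per 1–2 s from the published initial state).

Integration is Rush–Larsen for all gating variables and forward Euler
for concentrations and voltage (dt 0.005 ms single cell, 0.02 ms
tissue). Rush–Larsen is not optional for the modified model: the
modified fast-inactivation time constant falls below 1 µs at depolarised
potentials, where explicit-Euler gating diverges.

## Tissue propagation (monodomain)

The monodomain equation is solved on the voxel grid with node-centred
unknowns and element-centred anisotropic diffusivity
D = s·[σ_T' I + (σ_L − σ_T') f fᵀ] (mm²/ms), zero-flux boundaries.
Surface-to-volume ratio and capacitance are folded into the scale s.
Diagonal tensor entries use the conservative 7-point edge-conductance
stencil (exactly the classical Laplacian stencil for isotropic D);
fiber-rotation cross terms are added as trilinear-element cross-stiffness
contributions. The assembled operator is symmetric with zero row sums;
the solver divides the flux divergence by lumped dual-cell volume
fractions so boundary nodes see the same flux-per-volume as the
interior — this makes a planar wave exactly planar and the measured CV
independent of slab thickness (measured spread 0.0% between 0.8 and
6 mm), which licenses the thin calibration slabs used in tests.

Calibrated constants (all frozen in `crtsim.config`, calibrated once on
the 20×20 mm, 0.4 mm slab at dt 0.02 ms):

* `DIFFUSIVITY_SCALE = 0.50304` mm²/ms per S/m — longitudinal CV
  0.61 m/s at σ_L = 0.5 S/m.
* `TRANSVERSE_CORRECTION = 1.6415` — multiplies the transverse
  diffusivity. At 0.4 mm the transverse wavefront (~0.3 mm) is
  under-resolved and loses disproportionate speed to the grid; a single
  scale that fixes the longitudinal CV leaves the transverse at
  ~0.20 m/s. The correction restores 0.29 m/s, mirroring how the
  reference tissue solver's two conductivities were themselves tuned
  against the two CV targets. With it, CV_L/CV_T = 2.12, within 10% of
  √(σ_L/σ_T) = 2.24.
* `HF_SCALE_EXPONENT = 1.49066` — heart failure is modelled as a 50%
  CV reduction via a diffusivity multiplier (1−r)^γ. The continuum
  square-root law (γ=2) over-reduces on the working grid (61% measured)
  because the slowed front is narrower still; the calibrated exponent
  gives a measured 50.0% reduction.

Numerical behaviour at the calibrated operating point: halving dt
changes slab CV by 0.6%; refining the grid from 0.4 to 0.2 mm raises CV
by ~13% (the scheme at 0.4 mm sits below its fine-grid limit, which is
precisely why calibration is performed at the working resolution, as in
the reference study).

Focal stimuli (lead cubes, PMJ injections) use a resolution-aware
cluster model: on grids coarser than the 0.5 mm³ electrode cube the
stimulus is spread over the nodes within one grid spacing (a single
coarse node cannot drive its neighbours past threshold) with per-node
amplitude equal to the charge-conserving value clipped to
[100, nominal] µA/µF, and injection is gated off on tissue already above
0 mV (physiologically ineffective, numerically destabilising). On
0.4 mm grids this reduces to the nominal 400 µA/µF cube. Activation is
the first upward crossing of −10 mV, checked at every internal step.

## Conduction system (purkinje)

The tree is grown on the endocardial surface-node graph: a His stem
bifurcates into left and right bundles; the left bundle (a 3-element
chain, two elements of which are the LBBB lesion site) breaks out high
on the LV septal endocardium and spawns 3 main branches (posterior,
septal/apical, anterior); the right bundle descends to the apical third
of the septum before arborising into 2 main branches (septal-apical and
anterior/moderator-band) — the long right bundle is what delays RV
breakout ~1–10 ms after LV breakout under intrinsic conduction.
PMJ sites are sampled uniformly at random (seeded; default density
0.03/mm², giving ≈250 junctions on the default anatomy) and attached
through their geodesic paths, producing the stochastic subdivision of
each main branch; sampled sites that remain leaves become PMJs, paired
to their own myocardial node.

Conduction through the tree is graph shortest-path at constant velocity
(Dijkstra with a virtual super-source handling multiple onset sources
and retrograde re-entries); a Stewart-model 1D cable mode exists for
velocity calibration: cable diffusivity 1.1423 mm²/ms gives 2.50 m/s at
0.4 mm, and the graph mode uses that velocity. PMJ coupling is
event-based with earliest-wins semantics: anterograde tree→myocardium
events fire a junction stimulus after a 5 ms delay; myocardial
activation of a paired node re-enters the tree after 3 ms. The delays
are free parameters (no published values); they were chosen so that
apex pacing enters the conduction system within ~5–10 ms, matching the
reported behaviour class. LBBB blocks the two proximal left-bundle
elements; heart failure additionally applies the conductivity scaling.

## Forward ECG (ecg_forward)

The torso solve is replaced by the classical unbounded homogeneous
pseudo-ECG: every element contributes a current dipole −D∇V_m, summed
with the 1/r² lead field at each electrode. Six precordial electrodes
sit on an anterior plane 40 mm from the mesh (V1 over the RV, V6 lateral
to the LV); each is referenced against the mean of three distal sites
(Wilson-central-terminal surrogate). The gain is arbitrary but fixed:
morphologies and timings are meaningful, absolute voltages are not. The
heterogeneous-torso organ-conductivity table is carried as configuration
metadata for a future FEM backend.

## Delineation and biomarkers (delineation_metrics)

Per lead: onset is the first sustained (≥2 samples) crossing of 5% of
the maximum absolute slope; the end accumulates |d²φ/dt²| from the
onset, takes the 95%-of-area instant, and locates the minimum first
derivative between there and the end of the record. Derivatives are
central differences at 1 kHz after a 5-sample moving average (width 1
disables it). QRSd is earliest-onset to latest-end across leads. QRSa
integrates the absolute mean of the six leads over the QRS window;
t90QRSa is the 90%-of-area time. TAT is the first-to-last activation
interval; the activation-fraction curve uses all myocardial nodes in
its denominator (unactivated tissue caps it below 1 and leaves t90
undefined), with equal node weights on the uniform grid.

The synthetic QRS generator used for validation produces complexes with
exactly known support (fast 6 ms R upstroke, S descent, recovery hump,
concave terminal limb) plus 2%-of-peak noise band-limited to 10 Hz
(baseline-wander type). With the default parameters the chain recovers
QRSd within ±6 ms on 100/100 random complexes. A documented limitation:
broadband noise at the full 1 kHz bandwidth defeats any fixed relative
slope threshold (the derivative noise floor exceeds 5% of the maximum
slope for physiological upstrokes), so signals should be low-pass
filtered before delineation; the simulated ECGs here are noiseless.

## Protocols and statistics (crt_protocols, stats_report)

AVD is sinoatrial-to-lead time; without atria, intrinsic conduction is a
His stimulus at atrial conduction (100 ms) + AV-node delay (80 ms) =
180 ms on the sinoatrial clock, so the His fires 180 − AVD ms after the
leads (80 ms at AVD 100, 40 ms at AVD 140); VVD delays the RV lead after
the LV lead. The grid is 3 RV × 18 LV = 54 lead-location
configurations, ×4 delay settings (AVD ∈ {100, 140} × VVD ∈ {0, 30})
for the full grid. The solver clock starts at the earliest stimulus;
results are reported on the sinoatrial clock.

Correlations are Pearson r with two-sided t-distribution p-values
(α = 0.05, no multiplicity correction — three pre-specified pairs:
QRSd–TAT, QRSa–TAT, t90QRSa–t90). Rankings are stable ascending sorts
with lexicographic (rv, lv, AVD, VVD) tie-breaks; the report states
whether the shortest-QRSd and fastest-t90 optima coincide.

## Problem sizes

Acceptance quantities run at the study's own sizes: the 20×20 mm,
0.4 mm slab (thickness-reduced to 0.8 mm under the verified
thickness-invariance), a 30 mm Purkinje cable, and a single cell paced
100 beats at dt 0.005 ms. Whole-heart tests run on a 0.35-scaled
biventricle (0.8 mm edge, ≈7.5k nodes, dt 0.04 ms, denser PMJs
compensating the smaller endocardium) — the package's choice of test
problem size; at that scale the absolute QRSd/TAT values are not
comparable to a human heart, and the tests assert orderings and
correlation structure (healthy < best-CRT < HF+LBBB; r(t90QRSa, t90) >
r(QRSd, TAT)) rather than magnitudes.

## Known limitations

* Ellipsoidal anatomy without papillary muscles, trabeculations or a
  moderator band; base cut is a flat no-flux plane.
* Pseudo-ECG ignores torso heterogeneity and boundedness; only
  morphology/timing are interpretable.
* The tree generator approximates a stochastic-growth conduction system
  topologically (branch counts, connectivity), not geometrically; PMJ
  placement is density-based, not optimised against an ECG morphology.
* Transverse propagation at 0.4 mm (and all propagation on the coarse
  test hearts) is grid-corrected rather than grid-converged; the
  calibration constants are resolution-specific.
* Delineation assumes low-noise signals (see above).
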