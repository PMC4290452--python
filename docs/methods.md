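# Methods

This note records the models implemented in `spindlemech`, their assumptions,
the numerical choices behind them, and what the synthetic data do and do not
capture.

## Geometry and units

Reconstruction space is nanometres; simulation and architecture space is
micrometres.  The single conversion site is `spindlemech.traces.nm_to_um`.
Freeze-substitution shrinks microtubules in electron tomograms (apparent
diameter ~18 nm versus the 25 nm of a 13-protofilament microtubule); raw
coordinates are corrected once by the uniform, isotropic factor γ = 25/18.
Isotropy (the same factor on x, y, z) is an assumption: the provenance of the
correction does not distinguish axes, and the correction is refused a second
time so it cannot be stacked.

## Synthetic spindles

The generator stands in for non-deposited tomographic reconstructions.  It
emulates the features the downstream analyses rely on:

- **Architecture.** The MMO (maximal midzone overlap) rule gives
  N = round(2L_T/(L_s + L_m)) monodisperse microtubules of length
  (L_s + L_m)/2, each spanning from its pole to the far edge of the midzone.
  Defaults are the wild-type constants L_T = 27.1 μm, L_m = 2.5 μm; at
  L_s = 2.5 μm this yields the 11-microtubule early anaphase B spindle.
  An odd microtubule count is assigned to pole A (a deterministic
  tie-break).  The null model draws per-pole counts from
  Poisson(mean_per_pole), re-drawing if either pole is empty (the spindle
  must be bipolar), and partitions L_T uniformly at random via
  sorted-uniform spacings; lengths above L_s are truncated with the surplus
  spawning extra microtubules on random poles, conserving L_T exactly.
- **Transverse organisation.** Inside the central L_m the microtubules of
  the two poles occupy interleaved ("checkerboard") sites of a square
  lattice (40 nm); outside it each pole's microtubules relax to a hexagonal
  lattice (30 nm).  The two phases blend linearly over a 100 nm transition
  zone, reflecting the narrow phase boundaries seen in reconstructions.
- **Axis shape and noise.** Microtubules run parallel to a straight axis or
  a global circular arc (curvature in μm⁻¹); Gaussian positional noise of
  chosen sd is added per point.  Points are sampled every 50 nm: at 2 nm
  per-point noise this keeps the random-kink inflation of polyline lengths
  below ~0.3 % (at 25 nm spacing it would be ~1.3 %, visibly corrupting
  length recovery).

What the generator does **not** emulate: microtubule dynamic instability,
curvature variation along the spindle, partial lattice occupancy and defects,
astral/kinetochore microtubules, or anisotropic tomographic point-spread.
Passing tests on synthetic data therefore validate the analysis machinery,
not the biology of real reconstructions.

A known statistical consequence of per-point noise: the nearest-neighbour
distance is a minimum over ~4 noisy neighbour distances and is biased low by
roughly one standard deviation of the pairwise noise (~2 nm at sd 2 nm), so
recovered midzone medians sit at ~38 nm for a 40 nm lattice.

## Fibre tracking (IFTA)

The spindle axis is traced by sphere stepping with a single granularity
parameter R_s (200 nm for axis tracing, 100 nm for packing statistics).  The
seed is the centre of mass of the densest minus-end cluster; at each step the
next axis point is the point on the sphere of radius R_s minimising the mean
squared distance to the positions where microtubules cross the sphere
surface.  That constrained minimiser has the closed form
c + R_s·(q̄ − c)/|q̄ − c| (q̄ the crossing centroid), which is exact and
deterministic; the tests verify it against a Nelder–Mead optimiser on random
configurations.  Points inside the advanced sphere are masked so the front
cannot reverse.  Both poles are tried as seed and the longer completed trace
kept; tracing that never reaches the opposite cluster raises a partial-trace
error carrying the path.  Termination inserts the opposite cluster centroid
as the final axis point, so the last step may be shorter than R_s.

Cross-sections are taken on planes through consecutive axis-point midpoints,
perpendicular to the local axis; each trace contributes its plane crossing
nearest the axis when within a 500 nm capture radius (screening out unrelated
structures).  Centres are expressed in a parallel-transported 2D frame — the
computationally straightened spindle.  Packing angles are vertex angles
subtended at each centre by pairs of neighbours within 1.25× the modal
nearest-neighbour distance, reported in [0°, 120°]: square lattices give 90°,
hexagonal 60°.  The midzone is the maximal contiguous axial interval whose
sections contain ≥2 centres from each pole.  Region statistics are compared
with the standard two-sample Kolmogorov–Smirnov test.

## Transverse stiffness tensor

Microtubules are uniform hollow cylinders (r₁ = 7.5, r₂ = 12.5 nm).  The
bundle tensor uses the centroid of the centres as neutral axis; the explicit
sums and the covariance matrix form N[I_MT·I₂ + A_MT(tr(Σ)I₂ − Σ)] are both
implemented and agree to machine precision.  A Monte-Carlo area integration
over the annuli serves as an independent oracle in the tests (<0.1 %).

Cross-linkers are rectangles (width w, span h = centre separation − 2r₂)
with microtubule material.  Each contributes its own-axis rectangle tensor
(orientation θ measured from the y-axis) **plus** a parallel-axis area term
w·h·d² for its midpoint offset d.  The parallel-axis term is a design
choice: without it linker material could never raise I_min, contradicting
the observed w-dependence of the minimal stiffness; with it the w = 0
pathway (used for all spindle maps) is unchanged.  The composite neutral
axis is kept at the microtubule centroid for the same reason.

Idealized growth sequences: square arrays fill a 3-wide block with the row
of 3 at N = 3 and the 2×2 motif at N = 4 (configurations are per-N motifs,
not nested); hexagonal arrays grow by distance-then-angle order (pair,
equilateral triangle, edge-sharing rhombus, shells).  These sequences
reproduce the characteristic minimal-stiffness steps: N = 3 → 4 a ~11-fold
(~1100 %) jump to the isotropic 34 I_MT motif, N = 4 → 5 a ~3 % increase.
Stiffness is reported in MT units (multiples of I_MT); EI_MT = 20 pN·μm²
converts to physical flexural rigidity.  Isotropy is flagged at relative
eigenvalue degeneracy 1e-9.

## Buckling simulation

Overdamped bead-spring filaments (segment 0.1 μm, EI_MT = 20 pN·μm², slender
-body transverse drag 4πη/ln(L/d) per unit length, isotropic) in 3D, with
thermal noise at kT = 0.0042 pN·μm and viscosity 1 pN·s·μm⁻².  The SPBs are
bodies confined to the x-axis (Stokes drag of a 60 nm sphere).  Each
microtubule is connected to its SPB by a pair of stiff Hookean springs
(1000 pN/μm): one on the minus end at a face point Monte-Carlo-sampled with
pairwise separation ≥ 2× the 30 nm steric radius (the face radius grows as
√(N/6) beyond six microtubules, with a 10 % widening fallback if rejection
stalls), and one on the adjacent model point, clamping the minus-end
orientation at the pole.  Without the second spring the half-spindle fans
pivot freely and a soft jackknife mode dominates the response.  The
single-filament Euler stand-in instead uses single-point tethers at both
ends (hinged), matching the π²EI/L² oracle.

Numerics: backward Euler per filament for bending (discrete biharmonic,
free ends) and stretching (stiff axial springs, k = 2×10⁵ pN/μm, isotropic
split with the rest-length term lagged), giving one shared symmetric
pentadiagonal system per filament solved by banded Cholesky for x, y, z.
All couplings — linkers, tethers, steric contacts, confinement, centring —
are lagged-anchor diagonally implicit: their stiffness enters the diagonal,
their anchor the right-hand side.  This is stable at dt = 1 ms despite
spring constants up to 2×10⁵ pN/μm; axial strain stays below ~0.3 % at peak
load.  Steric repulsion is a one-sided quadratic engaging below 60 nm
centre separation (200 pN/μm per segment), evaluated with x-binned
neighbour lists.

Cross-linkers (up to 300; Hookean, rest length 50 nm, 1000 pN/μm) bind only
antiparallel filament pairs whose beads lie inside the central 2.5 μm
midzone cylinder, within a 75 nm capture distance, at most two per bead, in
randomized batches every 50 ms of the 50 s initialisation (a weak 20 Pa
lateral centring force is active only then, and the SPBs are pinned by a
stiff spring at the spindle rest length).  Detachment is then frozen.  The
ramp drops the pole-spring rest length by Δ = 1 μm and ramps its constant
linearly to k_max = 240 pN/μm (1500 for reinforced runs) over 150 s,
followed by a 50 s hold; the critical force is the hold-window mean of the
spring force, summarised as the median over replicates.  Buckle modes are
counted as strict local maxima of the smoothed backbone (mean lateral bead
position per 0.1 μm axial bin), with counts of 0 below a 2×steric-radius
deflection threshold.

Confinement α (Pa) adds a lateral Hookean restoring force of stiffness
α × segment length per model point toward the spindle axis — the per-unit-
length convention that reproduces the reinforced-buckling closed forms
λ = 2π(EI/α)^{1/4}, f_c = 2√(EI·α) (verified on single filaments to a few
per cent).  The axis is the anchor line; it is the only distinguished line
in the model.

### Desk scaling and problem sizes

Protocol durations scale uniformly by `time_scale`.  The test suite runs the
spindle sweeps at time_scale 0.5 with 3 replicates per condition and the
confined sweeps at 0.25: at 0.25 the *unconfined* longer spindles lock into
second-order buckling that fails to relax into the primary mode within the
hold window (the medians at 0.5 and 1.0 agree to ~1 %, so 0.5 is the fastest
faithful compression).  Single-filament oracles use time_scale 0.1 and
Δ = 0.5 μm (post-buckling end-shortening of Δ/L ≈ 0.2 would raise the
elastica plateau ~10 % above the Euler onset force; 0.1 keeps it within a
few per cent).  The unconfined sweep uses L_s ∈ {4, 5, 7, 9, 11} μm: the
ramp cannot exert more than k_max·Δ = 240 pN, which MMO architectures
shorter than ~4 μm approach, saturating the measurement.

### Known limitation: critical-force scaling with length

The free-exponent fit of median F_c against L_s over the grid above gives
p ≈ −2, not the −4 of the idealised argument F_c ∝ EI_eff/L² with
EI_eff ∝ N² ∝ L⁻².  The N² premise requires rigid cross-section coupling,
but Hookean bridging linkers have no first-order resistance to axial
sliding between filaments (a perpendicular spring opposes shear only
through its tension, ~30 pN/μm per linker here), so the composite operates
near the sliding-free limit EI_eff ≈ N·EI_MT and F_c ≈ π²·N·EI_MT/L_s²
(times an end-clamp factor).  The measured effective stiffness of long
simulated spindles (~6 MT units for 4–6 microtubules) is consistent with
this limit.  Under lateral confinement the same physics predicts and the
simulation reproduces F_c ∝ N ∝ (L_s + L_m)⁻¹, i.e. the ≈ −1 exponent, and
the confinement-induced transition from primary to higher-order buckling
modes.

## Scaling models and cell forces

Power-law fits are least squares in log-log space; the fixed-exponent mode
fits only the prefactor.  Median replicate forces are fitted (no replicate
weighting).  The conserved-volume cylinder gives r_c = √(V/πL) and
EI ∝ r_c⁴ ∝ L⁻²; combining N_MMO ∝ 1/(L_s + L_m) with the quadratic mean
stiffness of idealized arrays reproduces the −2 slope in the large-L limit.

The tubulin budget uses the sphero-cylinder volume
V_c = 2πR_c³(L_c/2R_c − 1/3), 13 protofilaments × 8 nm dimers, and
602.214 dimers·μm⁻³ per μM.  The relative spindle fluorescence intensity
(0.16) is interpreted as the polymerised fraction of cellular tubulin, so
total = polymerized/0.16 and free = total − polymerized; this chain
reproduces the polymerized (~0.69 μM), total (~4.3 μM) and free (~3.6 μM)
pools, while the whole-cell dimer abundance implied by it (~2.8×10⁵) is
reported but not asserted because no chain reconciles it with the other
quantities.

Nuclear drag uses γ = (9π²/(2√2))·η·r_nucleus/ε^{5/2} with clearance
ε = (r_cell − r_nucleus)/r_nucleus.  The prefactor is a reconstruction — the
source expression is typographically corrupted — fixed by requiring both
endpoints of the published 25–110 pN·s·μm⁻¹ range (r_nucleus = 0.8 and
1.0 μm at η = 1, r_cell = 1.6 μm); it is implemented as a named, swappable
function.  Spindle-ablation relaxation x(t) = x₀e^{−t/τ} is fitted
log-linearly when displacements are positive (exact on noiseless data) and
by nonlinear least squares otherwise; forces follow as F_v = γ·v_s/2 (v_s
converted from μm/min inside the function) and F_e = x₀γ/τ.

## Reproducibility

Every stochastic component takes an explicit seed: generators use
`numpy.random.default_rng(seed)`, the simulation engine seeds its compiled
RNG per replicate (derived from the state seed), and CLI manifests snapshot
configuration and seeds.  Identical seeds give bit-identical initial states
and trajectories within a process.
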