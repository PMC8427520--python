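# Methods

## The model

The package separates the *protocol layer* (supervision, scheduling,
acceptance, metadynamics, analysis) from the *dynamics layer* behind a
small engine contract (`run`, `resample`). The bundled engine
integrates beads in a composite potential with BAOAB-split Langevin
dynamics; any engine honoring the contract (including an all-atom MD
adapter) could be substituted without touching the protocol layer.

Units are fixed package-wide: Å, ps, amu, K, kcal/mol, with
k_B = 1.987204259×10⁻³ kcal/(mol·K). Because 1 amu·Å²/ps² = 10 J/mol
exactly, forces in kcal/(mol·Å) convert to accelerations with the
factor 418.4.

### Potential terms

* **Funnel well** (ligand beads): U = −depth·exp(−r²/2w²), r the
  distance to the site center. Smooth, finite everywhere, −depth at
  the site, → 0 at infinity — so the ligand–receptor interaction
  energy has clean asymptotics on both ends.
* **Soft-core repulsion** (all pairs except receptor–receptor):
  U = ε(1 − r/σ)² for r < σ. Finite at r = 0, C¹ at the cutoff.
* **Confining sphere**: flat inside a role-dependent radius, harmonic
  outside. Keeps the simulation volume finite (the stand-in for a
  solvated box); solvent may be confined more tightly than the ligand
  so that the bath stays near the receptor while the ligand is free
  to leave.
* **Quartic double well** (escape benchmark): U = h((x²−a²)/a²)²
  along x, harmonic in y/z.

Receptor beads are *fixed* by default; `restraint_k > 0` makes them
mobile under a harmonic positional restraint. Solvent beads are inert
(repulsion only): they exist to exercise the bridging-solvent metric
of the double-metric unbinding supervision.

### Integrator

Velocity BAOAB with exact Ornstein–Uhlenbeck damping
(c₁ = e^(−γΔt), noise scale √(k_BT/m)·√(1−c₁²)), default timestep
0.01 ps. A velocity-carrying integrator is required because the
supervision restart rule is defined on velocities ("restart with
randomly assigned velocities"). Noise is pre-drawn per save-chunk
from a PCG64 generator, so runs are bit-reproducible for a fixed
seed; the inner loop is numba-compiled. Divergence (non-finite or
> 10⁶ Å coordinates) raises an integration error carrying the step
index.

## Supervision

* **Slope fit**: ordinary least squares of the sampled metric against
  time (np.polyfit); a constant series returns exactly 0.
* **Acceptance**: binding → slope < 0; unbinding → *all* supervised
  slopes > 0. Slope exactly 0 counts as non-productive in both
  directions: zero slope is no progress, and the conservative reading
  keeps the tabu rule unambiguous on degenerate (e.g. all-zero
  solvent-count) series.
* **Tabu restart**: rejected windows restart from the last accepted
  frame; per-window engine and velocity seeds are spawned from the
  root seed by window index (SeedSequence), so a run is reproducible
  and rejected windows do not perturb later ones.
* **Binding termination** is evaluated on the end-of-window
  supervised distance of accepted windows — the supervision stream is
  the only observable the algorithm inspects, and mid-window minima
  of rejected windows belong to discarded states.
* **Unbinding**: the window length adapts via the four-branch
  schedule (boundaries on the ≤ side); the very first window runs for
  Δt₀. The r_L used for scheduling is the supervised centroid
  distance (configurable choice; the minimum interatomic distance is
  an equally defensible reading). After each productive window the
  receptor partner set for the bridging-solvent metric is re-detected
  as all receptor beads within the contact cutoff of the ligand,
  retaining the previous set when none qualify. Termination: no
  ligand–receptor pair below the 3.5 Å contact cutoff at the end of
  an accepted window. `max_windows` (default 10,000) counts all
  windows, accepted or not.

## Metadynamics

Well-tempered heights w_k = w₀·exp(−V(s,t)/((γ−1)k_BT)); the bias
V(s) = Σ w_k·exp(−(s−s_k)²/2σ²) acts on the ligand–site centroid
distance, its force −dV/ds projected on the CV gradient and shared
equally among ligand beads. Hills are stored exactly; the integrator
reads the bias from a dense grid of V and dV/ds (node spacing σ/100,
nodes updated analytically per hill within 10σ) with cubic-Hermite
interpolation — the cache agrees with the direct sum to ~1e-9
kcal/mol (tested). The stop condition (CV ≥ 50 Å by default) is
checked at deposition times, i.e. at 1 ps resolution. The grid spans
the stop threshold + 20 Å (capped at 520 Å); beyond it the bias force
clamps, which only matters for runs configured never to stop.

## Fixtures: what the toys emulate

`funnel_binding` places one ligand bead (500 amu — a single bead
stands for a whole drug-sized molecule) 32 Å from the binding site of
four fixed receptor beads, in a funnel well of depth 5 kcal/mol and
width 6 Å inside a 40 Å confining sphere. Friction is 50 ps⁻¹, giving
D = k_BT/(mγ) ≈ 0.01 Å²/ps: one 500 ps window moves the ligand a few
Å, so unsupervised binding from 30+ Å is a long random search while
supervision can ratchet inward — the regime the protocol was designed
for. A low-friction setting would let free diffusion cross the whole
box within one window and make supervision pointless for any method.

`bound_complex` seats the ligand at the center of an octahedral
six-bead receptor shell (radius 3 Å, so the start has six contacts
below the 3.5 Å cutoff), funnel depth 4 kcal/mol, plus 20 solvent
beads (18 amu) confined within 10 Å — enough bath for the
bridging-solvent metric to fluctuate and trend as the ligand leaves.
`solvated_complex` is the same with 55 solvent beads in 14 Å.
`double_well_1d` is a single 100 amu bead in a quartic double well
(barrier 3 kcal/mol ≈ 5 k_BT, minima ±3 Å).

All fixture randomness (ligand direction, solvent placement) derives
from the seed; (name, seed) → byte-identical files.

### What passing tests do and do not show

The toys establish that the *decision logic* is correct (schedule,
slope, acceptance, restart bookkeeping, termination), that the
sampling machinery has the right statistical mechanics
(equipartition, Maxwell–Boltzmann, well-tempered height decay), and
that supervision/bias genuinely accelerate first passage in a regime
where the event is rare. They say nothing about force-field accuracy,
solvent granularity, receptor flexibility, or the kinetics of any
real receptor–ligand pair; a single isotropic bead has no binding
pose, so pose-resolution claims are out of reach by construction.

## Analysis conventions

* Contacts: strict `< 3.5 Å` ("less than"); hydrogen bonds: `≤ 3.5 Å`
  donor–acceptor and `≥ 120°` D–H···A (boundary inclusion chosen and
  documented; the difference is measure-zero). The angle is measured
  at the hydrogen.
* Persistency: residue-level hits per frame (configurable through
  the extractor), pooled over all replicas — the denominator is the
  merged frame count, so it is invariant to replica order and to
  concatenation.
* Superposition: Kabsch-type fit via scipy's `align_vectors`, with
  the RMSD recomputed from the explicit residuals (the solver's
  reported residual loses precision for near-perfect fits). Collinear
  selections are rejected.
* Water occupancy: per-voxel fraction of frames with ≥ 1 solvent bead
  (default 1.0 Å spacing), "AquaMMapS-style"; hydrated spots are
  voxels above a configurable threshold (default 0.5). OpenDX text
  export.
* Landscapes: 2D histogram over two CVs; per-bin mean interaction
  energy plus an occupancy depth −k_BT·ln(count/total). Empty bins
  are flagged NaN, never zero. Interaction energy is the engine's
  ligand–receptor potential sum (funnel + ligand–receptor repulsion)
  — the package's stand-in for an end-state free-energy estimator
  such as MM/GBSA.

## Numerical choices and problem sizes

* Thermodynamics checks use the exactly harmonic transverse modes of
  the double-well fixture (U = k_t·y², spring 2k_t) with ~15,000
  decorrelated samples: variance tolerances of 5–10% sit > 4σ from
  the sampling noise.
* The efficacy benchmark runs 20 seeds of supervised binding, then
  gives every unsupervised run the *same shared budget* (the largest
  supervised run); unsupervised runs that never bind are censored at
  the budget. Reported: median steps ratio.
* The escape benchmark caps both biased and unbiased runs at 5 ns and
  compares median first-crossing times over 20 seeds.
* Acceptance-script runs use the default protocol parameters; typical
  costs are ~20 windows (binding), ~5–35 windows (unbinding), and
  2,000–6,000 hills (release) per seed.

## Known limitations

Solvent has no attractive interactions, so the bridging-solvent count
is sparse (0–3) and its slope is noisy; the double supervision
consequently rejects more windows than a hydrogen-bond-rich all-atom
interface would. The metadynamics bias is strictly 1D, and no
free-energy reconstruction/reweighting is provided. PDB output is
HETATM-only with role-coded residue names; binary trajectory formats
are out of scope.
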