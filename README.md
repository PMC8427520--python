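# sumd

Supervised molecular dynamics (SuMD) machinery — binding supervision,
double-metric adaptive unbinding supervision, RMSD-binned path
sampling, and well-tempered metadynamics ligand release — together
with the trajectory-analysis operators that usually accompany such
campaigns (contacts, hydrogen bonds, interaction persistency, RMSD and
superposition, interaction-energy landscapes, water-occupancy maps).
Everything runs on bundled toy bead-and-potential systems integrated
by a Langevin engine, so the full protocol is testable on a laptop
instead of a GPU cluster.

## Who this is for

People who study adaptive-sampling protocols for ligand
binding/unbinding — or who want a small, fully inspectable reference
implementation of the SuMD decision logic — without standing up an
all-atom receptor system. The algorithms are the real thing; the
physics underneath is a deliberately simple bead model.

## The algorithm

SuMD accelerates binding without biasing forces. Short unbiased MD
windows (Δt, default 500 ps) are run in sequence; within each window
the supervised metric m(t) — the distance between the ligand centroid
and the binding-site center — is sampled at regular intervals (50 ps)
and fitted to a straight line. For binding:

* slope dm/dt < 0 → the window is *productive*: the next window
  continues from the final coordinates and velocities;
* slope ≥ 0 → the window is discarded and the run restarts from the
  last productive state with velocities redrawn from the
  Maxwell–Boltzmann distribution (the tabu-like rule).

The run terminates once the end-of-window distance drops below 4 Å.

Unbinding uses a *double supervision* — the ligand–site distance and
the number of solvent beads bridging ligand and receptor must both
trend upward — and grows the window length along the pathway:
Δt = Δt₀·Nt_i with Nt_i ∈ {1, Nt₁, Nt₂, Nt₃} selected by comparing
the last end-of-window distance r_L with thresholds D₁ < D₂ < D₃
(defaults: Δt₀ = 300 ps; Nt = 3, 6, 10; D = 5, 8, 10 Å). Unbinding
ends when no ligand–receptor pair remains within the 3.5 Å contact
cutoff.

Path sampling relaxes the supervision bias: an adaptive trajectory is
clustered by ligand RMSD to its start (1 Å bins, after receptor
superposition), one random frame per bin seeds an unsupervised run,
and only those runs are analyzed.

Ligand release can also be driven by well-tempered metadynamics on
the centroid-distance CV: Gaussian hills (height 0.1 kcal/mol, width
0.1 Å) are deposited every 1 ps with heights decaying as
w_k = w₀·exp(−V(s)/((γ−1)k_BT)), bias factor γ = 20, until the CV
reaches 50 Å.

## Worked example

```bash
sumd fixtures funnel_binding --seed 1 --out-dir fx
sumd bind --config fx/funnel_binding.yaml --seed 7 --out-prefix bindrun
```

prints (stderr carries the per-window log; stdout the summary):

```json
{
  "termination_reason": "criterion_met",
  "n_windows": 24,
  "restart_count": 16,
  "final_site_distance": 3.3352913358186864,
  "config_hash": "cabb10220f0e46db",
  "seed": 7,
  "version": "0.1.0"
}
```

Reading: the ligand bead started 32 Å from the binding site; 24
supervision windows (12 ns of window time) were simulated, 16 of them
rejected and restarted from the last productive state with fresh
velocities, and the run stopped by its own criterion with the
supervised distance at 3.34 Å < 4 Å. Alongside the summary the run
writes `bindrun.xyz` (the accepted trajectory, extended XYZ with
`time=` metadata) and `bindrun.windows.jsonl` (one record per window:
chosen Δt, metric samples, fitted slopes, accept/reject, end
distance).

The same pattern drives the other stages: `sumd unbind`,
`sumd metadyn`, `sumd pathsample`, and `sumd analyze
contacts|hbonds-style persistency|rmsd|watermap|landscape` for the
post-processing. The library API (`sumd.run_sumd_binding`,
`sumd.run_metadynamics`, …) exposes everything the CLI does.

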