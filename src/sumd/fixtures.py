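"""Bundled toy fixtures.

Each fixture is a deterministic (name, seed) -> (ToySystem, start
Frame) recipe emulating one stage of a receptor:ligand simulation
campaign on a desk-scale bead system:

* ``funnel_binding`` — one ligand bead placed >= 30 A from the binding
  site of a fixed four-bead receptor, in a funnel-shaped attractive
  well: the binding-supervision workload.
* ``bound_complex`` — the ligand seated at the site center inside an
  octahedral receptor shell with a bath of inert solvent beads: the
  unbinding / metadynamics-release workload.
* ``solvated_complex`` — like bound_complex but with a larger solvent
  bath (>= 50 beads) for the double-metric supervisor.
* ``double_well_1d`` — a single ligand bead in a quartic double well
  along x: the enhanced-sampling escape benchmark.

All randomness (ligand direction, solvent placement) derives from the
seed, so the same (name, seed) always produces identical systems.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import Frame, ToySystem, build_toy_system
from .io import RunConfig, write_topology, write_trajectory
from .engine import Trajectory

FIXTURE_NAMES = ("funnel_binding", "bound_complex", "solvated_complex",
                 "double_well_1d")

# shared bead parameters: a single bead stands for a whole molecule,
# so the ligand carries a drug-like mass and solvent a water mass
LIGAND_MASS = 500.0
RECEPTOR_MASS = 100.0
SOLVENT_MASS = 18.0


def _receptor_octahedron(radius: float) -> list[list[float]]:
    return [[radius, 0, 0], [-radius, 0, 0], [0, radius, 0],
            [0, -radius, 0], [0, 0, radius], [0, 0, -radius]]


def _place_solvent(rng: np.random.Generator, n: int, r_min: float,
                   r_max: float, min_sep: float) -> list[list[float]]:
    """Rejection-sample non-overlapping solvent positions in a shell."""
    placed: list[np.ndarray] = []
    while len(placed) < n:
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = (r_min ** 3 + (r_max ** 3 - r_min ** 3) * rng.random()) ** (1 / 3)
        p = r * u
        if all(np.linalg.norm(p - q) > min_sep for q in placed):
            placed.append(p)
    return [[float(x) for x in p] for p in placed]


def _funnel_binding(seed: int) -> dict:
    rng = np.random.Generator(np.random.PCG64(seed))
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    ligand_pos = [float(x) for x in 32.0 * direction]  # >= 30 A out
    beads = [{"id": "L1", "role": "ligand", "mass": LIGAND_MASS,
              "position": ligand_pos}]
    for i, p in enumerate([[4, 0, 0], [-4, 0, 0], [0, 4, 0], [0, -4, 0]]):
        beads.append({"id": f"R{i + 1}", "role": "receptor",
                      "mass": RECEPTOR_MASS, "position": p})
    return {
        "beads": beads,
        "site_center": [0.0, 0.0, 0.0],
        "funnel": {"depth": 5.0, "width": 6.0},
        "repulsion": {"sigma": 2.5, "epsilon": 2.0},
        "confinement": {"radius": 40.0, "k": 10.0},
        "temperature": 300.0,
        # high effective friction: one supervision window moves the
        # ligand a few A, so binding from 30+ A is a genuinely long
        # search for unsupervised dynamics
        "friction": 50.0,
        "timestep": 0.01,
    }


def _bound_complex(seed: int, n_solvent: int = 20,
                   solvent_radius: float = 10.0) -> dict:
    rng = np.random.Generator(np.random.PCG64(seed))
    beads = [{"id": "L1", "role": "ligand", "mass": LIGAND_MASS,
              "position": [0.0, 0.0, 0.0]}]
    for i, p in enumerate(_receptor_octahedron(3.0)):
        beads.append({"id": f"R{i + 1}", "role": "receptor",
                      "mass": RECEPTOR_MASS, "position": p})
    for i, p in enumerate(_place_solvent(rng, n_solvent, 5.0,
                                         solvent_radius, 2.6)):
        beads.append({"id": f"W{i + 1}", "role": "solvent",
                      "mass": SOLVENT_MASS, "position": p})
    return {
        "beads": beads,
        "site_center": [0.0, 0.0, 0.0],
        "funnel": {"depth": 4.0, "width": 5.0},
        "repulsion": {"sigma": 2.5, "epsilon": 2.0},
        "confinement": {"radius": 60.0, "k": 10.0,
                        "solvent_radius": solvent_radius},
        "temperature": 300.0,
        "friction": 10.0,
        "timestep": 0.01,
    }


def _double_well_1d(seed: int) -> dict:
    del seed  # fully deterministic
    return {
        "beads": [
            {"id": "L1", "role": "ligand", "mass": 100.0,
             "position": [-3.0, 0.0, 0.0]},
            # inert marker so the system satisfies the one-receptor contract
            {"id": "R1", "role": "receptor", "mass": RECEPTOR_MASS,
             "position": [0.0, 0.0, 50.0]},
        ],
        "site_center": [3.0, 0.0, 0.0],
        "double_well": {"height": 3.0, "half_separation": 3.0,
                        "transverse_k": 5.0},
        "temperature": 300.0,
        "friction": 10.0,
        "timestep": 0.01,
    }


def fixture_config(name: str, seed: int = 0) -> dict:
    """The system-config mapping for a named fixture."""
    if name == "funnel_binding":
        return _funnel_binding(seed)
    if name == "bound_complex":
        return _bound_complex(seed)
    if name == "solvated_complex":
        return _bound_complex(seed, n_solvent=55, solvent_radius=14.0)
    if name == "double_well_1d":
        return _double_well_1d(seed)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")


def generate_fixture(name: str, seed: int = 0,
                     out_dir=None) -> tuple[ToySystem, Frame]:
    """Build a named fixture; optionally write its files to out_dir.

    Files written: ``<name>.pdb`` (topology), ``<name>_start.xyz``
    (start frame) and ``<name>.yaml`` (full run config with defaults).
    """
    cfg = fixture_config(name, seed)
    system = build_toy_system(cfg)
    start = system.initial_frame()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_topology(out_dir / f"{name}.pdb", system)
        roles = [b.role.upper()[:3] for b in system.beads]
        write_trajectory(
            out_dir / f"{name}_start.xyz",
            Trajectory(frames=[Frame(time=0.0, coords=start.coords)],
                       metadata={"roles": roles, "engine": "fixture",
                                 "seed": seed,
                                 "config_hash": system.fingerprint()}))
        RunConfig(system=cfg, seed=seed).save(out_dir / f"{name}.yaml")
    return system, start
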