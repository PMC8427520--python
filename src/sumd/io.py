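"""File formats and run configuration.

Trajectories travel as extended XYZ: an atom-count line, a comment
line carrying ``time=<ps>`` (and optionally ``window=<id>`` plus
provenance tokens), then one ``species x y z`` line per bead. Species
strings are the bead roles (LIG/REC/SOL). Topologies are written as
minimal PDB files (HETATM records, one bead per residue, residue name
from the role) through biotite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import Frame, ToySystem, Trajectory, ValidationError

_ROLE_TO_RES = {"ligand": "LIG", "receptor": "REC", "solvent": "SOL"}
_RES_TO_ROLE = {v: k for k, v in _ROLE_TO_RES.items()}


class ParseError(ValueError):
    """Malformed input file; the message carries line/frame context."""


# ---------------------------------------------------------------------------
# extended XYZ trajectories


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Write a trajectory as extended XYZ with per-frame time metadata."""
    path = Path(path)
    lines: list[str] = []
    meta = trajectory.metadata
    prov = " ".join(f"{k}={meta[k]}" for k in ("engine", "seed", "config_hash")
                    if k in meta)
    for frame in trajectory.frames:
        n = frame.coords.shape[0]
        lines.append(str(n))
        comment = f"time={frame.time:.6f}"
        if frame.window_id is not None:
            comment += f" window={frame.window_id}"
        if prov:
            comment += " " + prov
        lines.append(comment)
        roles = meta.get("roles")
        for i in range(n):
            species = roles[i] if roles is not None else "X"
            x, y, z = frame.coords[i]
            lines.append(f"{species} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    text = path.read_text().splitlines()
    if not any(line.strip() for line in text):
        raise ParseError(f"{path}: no frames (empty trajectory file)")
    frames: list[Frame] = []
    meta: dict = {}
    i = 0
    frame_no = 0
    species_list: list[str] | None = None
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 1} (frame {frame_no}): expected atom "
                f"count, got {text[i]!r}") from None
        if i + 1 >= len(text):
            raise ParseError(f"{path}: frame {frame_no}: missing comment line")
        tokens = dict(tok.split("=", 1) for tok in text[i + 1].split()
                      if "=" in tok)
        if "time" not in tokens:
            raise ParseError(
                f"{path}: line {i + 2} (frame {frame_no}): comment line "
                "missing time=<ps>")
        time = float(tokens["time"])
        window = tokens.get("window")
        coords = np.empty((n, 3))
        species = []
        for k in range(n):
            row = i + 2 + k
            if row >= len(text) or not text[row].strip():
                raise ParseError(
                    f"{path}: frame {frame_no}: wrong atom count "
                    f"(expected {n}, file ends at atom {k})")
            parts = text[row].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {row + 1} (frame {frame_no}): expected "
                    f"'species x y z', got {text[row]!r}")
            species.append(parts[0])
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {row + 1} (frame {frame_no}): "
                    "non-numeric coordinate") from None
        nxt = i + 2 + n
        if nxt < len(text) and text[nxt].strip():
            try:
                int(text[nxt].strip())
            except ValueError:
                raise ParseError(
                    f"{path}: frame {frame_no}: wrong atom count on frame "
                    f"{frame_no} (extra atom lines after {n})") from None
        frames.append(Frame(time=time, coords=coords, window_id=window))
        species_list = species
        for key in ("engine", "seed", "config_hash"):
            if key in tokens:
                meta[key] = tokens[key]
        i = nxt
        frame_no += 1
    if species_list is not None:
        meta["roles"] = species_list
    return Trajectory(frames=frames, metadata=meta)


# ---------------------------------------------------------------------------
# PDB topology


def write_topology(path, system: ToySystem) -> None:
    """Write the bead topology as a minimal PDB (HETATM records).

    One bead per residue; residue names LIG/REC/SOL encode the roles so
    the file round-trips through :func:`read_topology` and stays
    readable by standard structure viewers.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = system.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = system.positions.astype(np.float32)
    atoms.chain_id = np.array(["A"] * n)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array([_ROLE_TO_RES[b.role] for b in system.beads])
    atoms.atom_name = np.array(
        [f"B{i + 1}" for i in range(n)])
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.ones(n, dtype=bool)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_topology(path) -> tuple[list[str], np.ndarray]:
    """Read roles and coordinates back from a PDB topology.

    Returns (roles, coords); roles are decoded from the LIG/REC/SOL
    residue names.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    roles = []
    for res in atoms.res_name:
        if res not in _RES_TO_ROLE:
            raise ParseError(f"{path}: unknown residue name {res!r} "
                             "(expected LIG/REC/SOL)")
        roles.append(_RES_TO_ROLE[res])
    return roles, np.asarray(atoms.coord, dtype=float)


# ---------------------------------------------------------------------------
# run configuration


_SUPERVISION_KEYS = {
    "direction", "window_length", "save_interval", "metrics",
    "distance_threshold", "contact_cutoff", "solvent_shell",
    "solvent_hbond_dist", "mass_weighted", "max_windows", "seed",
}
_SCHEDULE_KEYS = {"dt0", "nt1", "nt2", "nt3", "d1", "d2", "d3"}
_METADYN_KEYS = {"hill_height", "hill_width", "period", "bias_factor",
                 "temperature", "stop_threshold", "max_time"}
_ANALYSIS_KEYS = {"contact_cutoff", "hbond_distance", "hbond_angle",
                  "grid_spacing", "occupancy_threshold", "rmsd_bin_width"}
_SYSTEM_KEYS = {
    "beads", "site_center", "temperature", "friction", "timestep",
    "funnel", "repulsion", "confinement", "double_well", "restraint_k",
}


@dataclass
class RunConfig:
    """Everything a run needs, grouped in blocks that mirror the
    module boundaries. Unknown keys are rejected at construction."""

    system: dict = field(default_factory=dict)
    supervision: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    metadyn: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name, block, allowed in (
                ("system", self.system, _SYSTEM_KEYS),
                ("supervision", self.supervision, _SUPERVISION_KEYS),
                ("schedule", self.schedule, _SCHEDULE_KEYS),
                ("metadyn", self.metadyn, _METADYN_KEYS),
                ("analysis", self.analysis, _ANALYSIS_KEYS)):
            unknown = set(block) - allowed
            if unknown:
                raise ValidationError(
                    f"unknown keys in '{name}' block: {sorted(unknown)}")

    # -- resolution into module objects ------------------------------------
    def build_system(self) -> ToySystem:
        from .engine import build_toy_system
        return build_toy_system(self.system)

    def build_supervision(self, direction: str | None = None):
        from .supervisor import SupervisionConfig
        kw = dict(self.supervision)
        if direction is not None:
            kw["direction"] = direction
        kw.setdefault("seed", self.seed)
        if "metrics" in kw and kw["metrics"] is not None:
            kw["metrics"] = tuple(kw["metrics"])
        return SupervisionConfig(**kw)

    def build_schedule(self):
        from .supervisor import UnbindingSchedule
        return UnbindingSchedule(**self.schedule)

    def build_metadyn(self):
        from .metadyn import MetadynParams
        return MetadynParams(**self.metadyn)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"system": self.system, "supervision": self.supervision,
                "schedule": self.schedule, "metadyn": self.metadyn,
                "analysis": self.analysis, "seed": self.seed}

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParseError("run config must be a mapping")
        unknown = set(data) - {"system", "supervision", "schedule",
                               "metadyn", "analysis", "seed"}
        if unknown:
            raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
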