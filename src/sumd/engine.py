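"""Toy bead dynamics engine.

This module provides the pluggable dynamics-engine contract used by the
supervision machinery, plus a bundled Langevin engine for bead systems
in a composite toy potential. The toy stands in for all-atom MD of a
receptor:ligand complex: a handful of fixed "receptor" beads define a
binding site, one or more "ligand" beads diffuse in a funnel-shaped
attractive well centered on the site, and optional inert "solvent"
beads exercise the double-metric (distance + bridging-water) unbinding
supervision.

Units are angstrom / picosecond / amu / kelvin / kcal/mol throughout
(:mod:`sumd.constants`).

The composite potential has four optional terms:

* a Gaussian funnel well ``U = -depth * exp(-r^2 / (2 width^2))``
  acting on each ligand bead, ``r`` its distance to the site center;
* a pairwise soft-core repulsion ``U = eps * (1 - r/sigma)^2`` for
  ``r < sigma`` between all pairs except receptor-receptor;
* a confining sphere, flat inside a role-dependent radius and harmonic
  outside, which keeps mobile beads in a finite simulation volume;
* a quartic double well along x (used by the 1D escape fixture).

Receptor beads are held fixed by default; setting ``restraint_k > 0``
makes them mobile under a harmonic restraint to their initial
positions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

from . import _kernels
from .constants import KB, KCAL_TO_INTERNAL, kbt_internal

ROLES = ("ligand", "receptor", "solvent")
_ROLE_CODE = {"ligand": 0, "receptor": 1, "solvent": 2}


class ValidationError(ValueError):
    """A system or configuration field failed validation."""


class IntegrationError(RuntimeError):
    """The integrator produced non-finite coordinates (blow-up)."""

    def __init__(self, message: str, step_index: int):
        super().__init__(message)
        self.step_index = step_index


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Bead:
    id: str
    role: str
    mass: float
    position: np.ndarray


@dataclass
class FunnelWell:
    """Gaussian attractive well on ligand beads. depth kcal/mol, width A."""

    depth: float
    width: float


@dataclass
class Repulsion:
    """Soft-core pair repulsion. sigma A (range), epsilon kcal/mol (height)."""

    sigma: float
    epsilon: float


@dataclass
class Confinement:
    """Spherical confinement: flat inside radius, harmonic k outside."""

    radius: float
    k: float = 10.0
    solvent_radius: float | None = None  # defaults to `radius`
    center: np.ndarray | None = None  # defaults to the site center


@dataclass
class DoubleWell:
    """Quartic double well U = h*((x^2-a^2)/a^2)^2 along x, plus a
    transverse harmonic k on y and z. Barrier height h at x=0, minima
    at x = +-a."""

    height: float
    half_separation: float
    transverse_k: float = 5.0


@dataclass
class ToySystem:
    beads: list[Bead]
    site_center: np.ndarray
    temperature: float = 300.0
    friction: float = 10.0
    timestep: float = 0.01
    funnel: FunnelWell | None = None
    repulsion: Repulsion | None = None
    confinement: Confinement | None = None
    double_well: DoubleWell | None = None
    restraint_k: float = 0.0

    def __post_init__(self):
        self.site_center = np.asarray(self.site_center, dtype=float)
        for b in self.beads:
            b.position = np.asarray(b.position, dtype=float)
        self.validate()

    # -- derived arrays ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def roles(self) -> np.ndarray:
        return np.array([_ROLE_CODE[b.role] for b in self.beads], dtype=np.int64)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == 0)

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == 1)

    @property
    def solvent_indices(self) -> np.ndarray:
        return np.flatnonzero(self.roles == 2)

    @property
    def mobile_mask(self) -> np.ndarray:
        mobile = self.roles != 1
        if self.restraint_k > 0:
            mobile = np.ones(self.n_beads, dtype=bool)
        return mobile

    def validate(self) -> None:
        roles = [b.role for b in self.beads]
        for b in self.beads:
            if b.role not in ROLES:
                raise ValidationError(f"bead {b.id}: unknown role {b.role!r}")
            if not b.mass > 0:
                raise ValidationError(f"bead {b.id}: mass must be > 0")
            if b.position.shape != (3,):
                raise ValidationError(f"bead {b.id}: position must be a 3-vector")
        if "ligand" not in roles:
            raise ValidationError("system needs at least one ligand bead (role)")
        if "receptor" not in roles:
            raise ValidationError("system needs at least one receptor bead (role)")
        if not self.timestep > 0:
            raise ValidationError("timestep must be > 0")
        if not self.friction > 0:
            raise ValidationError("friction must be > 0")
        if self.temperature < 0:
            raise ValidationError("temperature must be >= 0")
        e0 = potential_energy(self, self.positions)
        if not np.isfinite(e0):
            raise ValidationError("potential energy not finite at initial positions")

    def fingerprint(self) -> str:
        """Deterministic hash of the full system definition."""
        payload = {
            "beads": [
                [b.id, b.role, b.mass, [round(float(x), 12) for x in b.position]]
                for b in self.beads
            ],
            "site_center": [round(float(x), 12) for x in self.site_center],
            "temperature": self.temperature,
            "friction": self.friction,
            "timestep": self.timestep,
            "funnel": None if self.funnel is None else [self.funnel.depth, self.funnel.width],
            "repulsion": None
            if self.repulsion is None
            else [self.repulsion.sigma, self.repulsion.epsilon],
            "confinement": None
            if self.confinement is None
            else [
                self.confinement.radius,
                self.confinement.k,
                self.confinement.solvent_radius,
                None
                if self.confinement.center is None
                else [float(x) for x in np.asarray(self.confinement.center)],
            ],
            "double_well": None
            if self.double_well is None
            else [
                self.double_well.height,
                self.double_well.half_separation,
                self.double_well.transverse_k,
            ],
            "restraint_k": self.restraint_k,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def initial_frame(self) -> "Frame":
        return Frame(time=0.0, coords=self.positions,
                     velocities=np.zeros((self.n_beads, 3)))


@dataclass
class Frame:
    """One time-stamped snapshot. coords (N,3) in A; velocities A/ps."""

    time: float
    coords: np.ndarray
    velocities: np.ndarray | None = None
    window_id: int | str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.time < 0:
            raise ValidationError("frame time must be non-negative")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must have shape (N, 3)")


@dataclass
class Trajectory:
    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("trajectory must contain at least one frame")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# potential energy (reference NumPy path, used for validation and analysis)


def _pair_terms(system: ToySystem, coords: np.ndarray,
                idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    if system.repulsion is None or len(idx_a) == 0 or len(idx_b) == 0:
        return 0.0
    sigma, eps = system.repulsion.sigma, system.repulsion.epsilon
    d = np.linalg.norm(coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=-1)
    inside = d < sigma
    return float(np.sum(eps * (1.0 - d[inside] / sigma) ** 2))


def potential_energy(system: ToySystem, coords: np.ndarray) -> float:
    """Total potential energy (kcal/mol) of a coordinate set."""
    coords = np.asarray(coords, dtype=float)
    u = 0.0
    lig = system.ligand_indices
    if system.funnel is not None:
        r2 = np.sum((coords[lig] - system.site_center) ** 2, axis=1)
        u -= float(np.sum(system.funnel.depth
                          * np.exp(-0.5 * r2 / system.funnel.width ** 2)))
    if system.double_well is not None:
        dw = system.double_well
        x = coords[lig, 0]
        u += float(np.sum(dw.height * ((x ** 2 - dw.half_separation ** 2)
                                       / dw.half_separation ** 2) ** 2))
        u += float(np.sum(dw.transverse_k * (coords[lig, 1] ** 2 + coords[lig, 2] ** 2)))
    if system.repulsion is not None:
        roles = system.roles
        n = system.n_beads
        sigma, eps = system.repulsion.sigma, system.repulsion.epsilon
        for i in range(n):
            for j in range(i + 1, n):
                if roles[i] == 1 and roles[j] == 1:
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if d < sigma:
                    u += eps * (1.0 - d / sigma) ** 2
    if system.confinement is not None:
        conf = system.confinement
        center = system.site_center if conf.center is None else np.asarray(conf.center)
        for i in range(system.n_beads):
            if system.roles[i] == 1:
                continue
            radius = conf.radius if system.roles[i] == 0 else (
                conf.solvent_radius if conf.solvent_radius is not None else conf.radius)
            rho = float(np.linalg.norm(coords[i] - center))
            if rho > radius:
                u += conf.k * (rho - radius) ** 2
    if system.restraint_k > 0:
        rec = system.receptor_indices
        u += float(system.restraint_k
                   * np.sum((coords[rec] - system.positions[rec]) ** 2))
    return u


def interaction_energy(system: ToySystem, frame: Frame) -> float:
    """Ligand-receptor interaction energy (kcal/mol).

    Sum of the funnel-well terms (the toy's stand-in for the
    ligand-receptor attraction) and the ligand-receptor soft-core
    repulsion. Solvent terms and receptor-internal terms are excluded,
    mirroring an interaction-energy (MM/GBSA-like) decomposition.
    """
    coords = np.asarray(frame.coords, dtype=float)
    if coords.shape[0] != system.n_beads:
        raise ValidationError("frame bead count does not match system")
    u = 0.0
    lig = system.ligand_indices
    if system.funnel is not None:
        r2 = np.sum((coords[lig] - system.site_center) ** 2, axis=1)
        u -= float(np.sum(system.funnel.depth
                          * np.exp(-0.5 * r2 / system.funnel.width ** 2)))
    u += _pair_terms(system, coords, lig, system.receptor_indices)
    return u


def solvent_contact_count(system: ToySystem, frame: Frame,
                          shell: float = 4.0, hbond_dist: float = 3.5,
                          receptor_subset: Sequence[int] | None = None) -> int:
    """Count solvent beads bridging ligand and receptor.

    A solvent bead counts when it is simultaneously within ``shell`` of
    any receptor bead (optionally restricted to ``receptor_subset``)
    and within ``hbond_dist`` of any ligand bead — the toy analog of a
    water oxygen near the protein that hydrogen-bonds the ligand.
    Returns 0 when the system has no solvent beads.
    """
    sol = system.solvent_indices
    if len(sol) == 0:
        return 0
    rec = (np.asarray(receptor_subset, dtype=int)
           if receptor_subset is not None and len(receptor_subset) > 0
           else system.receptor_indices)
    lig = system.ligand_indices
    coords = np.asarray(frame.coords, dtype=float)
    d_rec = np.linalg.norm(coords[sol][:, None, :] - coords[rec][None, :, :], axis=-1)
    d_lig = np.linalg.norm(coords[sol][:, None, :] - coords[lig][None, :, :], axis=-1)
    near_rec = (d_rec < shell).any(axis=1)
    near_lig = (d_lig < hbond_dist).any(axis=1)
    return int(np.count_nonzero(near_rec & near_lig))


def ligand_site_distance(system: ToySystem, coords: np.ndarray,
                         mass_weighted: bool = False) -> float:
    """Distance (A) between the ligand center and the site center.

    Geometric center by default; center of mass when ``mass_weighted``.
    """
    coords = np.asarray(coords, dtype=float)
    lig = system.ligand_indices
    if mass_weighted:
        w = system.masses[lig]
        center = np.average(coords[lig], axis=0, weights=w)
    else:
        center = coords[lig].mean(axis=0)
    return float(np.linalg.norm(center - system.site_center))


# ---------------------------------------------------------------------------
# velocity resampling


def resample_velocities(state: Frame, temperature: float,
                        masses: Iterable[float], seed: int) -> Frame:
    """Redraw velocities from the Maxwell-Boltzmann distribution.

    Coordinates are untouched; each velocity component of bead i is
    drawn N(0, kB*T/m_i) (internal units). At T = 0 all velocities are
    exactly zero.
    """
    masses = np.asarray(list(masses), dtype=float)
    if np.any(masses <= 0):
        raise ValidationError("masses must be positive")
    n = state.coords.shape[0]
    if masses.shape[0] != n:
        raise ValidationError("mass count does not match frame bead count")
    rng = np.random.Generator(np.random.PCG64(seed))
    if temperature == 0:
        vel = np.zeros((n, 3))
    else:
        sigma = np.sqrt(kbt_internal(temperature) / masses)
        vel = rng.standard_normal((n, 3)) * sigma[:, None]
    return Frame(time=state.time, coords=state.coords.copy(),
                 velocities=vel, window_id=state.window_id)


# ---------------------------------------------------------------------------
# Langevin dynamics


def _kernel_args(system: ToySystem):
    zeros3 = np.zeros(3)
    funnel = system.funnel
    rep = system.repulsion
    conf = system.confinement
    dw = system.double_well
    conf_center = zeros3
    conf_r_lig = 0.0
    conf_r_sol = 0.0
    conf_k = 0.0
    if conf is not None:
        conf_center = (system.site_center if conf.center is None
                       else np.asarray(conf.center, dtype=float))
        conf_r_lig = conf.radius
        conf_r_sol = conf.solvent_radius if conf.solvent_radius is not None else conf.radius
        conf_k = conf.k
    return dict(
        site_center=system.site_center,
        funnel_depth=0.0 if funnel is None else funnel.depth,
        funnel_width=1.0 if funnel is None else funnel.width,
        rep_sigma=1.0 if rep is None else rep.sigma,
        rep_eps=0.0 if rep is None else rep.epsilon,
        conf_center=conf_center,
        conf_radius_lig=conf_r_lig,
        conf_radius_sol=conf_r_sol,
        conf_k=conf_k,
        dw_height=0.0 if dw is None else dw.height,
        dw_half_sep=1.0 if dw is None else dw.half_separation,
        dw_transverse_k=0.0 if dw is None else dw.transverse_k,
        restraint_k=system.restraint_k,
        restraint_ref=system.positions,
    )


def _check_commensurate(duration: float, save_interval: float, timestep: float):
    n_frames = duration / save_interval
    if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 1:
        raise ValidationError(
            f"duration {duration} ps is not a positive integer multiple of "
            f"save_interval {save_interval} ps")
    n_sub = save_interval / timestep
    if abs(n_sub - round(n_sub)) > 1e-9 or round(n_sub) < 1:
        raise ValidationError(
            f"save_interval {save_interval} ps is not a positive integer "
            f"multiple of timestep {timestep} ps")
    return int(round(n_frames)), int(round(n_sub))


def langevin_run(system: ToySystem, state: Frame, duration: float,
                 save_interval: float, seed: int,
                 window_id: int | str | None = None,
                 _bias_grid=None) -> Trajectory:
    """Run BAOAB Langevin dynamics from ``state``.

    Returns ``duration/save_interval`` frames saved every
    ``save_interval`` ps (the starting frame is not included). The run
    is bit-reproducible for a fixed seed. Receptor beads stay fixed
    unless the system defines a positional restraint.
    """
    n_frames, steps_per_save = _check_commensurate(
        duration, save_interval, system.timestep)
    n = system.n_beads
    if state.coords.shape[0] != n:
        raise ValidationError("frame bead count does not match system")
    pos = state.coords.copy()
    vel = (state.velocities.copy() if state.velocities is not None
           else np.zeros((n, 3)))
    roles = system.roles
    mobile = system.mobile_mask
    masses = system.masses
    acc_scale = KCAL_TO_INTERNAL / masses
    dt = system.timestep
    c_fric = float(np.exp(-system.friction * dt))
    kbt = kbt_internal(system.temperature)
    c_noise = np.sqrt(kbt / masses) * np.sqrt(1.0 - c_fric ** 2)
    kw = _kernel_args(system)
    if _bias_grid is None:
        bias_on = False
        grid_dv = np.zeros(2)
        grid_x0, grid_dx = 0.0, 1.0
    else:
        bias_on = True
        grid_dv, grid_x0, grid_dx = _bias_grid

    rng = np.random.Generator(np.random.PCG64(seed))
    frames: list[Frame] = []
    for k in range(n_frames):
        noise = rng.standard_normal((steps_per_save, n, 3))
        status = _kernels._baoab_chunk(
            pos, vel, roles, mobile, acc_scale, steps_per_save, dt,
            c_fric, c_noise, noise,
            kw["site_center"], kw["funnel_depth"], kw["funnel_width"],
            kw["rep_sigma"], kw["rep_eps"],
            kw["conf_center"], kw["conf_radius_lig"], kw["conf_radius_sol"],
            kw["conf_k"], kw["dw_height"], kw["dw_half_sep"],
            kw["dw_transverse_k"], kw["restraint_k"], kw["restraint_ref"],
            bias_on, grid_dv, grid_x0, grid_dx)
        if status != 0:
            global_step = k * steps_per_save + status
            raise IntegrationError(
                f"integration blew up at step {global_step} "
                f"(frame {k})", global_step)
        frames.append(Frame(time=state.time + (k + 1) * save_interval,
                            coords=pos.copy(), velocities=vel.copy(),
                            window_id=window_id))
    return Trajectory(frames=frames, metadata={
        "engine": "langevin-baoab", "seed": int(seed),
        "config_hash": system.fingerprint(),
        "save_interval": save_interval,
    })


class DynamicsEngine(Protocol):
    """Contract the supervision machinery relies on."""

    def run(self, system: ToySystem, state: Frame, duration: float,
            save_interval: float, seed: int,
            window_id: int | str | None = None) -> Trajectory: ...

    def resample(self, system: ToySystem, state: Frame, seed: int) -> Frame: ...


class LangevinEngine:
    """The bundled toy engine: BAOAB Langevin dynamics on ToySystem."""

    name = "langevin-baoab"

    def run(self, system: ToySystem, state: Frame, duration: float,
            save_interval: float, seed: int,
            window_id: int | str | None = None) -> Trajectory:
        return langevin_run(system, state, duration, save_interval, seed,
                            window_id=window_id)

    def run_biased(self, system: ToySystem, state: Frame, duration: float,
                   save_interval: float, seed: int, bias_grid,
                   window_id: int | str | None = None) -> Trajectory:
        """Like :meth:`run` but with a 1D CV bias force (metadynamics)."""
        return langevin_run(system, state, duration, save_interval, seed,
                            window_id=window_id, _bias_grid=bias_grid)

    def resample(self, system: ToySystem, state: Frame, seed: int) -> Frame:
        return resample_velocities(state, system.temperature,
                                   system.masses, seed)


# ---------------------------------------------------------------------------
# config-driven construction


_SYSTEM_KEYS = {
    "beads", "site_center", "temperature", "friction", "timestep",
    "funnel", "repulsion", "confinement", "double_well", "restraint_k",
}


def build_toy_system(config: dict) -> ToySystem:
    """Build and validate a ToySystem from a key-value configuration.

    The config maps directly onto the dataclass fields; ``beads`` is a
    list of ``{id, role, mass, position}`` mappings. Unknown keys are
    rejected. Deterministic: the same config always yields systems with
    the same fingerprint.
    """
    unknown = set(config) - _SYSTEM_KEYS
    if unknown:
        raise ValidationError(f"unknown system config keys: {sorted(unknown)}")
    if "beads" not in config:
        raise ValidationError("system config must define 'beads'")
    if "site_center" not in config:
        raise ValidationError("system config must define 'site_center'")
    beads = []
    for i, spec in enumerate(config["beads"]):
        for key in ("role", "mass", "position"):
            if key not in spec:
                raise ValidationError(f"bead {i}: missing '{key}'")
        beads.append(Bead(id=str(spec.get("id", i)), role=spec["role"],
                          mass=float(spec["mass"]),
                          position=np.asarray(spec["position"], dtype=float)))
    def _sub(cls, key):
        if key not in config or config[key] is None:
            return None
        val = dict(config[key])
        if "center" in val and val["center"] is not None:
            val["center"] = np.asarray(val["center"], dtype=float)
        return cls(**val)

    return ToySystem(
        beads=beads,
        site_center=np.asarray(config["site_center"], dtype=float),
        temperature=float(config.get("temperature", 300.0)),
        friction=float(config.get("friction", 10.0)),
        timestep=float(config.get("timestep", 0.01)),
        funnel=_sub(FunnelWell, "funnel"),
        repulsion=_sub(Repulsion, "repulsion"),
        confinement=_sub(Confinement, "confinement"),
        double_well=_sub(DoubleWell, "double_well"),
        restraint_k=float(config.get("restraint_k", 0.0)),
    )
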