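"""Supervised MD (SuMD) proper: windowed simulation with tabu-like
slope acceptance, adaptive window scheduling for unbinding, and
termination criteria.

The algorithm runs a series of short unbiased MD windows. After each
window the supervised observables, sampled at regular intervals, are
fitted to a linear function of time. For binding, a window is
productive when the ligand-site distance slope is negative; the next
window then continues from the last coordinates and velocities.
Otherwise the window is discarded and the simulation restarts from the
last accepted state with freshly drawn Maxwell-Boltzmann velocities
(the tabu-like rule). Unbinding uses a double supervision — the
ligand-site distance and the number of bridging solvent beads must
both trend upward — and grows the window length along the pathway
according to a three-threshold schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .engine import (
    DynamicsEngine,
    Frame,
    LangevinEngine,
    ToySystem,
    Trajectory,
    ValidationError,
    ligand_site_distance,
    solvent_contact_count,
)

METRIC_SITE_DISTANCE = "site_distance"
METRIC_BRIDGING_SOLVENT = "bridging_solvent"


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class SupervisionConfig:
    """All SuMD control parameters.

    window_length is the (initial) window Δt in ps; binding default
    500 ps with samples every 50 ps and a 4 A termination threshold.
    For unbinding the defaults add the bridging-solvent metric and a
    3.5 A no-contact termination cutoff.
    """

    direction: str = "binding"
    window_length: float = 500.0
    save_interval: float = 50.0
    metrics: tuple[str, ...] | None = None
    distance_threshold: float = 4.0
    contact_cutoff: float = 3.5
    solvent_shell: float = 4.0
    solvent_hbond_dist: float = 3.5
    mass_weighted: bool = False
    max_windows: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.direction not in ("binding", "unbinding"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.metrics is None:
            self.metrics = ((METRIC_SITE_DISTANCE,) if self.direction == "binding"
                            else (METRIC_SITE_DISTANCE, METRIC_BRIDGING_SOLVENT))
        self.metrics = tuple(self.metrics)
        n = self.window_length / self.save_interval
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValidationError(
                "window_length must be a multiple of save_interval with at "
                "least 2 samples per window (a slope needs >= 2 points)")
        if self.max_windows < 1:
            raise ValidationError("max_windows must be >= 1")


@dataclass
class UnbindingSchedule:
    """Adaptive window-length schedule for unbinding.

    The window length is dt0 * Nt_i where Nt_i is picked from
    {1, nt1, nt2, nt3} by comparing the last end-of-window
    ligand-protein distance r_L with the thresholds d1 < d2 < d3.
    Defaults: dt0 = 300 ps, multipliers 3, 6, 10, thresholds 5, 8, 10 A.
    """

    dt0: float = 300.0
    nt1: int = 3
    nt2: int = 6
    nt3: int = 10
    d1: float = 5.0
    d2: float = 8.0
    d3: float = 10.0

    def __post_init__(self):
        if not (self.dt0 > 0 and self.nt1 > 0 and self.nt2 > 0 and self.nt3 > 0):
            raise ValidationError("schedule dt0 and multipliers must be positive")
        if not (self.nt1 <= self.nt2 <= self.nt3):
            raise ValidationError("schedule multipliers must satisfy nt1 <= nt2 <= nt3")
        if not (0 < self.d1 < self.d2 < self.d3):
            raise ValidationError("schedule thresholds must satisfy 0 < d1 < d2 < d3")


@dataclass
class WindowRecord:
    window_id: int
    start_frame_id: int  # index into the accepted trajectory; -1 = initial frame
    dt: float
    samples: dict[str, tuple[list[float], list[float]]]
    slopes: dict[str, float]
    accepted: bool
    r_end: float

    def to_json(self) -> str:
        payload = {
            "window_id": self.window_id,
            "start_frame_id": self.start_frame_id,
            "dt": self.dt,
            "samples": {k: [list(t), list(v)] for k, (t, v) in self.samples.items()},
            "slopes": self.slopes,
            "accepted": self.accepted,
            "r_end": self.r_end,
        }
        return json.dumps(payload)


@dataclass
class SuMDResult:
    trajectory: Trajectory | None
    windows: list[WindowRecord]
    restart_count: int
    termination_reason: str  # "criterion_met" | "max_windows"
    final_state: Frame

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def total_simulated_time(self) -> float:
        """Simulated time over ALL windows, accepted and rejected (ps)."""
        return float(sum(w.dt for w in self.windows))


# ---------------------------------------------------------------------------
# elementary operations


def fit_slope(times, values) -> float:
    """Ordinary least-squares slope of ``values`` against ``times``.

    The supervision stream is a short series of observable samples at
    regular time intervals; its linear trend decides window acceptance.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValidationError("times and values must be 1D of equal length")
    if t.size < 2:
        raise ValidationError("slope fit needs at least 2 points")
    if np.ptp(t) == 0:
        raise ValidationError("times are degenerate (all equal)")
    if np.ptp(v) == 0:
        return 0.0  # constant series: exactly flat
    return float(np.polyfit(t, v, 1)[0])


def schedule_window_length(r_l: float, schedule: UnbindingSchedule) -> float:
    """Window length Δt = dt0 * Nt_i for the current distance r_L.

    Branches (boundaries belong to the ``<=`` side):
    r_L <= d1 -> 1; d1 < r_L <= d2 -> nt1; d2 < r_L <= d3 -> nt2;
    r_L > d3 -> nt3.
    """
    if r_l < 0:
        raise ValidationError("r_L must be non-negative")
    if r_l <= schedule.d1:
        nt = 1
    elif r_l <= schedule.d2:
        nt = schedule.nt1
    elif r_l <= schedule.d3:
        nt = schedule.nt2
    else:
        nt = schedule.nt3
    return schedule.dt0 * nt


def classify_window(slopes, direction: str) -> bool:
    """Tabu-like acceptance: binding wants the supervised distance to
    fall (slope < 0), unbinding wants every supervised series to rise
    (all slopes > 0). A slope of exactly 0 is non-productive in both
    directions (no progress)."""
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    if slopes.size < 1:
        raise ValidationError("need at least one slope")
    if direction == "binding":
        return bool(np.all(slopes < 0))
    if direction == "unbinding":
        return bool(np.all(slopes > 0))
    raise ValidationError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# metric evaluation


def _metric_value(name: str, system: ToySystem, frame: Frame,
                  config: SupervisionConfig,
                  partner_set: np.ndarray | None) -> float:
    if name == METRIC_SITE_DISTANCE:
        return ligand_site_distance(system, frame.coords,
                                    mass_weighted=config.mass_weighted)
    if name == METRIC_BRIDGING_SOLVENT:
        return float(solvent_contact_count(
            system, frame, shell=config.solvent_shell,
            hbond_dist=config.solvent_hbond_dist,
            receptor_subset=partner_set))
    raise ValidationError(f"unknown supervised metric {name!r}")


def min_ligand_receptor_distance(system: ToySystem, frame: Frame) -> float:
    """Minimum over all ligand-receptor bead pairs of the distance (A)."""
    coords = np.asarray(frame.coords, dtype=float)
    lig, rec = system.ligand_indices, system.receptor_indices
    d = np.linalg.norm(coords[lig][:, None, :] - coords[rec][None, :, :], axis=-1)
    return float(d.min())


def _update_partner_set(system: ToySystem, frame: Frame, cutoff: float,
                        previous: np.ndarray | None) -> np.ndarray | None:
    """Re-detect the receptor beads interacting with the ligand.

    Toy analog of re-detecting the protein atoms hydrogen-bonded (or,
    failing that, in van der Waals contact) with the ligand after each
    productive window: all receptor beads within the contact cutoff of
    any ligand bead; when none qualify the previous set is retained.
    """
    coords = np.asarray(frame.coords, dtype=float)
    lig, rec = system.ligand_indices, system.receptor_indices
    d = np.linalg.norm(coords[rec][:, None, :] - coords[lig][None, :, :], axis=-1)
    hit = rec[(d < cutoff).any(axis=1)]
    if hit.size == 0:
        return previous
    return hit


def _window_seeds(root_seed: int, window_index: int) -> tuple[int, int]:
    """Independent, reproducible per-window seeds from one root seed."""
    ss = np.random.SeedSequence(entropy=root_seed,
                                spawn_key=(window_index,))
    run_seed, vel_seed = ss.generate_state(2, dtype=np.uint32)
    return int(run_seed), int(vel_seed)


# ---------------------------------------------------------------------------
# the SuMD drivers


def _run_supervised(engine: DynamicsEngine, system: ToySystem, start: Frame,
                    config: SupervisionConfig,
                    schedule: UnbindingSchedule | None,
                    log: Callable[[str], None] | None = None) -> SuMDResult:
    direction = config.direction
    state = start
    last_accepted = start
    accepted_frames: list[Frame] = []
    records: list[WindowRecord] = []
    restarts = 0
    partner_set: np.ndarray | None = None
    reason = "max_windows"
    r_l = _metric_value(METRIC_SITE_DISTANCE, system, start, config, None)
    if direction == "unbinding":
        partner_set = _update_partner_set(system, start, config.contact_cutoff, None)

    for w in range(config.max_windows):
        if direction == "unbinding":
            # the very first window runs for dt0; afterwards the length
            # adapts to the r_L of the last productive window
            dt = schedule.dt0 if w == 0 else schedule_window_length(r_l, schedule)
        else:
            dt = config.window_length
        run_seed, vel_seed = _window_seeds(config.seed, w)
        traj = engine.run(system, state, dt, config.save_interval,
                          run_seed, window_id=w)
        samples: dict[str, tuple[list[float], list[float]]] = {}
        slopes: dict[str, float] = {}
        for name in config.metrics:
            times = [f.time for f in traj.frames]
            values = [_metric_value(name, system, f, config, partner_set)
                      for f in traj.frames]
            samples[name] = (times, values)
            slopes[name] = fit_slope(times, values)
        accepted = classify_window([slopes[m] for m in config.metrics], direction)
        end_frame = traj.frames[-1]
        end_distance = _metric_value(METRIC_SITE_DISTANCE, system, end_frame,
                                     config, None)
        records.append(WindowRecord(
            window_id=w,
            start_frame_id=len(accepted_frames) - 1,
            dt=dt, samples=samples, slopes=slopes,
            accepted=accepted, r_end=end_distance))
        if log is not None:
            log(f"window {w}: dt={dt:g} ps slopes="
                f"{[round(slopes[m], 5) for m in config.metrics]} "
                f"accepted={accepted} r_end={end_distance:.3f} A")
        if accepted:
            accepted_frames.extend(traj.frames)
            state = end_frame
            last_accepted = end_frame
            r_l = end_distance
            if direction == "binding":
                if end_distance < config.distance_threshold:
                    reason = "criterion_met"
                    break
            else:
                partner_set = _update_partner_set(
                    system, end_frame, config.contact_cutoff, partner_set)
                if min_ligand_receptor_distance(system, end_frame) >= config.contact_cutoff:
                    reason = "criterion_met"
                    break
        else:
            restarts += 1
            state = engine.resample(system, last_accepted, vel_seed)

    trajectory = (Trajectory(frames=accepted_frames,
                             metadata={"direction": direction,
                                       "seed": config.seed,
                                       "config_hash": system.fingerprint()})
                  if accepted_frames else None)
    return SuMDResult(trajectory=trajectory, windows=records,
                      restart_count=restarts, termination_reason=reason,
                      final_state=last_accepted)


def run_sumd_binding(engine: DynamicsEngine, system: ToySystem, start: Frame,
                     config: SupervisionConfig,
                     log: Callable[[str], None] | None = None) -> SuMDResult:
    """SuMD binding: fixed-length windows until the supervised
    ligand-site distance at the end of an accepted window falls below
    the termination threshold (default 4 A)."""
    if config.direction != "binding":
        raise ValidationError("config.direction must be 'binding'")
    return _run_supervised(engine, system, start, config, None, log=log)


def run_sumd_unbinding(engine: DynamicsEngine, system: ToySystem, start: Frame,
                       config: SupervisionConfig,
                       schedule: UnbindingSchedule | None = None,
                       log: Callable[[str], None] | None = None) -> SuMDResult:
    """SuMD unbinding with double supervision and adaptive windows.

    The start frame must be a bound configuration (at least one
    ligand-receptor pair within the contact cutoff). Each window's
    length comes from the schedule applied to the distance r_L at the
    end of the previous productive window; termination fires when the
    final frame has no ligand-receptor contact.
    """
    if config.direction != "unbinding":
        raise ValidationError("config.direction must be 'unbinding'")
    if schedule is None:
        schedule = UnbindingSchedule()
    if min_ligand_receptor_distance(system, start) >= config.contact_cutoff:
        raise ValidationError(
            "start frame is not bound: no ligand-receptor contact at "
            f"{config.contact_cutoff} A")
    return _run_supervised(engine, system, start, config, schedule, log=log)


# ---------------------------------------------------------------------------
# supervision-efficacy benchmark


def binding_efficacy_benchmark(system: ToySystem, start: Frame,
                               config: SupervisionConfig, n_seeds: int = 20,
                               engine: DynamicsEngine | None = None) -> dict:
    """Compare integration steps to binding for SuMD vs plain MD.

    For each seed, run SuMD binding and count integration steps over
    all windows (accepted and rejected). Then run one unsupervised
    Langevin trajectory with the same total step budget, observing the
    supervised distance at the same save interval, and record the first
    passage below the termination threshold (the full budget when it
    never binds). Returns the per-seed step counts, medians and their
    ratio.
    """
    if engine is None:
        engine = LangevinEngine()
    dt = system.timestep
    sumd_steps = []
    for s in range(n_seeds):
        cfg = SupervisionConfig(**{**config.__dict__, "seed": config.seed + s,
                                   "metrics": config.metrics})
        res = run_sumd_binding(engine, system, start, cfg)
        sumd_steps.append(int(round(res.total_simulated_time() / dt)))
    # every unsupervised run gets the same total budget: the largest
    # supervised run (so no method ever receives more compute)
    budget_time = max(sumd_steps) * dt
    cmd_steps = []
    for s in range(n_seeds):
        state = start
        elapsed = 0.0
        reached = None
        chunk = config.save_interval
        rng_seed = _window_seeds(10_000_019 + config.seed + s, 0)[0]
        while elapsed + chunk <= budget_time + 1e-9:
            traj = engine.run(system, state, chunk, chunk,
                              seed=(rng_seed + int(elapsed / chunk)) & 0x7FFFFFFF)
            state = traj.frames[-1]
            elapsed += chunk
            d = ligand_site_distance(system, state.coords,
                                     mass_weighted=config.mass_weighted)
            if d < config.distance_threshold:
                reached = elapsed
                break
        cmd_steps.append(int(round((reached if reached is not None
                                    else budget_time) / dt)))
    med_s = float(np.median(sumd_steps))
    med_c = float(np.median(cmd_steps))
    return {
        "sumd_steps": sumd_steps,
        "cmd_steps": cmd_steps,
        "median_sumd": med_s,
        "median_cmd": med_c,
        "ratio": med_s / med_c if med_c > 0 else float("inf"),
    }
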