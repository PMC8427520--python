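"""SuMD path sampling.

An adaptive (supervised) trajectory over-represents progress and
under-represents metastable dwelling. To relax that bias, the
trajectory is clustered by ligand RMSD to its starting positions in
fixed-width bins (1 A by default, after superposing each frame on the
receptor), one frame is drawn at random from each bin, and an
unsupervised simulation is launched from every drawn frame with
freshly resampled velocities. Downstream analysis then uses only these
unsupervised trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import superpose
from .engine import (
    DynamicsEngine,
    Frame,
    ToySystem,
    Trajectory,
    ValidationError,
)


@dataclass
class RmsdBinning:
    """Frames grouped by ligand RMSD to the reference (first) frame.

    bin index = floor(RMSD / bin_width); intervals are half-open
    [k*w, (k+1)*w).
    """

    reference_frame_id: int
    bin_width: float
    bins: dict[int, list[int]] = field(default_factory=dict)
    rmsd_values: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return sum(len(v) for v in self.bins.values())


def ligand_rmsd_to_start(traj: Trajectory, ligand_selection,
                         alignment_selection) -> np.ndarray:
    """Ligand RMSD of every frame to the first frame, after aligning
    each frame on ``alignment_selection`` (receptor beads in the toy)."""
    lig = np.asarray(ligand_selection, dtype=int)
    align = np.asarray(alignment_selection, dtype=int)
    if lig.size == 0 or align.size == 0:
        raise ValidationError("ligand and alignment selections must be non-empty")
    ref = traj.frames[0].coords
    out = np.empty(len(traj.frames))
    for i, frame in enumerate(traj.frames):
        coords = frame.coords
        if align.size >= 3:
            rot, trans, _ = superpose(coords[align], ref[align])
            moved = coords @ rot.T + trans
        else:
            # too few alignment beads for a unique rotation: translate only
            moved = coords - coords[align].mean(axis=0) + ref[align].mean(axis=0)
        diff = moved[lig] - ref[lig]
        out[i] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return out


def bin_frames_by_rmsd(traj: Trajectory, ligand_selection,
                       alignment_selection,
                       bin_width: float = 1.0) -> RmsdBinning:
    """Cluster frames into half-open ligand-RMSD bins of ``bin_width`` A."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    rmsd = ligand_rmsd_to_start(traj, ligand_selection, alignment_selection)
    bins: dict[int, list[int]] = {}
    for i, r in enumerate(rmsd):
        k = int(np.floor(r / bin_width))
        bins.setdefault(k, []).append(i)
    return RmsdBinning(reference_frame_id=0, bin_width=bin_width,
                       bins=bins, rmsd_values=rmsd)


def seed_path_sampling(binning: RmsdBinning, traj: Trajectory,
                       engine: DynamicsEngine, system: ToySystem,
                       run_length: float, seed: int,
                       save_interval: float | None = None,
                       ) -> tuple[list[Trajectory], dict[int, int]]:
    """Launch one unsupervised run per RMSD bin.

    One frame is drawn uniformly from each non-empty bin (reproducibly
    from ``seed``), its velocities are resampled at the system
    temperature, and an engine run of ``run_length`` ps starts from it.
    Returns the trajectories (first frame = the selected source frame)
    and the bin -> source-frame-id manifest.
    """
    if binning.n_frames != len(traj.frames):
        raise ValidationError("binning was not built from this trajectory")
    save = save_interval if save_interval is not None else run_length / 10.0
    rng = np.random.Generator(np.random.PCG64(seed))
    trajectories: list[Trajectory] = []
    manifest: dict[int, int] = {}
    for k in sorted(binning.bins):
        frame_ids = binning.bins[k]
        chosen = int(frame_ids[rng.integers(len(frame_ids))])
        manifest[k] = chosen
        source = traj.frames[chosen]
        child_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(k,)).generate_state(1, dtype=np.uint32)[0])
        state = engine.resample(
            system,
            Frame(time=0.0, coords=source.coords.copy(), window_id=f"bin{k}"),
            child_seed)
        out = engine.run(system, state, run_length, save, child_seed + 1,
                         window_id=f"bin{k}")
        frames = [state] + list(out.frames)
        trajectories.append(Trajectory(frames=frames, metadata={
            **out.metadata, "source_frame": chosen, "bin": k}))
    return trajectories, manifest
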