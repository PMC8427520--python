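"""Trajectory-analysis operators.

Geometric interaction detectors (contacts, hydrogen bonds), their
persistency over merged replicas, least-squares superposition and
RMSD, voxelized solvent-occupancy ("hydrated spot") maps, and 2-CV
interaction-energy landscapes.

Conventions: a contact is a cross-group atom pair strictly closer than
the cutoff (default 3.5 A). A hydrogen bond requires donor-acceptor
distance <= 3.5 A and a D-H...A angle (measured at the hydrogen)
>= 120 degrees. Persistency is the percentage of frames, pooled over
all replicas, in which a residue/bead forms at least one qualifying
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .constants import KB
from .engine import Trajectory, ValidationError


# ---------------------------------------------------------------------------
# superposition and RMSD


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: Sequence[int] | None = None,
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation 3x3, translation 3-vector, rmsd) such that
    ``mobile @ R.T + t`` best matches the reference over the selection
    (all points by default). The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        m, r = mobile[sel], reference[sel]
    else:
        m, r = mobile, reference
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValidationError("selections must be equal-length (N, 3) arrays")
    if m.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 points")
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    if np.linalg.matrix_rank(m0, tol=1e-10) < 2:
        raise ValidationError("degenerate (collinear) selection: rotation "
                              "is not unique")
    rot, _ = Rotation.align_vectors(r0, m0)
    rotation = rot.as_matrix()
    translation = rc - rotation @ mc
    # recompute the residual directly: the rssd returned by
    # align_vectors loses precision for near-perfect fits
    resid = m @ rotation.T + translation - r
    rmsd_val = np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))
    return rotation, translation, float(rmsd_val)


def rmsd(coords: np.ndarray, reference: np.ndarray,
         selection: Sequence[int] | None = None, fit: bool = False,
         fit_selection: Sequence[int] | None = None) -> float:
    """Root-mean-square deviation (A), optionally after a rigid fit.

    The fit may use a different selection than the measurement (e.g.
    align on the receptor, measure the ligand).
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise ValidationError("coords and reference shapes differ")
    if fit:
        fsel = fit_selection if fit_selection is not None else selection
        rot, trans, _ = superpose(coords, reference, fsel)
        coords = coords @ rot.T + trans
    sel = np.asarray(selection, dtype=int) if selection is not None else slice(None)
    diff = coords[sel] - reference[sel]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


# ---------------------------------------------------------------------------
# interaction detectors


def detect_contacts(coords: np.ndarray, group_a: Sequence[int],
                    group_b: Sequence[int],
                    cutoff: float = 3.5) -> set[tuple[int, int]]:
    """All cross-group pairs with interatomic distance strictly < cutoff."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValidationError("contact groups must be disjoint")
    if a.size == 0 or b.size == 0:
        return set()
    coords = np.asarray(coords, dtype=float)
    d = cdist(coords[a], coords[b])
    ii, jj = np.nonzero(d < cutoff)
    return {(int(a[i]), int(b[j])) for i, j in zip(ii, jj)}


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond cut-offs: donor-acceptor distance (A)
    and D-H...A angle (degrees, measured at the hydrogen)."""

    distance: float = 3.5
    angle: float = 120.0

    def __post_init__(self):
        if self.distance <= 0 or self.angle <= 0:
            raise ValidationError("hbond cutoffs must be positive")
        if self.angle > 180:
            raise ValidationError("hbond angle cutoff cannot exceed 180 deg")


def detect_hbonds(coords: np.ndarray, hydrogen_to_donor: dict[int, int],
                  acceptors: Sequence[int],
                  criteria: HBondCriteria | None = None,
                  ) -> list[tuple[int, int, int]]:
    """Hydrogen bonds as (donor, hydrogen, acceptor) triples.

    A triple qualifies when the donor-acceptor distance is <= the
    distance cutoff and the D-H...A angle is >= the angle cutoff.
    ``hydrogen_to_donor`` maps each polar hydrogen to its covalently
    attached donor heavy atom.
    """
    if criteria is None:
        criteria = HBondCriteria()
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    out: list[tuple[int, int, int]] = []
    for h, d in hydrogen_to_donor.items():
        if d is None or not (0 <= d < n):
            raise ValidationError(f"hydrogen {h} has no valid donor")
        for a in acceptors:
            if a == d or a == h:
                continue
            if np.linalg.norm(coords[d] - coords[a]) > criteria.distance:
                continue
            v1 = coords[d] - coords[h]
            v2 = coords[a] - coords[h]
            cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
            if angle >= criteria.angle:
                out.append((int(d), int(h), int(a)))
    return out


# ---------------------------------------------------------------------------
# persistency over merged replicas


def persistency(trajectories: Iterable[Trajectory],
                extractor: Callable[[np.ndarray], Iterable],
                interaction_type: str = "contact") -> pd.DataFrame:
    """Percentage of pooled frames in which each id interacts.

    ``extractor(coords)`` returns the ids (residues/beads) with at
    least one qualifying interaction in that frame. All replicas are
    merged: the denominator is the total frame count across the list.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    n_beads = trajectories[0].frames[0].coords.shape[0]
    for t in trajectories:
        if t.frames[0].coords.shape[0] != n_beads:
            raise ValidationError("trajectories do not share a topology")
    counts: dict = {}
    total = 0
    for traj in trajectories:
        for frame in traj.frames:
            total += 1
            for rid in set(extractor(frame.coords)):
                counts[rid] = counts.get(rid, 0) + 1
    rows = [{"id": rid, "interaction": interaction_type,
             "percent": 100.0 * c / total, "n_frames_total": total}
            for rid, c in sorted(counts.items(), key=lambda kv: str(kv[0]))]
    return pd.DataFrame(rows, columns=["id", "interaction", "percent",
                                       "n_frames_total"])


# ---------------------------------------------------------------------------
# solvent-occupancy (hydrated spot) maps


@dataclass
class OccupancyGrid:
    """AquaMMapS-style voxel map of solvent occupancy.

    occupancy[i,j,k] is the fraction of frames with at least one
    solvent bead inside voxel (i,j,k).
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray  # 3D, values in [0, 1]
    n_frames: int

    def hydrated_spots(self, threshold: float = 0.5) -> np.ndarray:
        """Voxel indices with occupancy above ``threshold``."""
        return np.argwhere(self.occupancy > threshold)

    def to_dx(self) -> str:
        """OpenDX-style scalar grid text."""
        nx, ny, nz = self.occupancy.shape
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            "origin {:.6f} {:.6f} {:.6f}".format(*self.origin),
            f"delta {self.spacing:.6f} 0.0 0.0",
            f"delta 0.0 {self.spacing:.6f} 0.0",
            f"delta 0.0 0.0 {self.spacing:.6f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
        ]
        flat = self.occupancy.ravel(order="C")
        for i in range(0, flat.size, 3):
            lines.append(" ".join(f"{v:.6f}" for v in flat[i:i + 3]))
        lines.append('attribute "dep" string "positions"')
        return "\n".join(lines) + "\n"


def water_occupancy(trajectories: Iterable[Trajectory],
                    solvent_selection: Sequence[int],
                    region: tuple[Sequence[float], Sequence[float]],
                    spacing: float = 1.0,
                    align_selection: Sequence[int] | None = None,
                    ) -> OccupancyGrid:
    """Per-voxel fraction of frames containing a solvent bead.

    ``region`` is (lower corner, upper corner) in A. When
    ``align_selection`` is given, every frame is first superposed on
    the first frame of the first trajectory over that selection
    (receptor beads, typically); otherwise frames are assumed
    pre-aligned.
    """
    trajectories = list(trajectories)
    sol = np.asarray(solvent_selection, dtype=int)
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValidationError("region upper corner must exceed lower corner")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    hits = np.zeros(tuple(dims), dtype=np.int64)
    reference = trajectories[0].frames[0].coords
    total = 0
    for traj in trajectories:
        for frame in traj.frames:
            coords = frame.coords
            if align_selection is not None:
                rot, trans, _ = superpose(coords, reference, align_selection)
                coords = coords @ rot.T + trans
            total += 1
            idx = np.floor((coords[sol] - lo) / spacing).astype(int)
            inside = np.all((idx >= 0) & (idx < dims), axis=1)
            occupied = np.unique(idx[inside], axis=0)
            for i, j, k in occupied:
                hits[i, j, k] += 1
    return OccupancyGrid(origin=lo, spacing=spacing,
                         occupancy=hits / max(total, 1), n_frames=total)


# ---------------------------------------------------------------------------
# 2-CV interaction-energy landscapes


@dataclass
class LandscapeMap:
    """2D binned map over two collective variables.

    count: frames per bin; mean_energy: average interaction energy of
    the member frames (NaN for empty bins); depth: -kB*T*ln(p) with p
    the bin probability (NaN for empty bins, which are flagged, not
    zero-energy).
    """

    cv1_edges: np.ndarray
    cv2_edges: np.ndarray
    count: np.ndarray
    mean_energy: np.ndarray
    depth: np.ndarray
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.count.shape[0]):
            for j in range(self.count.shape[1]):
                rows.append({
                    "cv1_lo": self.cv1_edges[i], "cv1_hi": self.cv1_edges[i + 1],
                    "cv2_lo": self.cv2_edges[j], "cv2_hi": self.cv2_edges[j + 1],
                    "count": int(self.count[i, j]),
                    "mean_energy": self.mean_energy[i, j],
                    "depth": self.depth[i, j],
                })
        return pd.DataFrame(rows)


def energy_landscape(cv1: Sequence[float], cv2: Sequence[float],
                     energy: Sequence[float],
                     bin_width: tuple[float, float] = (1.0, 1.0),
                     temperature: float = 300.0) -> LandscapeMap:
    """Bin frames on (cv1, cv2); per-bin mean interaction energy and
    occupancy depth -kB*T*ln(count/total)."""
    cv1 = np.asarray(cv1, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if not (cv1.shape == cv2.shape == energy.shape):
        raise ValidationError("cv1, cv2 and energy series must have equal length")
    w1, w2 = bin_width
    e1 = np.arange(np.floor(cv1.min() / w1) * w1,
                   np.floor(cv1.max() / w1) * w1 + 2 * w1, w1)
    e2 = np.arange(np.floor(cv2.min() / w2) * w2,
                   np.floor(cv2.max() / w2) * w2 + 2 * w2, w2)
    count, _, _ = np.histogram2d(cv1, cv2, bins=[e1, e2])
    esum, _, _ = np.histogram2d(cv1, cv2, bins=[e1, e2], weights=energy)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_energy = np.where(count > 0, esum / np.maximum(count, 1), np.nan)
        p = count / count.sum()
        depth = np.where(count > 0, -KB * temperature * np.log(
            np.where(p > 0, p, 1.0)), np.nan)
    return LandscapeMap(cv1_edges=e1, cv2_edges=e2, count=count,
                        mean_energy=mean_energy, depth=depth,
                        temperature=temperature)
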