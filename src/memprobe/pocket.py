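"""Binding-pocket statistics over structural trajectories.

Four independent measurements:

* grid flood-fill cavity volume — probe-accessible grid points reachable
  from a seed point inside an axis-aligned region;
* per-residue ligand contact occupancy — fraction of frames with at least
  one heavy-atom pair within a cutoff (default 6 Å);
* salt-bridge (or any donor–acceptor) minimum-distance traces with
  sub-threshold occupancy (default 3.5 Å, strict inequality);
* area per lipid from the simulation box, assuming two equal leaflets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .pdbio import StructureFrame, Trajectory

__all__ = [
    "VDW_RADII",
    "CavityConfig",
    "ContactOccupancy",
    "DistanceTrace",
    "LipidAreaSeries",
    "cavity_volume",
    "contact_occupancy",
    "salt_bridge_trace",
    "area_per_lipid",
]

#: van der Waals radii (Å) used for the probe-excluded cavity grid.
VDW_RADII: dict[str, float] = {
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "H": 1.2,
    "P": 1.8,
}
_DEFAULT_VDW = 1.7


@dataclass
class CavityConfig:
    """Grid definition for the flood-fill cavity volume.

    ``region`` is an axis-aligned box ((x_min, x_max), (y_min, y_max),
    (z_min, z_max)) in Å — typically a slab along the membrane normal with
    lateral bounds around the transport pathway. ``seed_point`` must lie
    inside the cavity of interest.
    """

    region: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    seed_point: tuple[float, float, float]
    grid_spacing: float = 1.0
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        for (lo, hi), s in zip(self.region, self.seed_point):
            if not lo < hi:
                raise ValueError("region bounds must satisfy min < max on every axis")
            if not lo <= s <= hi:
                raise ValueError("seed_point must lie inside region")


@dataclass
class ContactOccupancy:
    """Per-residue fraction of frames with a ligand contact within cutoff."""

    residue_numbers: np.ndarray
    fractions: np.ndarray  # pooled across replicas, frame-weighted
    per_replica: dict[str, np.ndarray]
    cutoff: float
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"residue": self.residue_numbers, "fraction": self.fractions})
        for rid, fr in self.per_replica.items():
            df[f"fraction_{rid}"] = fr
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


@dataclass
class DistanceTrace:
    """Per-frame minimum donor–acceptor distance with threshold occupancy."""

    distances: np.ndarray
    threshold: float
    occupancy: float  # fraction of frames strictly below threshold
    mean: float
    sd: float  # ddof = 1 over frames

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"frame": np.arange(len(self.distances)), "min_distance_A": self.distances}
        )
        df.to_csv(path, index=False, float_format="%.6f")
        with open(path, "a") as fh:
            fh.write(
                f"# occupancy(<{self.threshold:g} A)={self.occupancy:.6f} "
                f"mean={self.mean:.6f} sd={self.sd:.6f}\n"
            )


@dataclass
class LipidAreaSeries:
    """Per-frame area per lipid (Å²), assuming two equal leaflets."""

    areas: np.ndarray
    mean: float
    sd: float

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"frame": np.arange(len(self.areas)), "area_A2": self.areas})
        df.to_csv(path, index=False, float_format="%.6f")


def cavity_volume(frame: StructureFrame, cfg: CavityConfig) -> float:
    """Probe-accessible cavity volume (Å³) by seeded 6-connected flood fill.

    Grid points inside the region are free when farther than
    (vdW radius + probe radius) from every atom; the cavity is the free
    connected component containing the seed, and the volume is its point
    count times spacing³.
    """
    # cell-centered grid: each point represents one spacing³ voxel, so an
    # empty L³ region yields exactly (L/spacing)³ points
    axes = [
        np.arange(lo + 0.5 * cfg.grid_spacing, hi, cfg.grid_spacing)
        for lo, hi in cfg.region
    ]
    shape = tuple(len(a) for a in axes)
    if min(shape) == 0:
        raise ValueError("region produces an empty grid")
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    free = np.ones(points.shape[0], dtype=bool)
    if frame.n_atoms > 0:
        radii = np.array(
            [VDW_RADII.get(e, _DEFAULT_VDW) for e in frame.elements()], dtype=float
        )
        tree = cKDTree(points)
        for xyz, r in zip(frame.coords, radii):
            hit = tree.query_ball_point(xyz, r + cfg.probe_radius)
            free[hit] = False
    free = free.reshape(shape)

    seed_idx = tuple(
        int(np.argmin(np.abs(ax - s))) for ax, s in zip(axes, cfg.seed_point)
    )
    if not free[seed_idx]:
        raise ValueError("seed_point is occluded by an atom exclusion sphere")

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(free, structure=structure)
    cavity = labels == labels[seed_idx]
    return float(cavity.sum()) * cfg.grid_spacing**3


def _as_traj_list(trajs: Trajectory | Sequence[Trajectory]) -> list[Trajectory]:
    return [trajs] if isinstance(trajs, Trajectory) else list(trajs)


def contact_occupancy(
    trajs: Trajectory | Sequence[Trajectory],
    ligand_selection: Mapping[str, object],
    residue_set: Sequence[int],
    cutoff: float = 6.0,
    include_hydrogens: bool = False,
) -> ContactOccupancy:
    """Fraction of frames each residue contacts the ligand within ``cutoff``.

    A contact is at least one atom pair (residue atom, ligand atom) at a
    distance strictly below the cutoff; heavy atoms only unless
    ``include_hydrogens``. Multiple replicas are pooled frame-weighted
    (total contact frames over total frames), with per-replica fractions
    reported alongside.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    residue_set = np.atleast_1d(np.asarray(residue_set, dtype=int))
    traj_list = _as_traj_list(trajs)
    heavy = not include_hydrogens

    per_replica: dict[str, np.ndarray] = {}
    total_contact = np.zeros(residue_set.size)
    total_frames = 0
    for traj in traj_list:
        f0 = traj.frames[0]
        lig_idx = f0.select(heavy_only=heavy, **ligand_selection)
        if lig_idx.size == 0:
            raise ValueError(f"empty ligand selection {dict(ligand_selection)!r}")
        res_idx = [f0.select(resids=r, heavy_only=heavy) for r in residue_set]
        if any(ix.size == 0 for ix in res_idx):
            empty = [int(r) for r, ix in zip(residue_set, res_idx) if ix.size == 0]
            raise KeyError(f"residues with no atoms: {empty}")
        counts = np.zeros(residue_set.size)
        for fr in traj.frames:
            lig = fr.coords[lig_idx]
            for k, ix in enumerate(res_idx):
                d = np.linalg.norm(
                    fr.coords[ix][:, None, :] - lig[None, :, :], axis=-1
                )
                if (d < cutoff).any():
                    counts[k] += 1
        per_replica[traj.replica_id] = counts / traj.n_frames
        total_contact += counts
        total_frames += traj.n_frames

    return ContactOccupancy(
        residue_numbers=residue_set,
        fractions=total_contact / total_frames,
        per_replica=per_replica,
        cutoff=cutoff,
        n_frames=total_frames,
    )


def salt_bridge_trace(
    traj: Trajectory,
    donor_atoms: Mapping[str, object],
    acceptor_atoms: Mapping[str, object],
    threshold: float = 3.5,
) -> DistanceTrace:
    """Per-frame minimum donor–acceptor distance and sub-threshold occupancy.

    Occupancy counts frames with minimum distance strictly below the
    threshold; frames at exactly the threshold are excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    f0 = traj.frames[0]
    d_idx = f0.select(**donor_atoms)
    a_idx = f0.select(**acceptor_atoms)
    if d_idx.size == 0:
        raise KeyError(f"donor selection matched no atoms: {dict(donor_atoms)!r}")
    if a_idx.size == 0:
        raise KeyError(f"acceptor selection matched no atoms: {dict(acceptor_atoms)!r}")

    dists = np.empty(traj.n_frames)
    for i, fr in enumerate(traj.frames):
        d = np.linalg.norm(
            fr.coords[d_idx][:, None, :] - fr.coords[a_idx][None, :, :], axis=-1
        )
        dists[i] = d.min()
    occ = float((dists < threshold).mean())
    sd = float(np.std(dists, ddof=1)) if dists.size > 1 else 0.0
    return DistanceTrace(
        distances=dists,
        threshold=threshold,
        occupancy=occ,
        mean=float(dists.mean()),
        sd=sd,
    )


def area_per_lipid(
    traj: Trajectory, n_lipids_total: int, protein_area: float = 0.0
) -> LipidAreaSeries:
    """Area per lipid from the lateral box area, two equal leaflets assumed.

    ``protein_area`` (Å², default 0) is subtracted from the lateral box area
    before dividing, for membranes with an embedded protein of known
    cross-section.
    """
    if n_lipids_total <= 0 or n_lipids_total % 2:
        raise ValueError("n_lipids_total must be even and > 0")
    per_leaflet = n_lipids_total // 2
    areas = np.empty(traj.n_frames)
    for i, fr in enumerate(traj.frames):
        if fr.box is None:
            raise ValueError(f"frame {i} carries no box dimensions")
        areas[i] = (fr.box[0] * fr.box[1] - protein_area) / per_leaflet
    if (areas <= 0).any():
        raise ValueError("non-positive area per lipid; check protein_area and box")
    sd = float(np.std(areas, ddof=1)) if areas.size > 1 else 0.0
    return LipidAreaSeries(areas=areas, mean=float(areas.mean()), sd=sd)
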