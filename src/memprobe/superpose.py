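"""Least-squares rigid superposition (Kabsch) and Cα RMSD time series.

The Kabsch algorithm finds the proper rotation minimising the RMSD between
two equal-length point sets after centering, via the SVD of the covariance
matrix with a determinant sign correction so reflections are never returned.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pdbio import StructureFrame, Trajectory

__all__ = ["kabsch_superpose", "rmsd_series", "RMSDSeries", "plateau_stats"]


@dataclass
class RMSDSeries:
    """Per-frame RMSD (Å) of a residue selection against a reference frame."""

    values: np.ndarray
    selection: np.ndarray  # residue numbers used
    replica_id: str = "rep0"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.values)), "rmsd_A": self.values}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the RMSD to
    ``reference``. The rotation is always proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both have shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points are required for a rigid superposition")
    if not (np.isfinite(P).all() and np.isfinite(Q).all()):
        raise ValueError("non-finite coordinates")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if S[1] <= 1e-8 * max(S[0], 1.0):
        warnings.warn(
            "degenerate (collinear) point set: superposition solved but the "
            "rotation about the common axis is arbitrary",
            stacklevel=2,
        )
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _ca_coords(frame: StructureFrame, selection: Sequence[int]) -> np.ndarray:
    sel = np.atleast_1d(np.asarray(selection, dtype=int))
    if sel.size == 0:
        raise ValueError("empty residue selection")
    idx = frame.select(resids=sel, names="CA")
    found = set(frame.residue_numbers[idx].tolist())
    missing = sorted(set(sel.tolist()) - found)
    if missing:
        raise KeyError(f"residues missing CA atoms: {missing}")
    order = np.argsort(frame.residue_numbers[idx], kind="stable")
    return frame.coords[idx[order]]


def rmsd_series(
    traj: Trajectory,
    selection: Sequence[int],
    reference_frame: StructureFrame | int = 0,
) -> RMSDSeries:
    """Cα RMSD of ``selection`` per frame after Kabsch superposition.

    Each frame is superposed onto the reference over the selected Cα atoms
    and the RMSD is computed over the same atoms. The reference may be a
    frame index within the trajectory (default 0) or an external frame —
    e.g. the initial snapshot of a different (apo) run.
    """
    ref = (
        traj.frames[reference_frame]
        if isinstance(reference_frame, (int, np.integer))
        else reference_frame
    )
    ref_xyz = _ca_coords(ref, selection)
    values = np.empty(traj.n_frames)
    for i, fr in enumerate(traj.frames):
        _, _, values[i] = kabsch_superpose(_ca_coords(fr, selection), ref_xyz)
    return RMSDSeries(
        values=values,
        selection=np.atleast_1d(np.asarray(selection, dtype=int)),
        replica_id=traj.replica_id,
    )


def plateau_stats(series: list[RMSDSeries], window_fraction: float = 0.5) -> dict:
    """Mean ± SD of the RMSD over the final window of each replica.

    Summarises stabilised RMSD the way plateau values are quoted for
    production runs: per replica, the mean over the last
    ``window_fraction`` of frames; across replicas, mean and SD (ddof=1)
    of those per-replica means.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    per_replica = []
    for s in series:
        n = len(s.values)
        start = n - max(1, int(round(window_fraction * n)))
        per_replica.append(float(np.mean(s.values[start:])))
    arr = np.array(per_replica)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {
        "per_replica_mean_A": per_replica,
        "mean_A": float(arr.mean()),
        "sd_A": sd,
        "window_fraction": window_fraction,
    }
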