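"""Structural frames and multi-model PDB input/output.

A trajectory is an ordered list of frames sharing one atom table; frames come
from MODEL/ENDMDL records of a multi-model PDB. Reading is delegated to
MDAnalysis; writing emits standard fixed-width PDB records (with a CRYST1
line when box dimensions are known).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StructureFrame",
    "Trajectory",
    "TrajectoryError",
    "read_trajectory",
    "write_trajectory",
    "element_of",
]


class TrajectoryError(ValueError):
    """Raised for empty, inconsistent or malformed trajectories."""


def element_of(atom_name: str) -> str:
    """Element symbol guessed from a PDB atom name (digits stripped)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA2"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class StructureFrame:
    """One structural snapshot: a flat atom table plus coordinates in Å."""

    atom_names: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chains: np.ndarray
    coords: np.ndarray  # (n_atoms, 3)
    frame_index: int = 0
    box: np.ndarray | None = None  # orthorhombic box lengths (3,) in Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryError("coords must have shape (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise TrajectoryError("non-finite coordinates")
        n = self.coords.shape[0]
        for name in ("atom_names", "residue_numbers", "residue_names", "chains"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise TrajectoryError(f"{name} length {arr.shape} != n_atoms {n}")
            setattr(self, name, arr)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def elements(self) -> np.ndarray:
        return np.array([element_of(a) for a in self.atom_names])

    def heavy_mask(self) -> np.ndarray:
        return self.elements() != "H"

    def select(
        self,
        resids: object = None,
        names: object = None,
        resnames: object = None,
        chain: str | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resids is not None:
            mask &= np.isin(self.residue_numbers, np.atleast_1d(resids))
        if names is not None:
            mask &= np.isin(self.atom_names, np.atleast_1d(names))
        if resnames is not None:
            mask &= np.isin(self.residue_names, np.atleast_1d(resnames))
        if chain is not None:
            mask &= self.chains == chain
        if heavy_only:
            mask &= self.heavy_mask()
        return np.nonzero(mask)[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        """A copy with ``x -> x @ R.T + t`` applied to every atom."""
        return replace(self, coords=self.coords @ np.asarray(rotation).T + translation)


@dataclass
class Trajectory:
    """Ordered frames from one simulation replica."""

    frames: list[StructureFrame]
    replica_id: str = "rep0"

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory has no frames")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if fr.n_atoms != ref.n_atoms or not (
                np.array_equal(fr.atom_names, ref.atom_names)
                and np.array_equal(fr.residue_numbers, ref.residue_numbers)
            ):
                raise TrajectoryError(
                    f"inconsistent atom ordering between frames in {self.replica_id}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms


def read_trajectory(path: str | Path, replica_id: str | None = None) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory (one frame per MODEL)."""
    import MDAnalysis as mda

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # mda guessers are chatty on minimal PDBs
            u = mda.Universe(str(path))
    except Exception as exc:
        raise TrajectoryError(f"{path}: cannot read multi-model PDB: {exc}") from exc
    atoms = u.atoms
    if len(atoms) == 0:
        raise TrajectoryError(f"{path}: no atoms")
    names = np.array([a.name for a in atoms])
    resids = np.array([a.resid for a in atoms], dtype=int)
    resnames = np.array([a.resname for a in atoms])
    try:
        chains = np.array([a.chainID for a in atoms])
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.array([str(a.segid).strip() or "A" for a in atoms])

    frames = []
    for i, ts in enumerate(u.trajectory):
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = np.array(ts.dimensions[:3], dtype=float)
        frames.append(
            StructureFrame(
                atom_names=names,
                residue_numbers=resids,
                residue_names=resnames,
                chains=chains,
                coords=ts.positions.astype(float).copy(),
                frame_index=i,
                box=box,
            )
        )
    if not frames:
        raise TrajectoryError(f"{path}: zero models")
    return Trajectory(frames=frames, replica_id=replica_id or path.stem)


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: element-aligned names start in column 14 when short
    name = name.strip()
    return f" {name:<3s}" if len(name) < 4 else name[:4]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    path = Path(path)
    box = traj.frames[0].box
    with open(path, "w") as fh:
        if box is not None:
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for m, fr in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for k in range(fr.n_atoms):
                x, y, z = fr.coords[k]
                elem = element_of(str(fr.atom_names[k]))
                fh.write(
                    f"ATOM  {k + 1:5d} {_format_atom_name(str(fr.atom_names[k]))}"
                    f" {str(fr.residue_names[k])[:3]:>3s} {str(fr.chains[k])[:1] or 'A'}"
                    f"{int(fr.residue_numbers[k]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
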