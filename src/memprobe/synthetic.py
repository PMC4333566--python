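"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic given its seed and returns its ground truth
alongside the data (a "sidecar" dict), so estimates can be compared to truth
mechanically. Per-component seeds are derived by stable hashing of
(seed, component name), so adding a generator never perturbs the streams of
existing ones.

What is emulated — and what is not: alignments have controlled per-column
residue-class frequencies but no phylogenetic correlation between rows;
trajectories are ideal-geometry α-helical backbones with controlled
per-residue unwinding (no force field, no dynamics, no lipids beyond box
metadata); ligand traces place a pseudo-atom at prescribed distances rather
than docking; dose-response curves come from the same 4PL forward model the
fitting stage assumes.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment, HYDROPHOBIC_CLASS, STANDARD_AA
from .assay import DoseResponse, four_parameter_logistic
from .geometry import place_atom
from .pdbio import StructureFrame, Trajectory
from .topology import TopologyTrack

__all__ = [
    "derive_seed",
    "MsaSpec",
    "gen_msa",
    "build_backbone",
    "HelixSpec",
    "gen_helix_trajectory",
    "expected_helical_mask",
    "gen_topology_tracks",
    "gen_contact_trace",
    "gen_salt_bridge_trace",
    "gen_lipid_boxes",
    "gen_spherical_pocket",
    "gen_dose_response",
]

# standard peptide geometry (Å / degrees) for the internal-coordinate builder
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.6
_A_C_N_CA = 121.9
_A_CA_C_O = 120.8

#: ideal α-helix backbone dihedrals (degrees)
HELIX_PHI, HELIX_PSI = -57.0, -47.0
#: extended basin used for unwinding; non-helical under the H-bond rule
UNWOUND_PHI_RANGE = (-180.0, -120.0)
UNWOUND_PSI_RANGE = (120.0, 180.0)


def derive_seed(seed: int, component: str) -> int:
    """Stable per-component seed below 2**31."""
    return (int(seed) * 1000003 + zlib.crc32(component.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# alignments


@dataclass
class MsaSpec:
    """Controlled-composition alignment: per-column class frequency and gap
    probability. Row 0 is the gap-free reference."""

    n_rows: int = 758
    length: int = 40
    class_freq: float | Sequence[float] = 0.8
    gap_prob: float | Sequence[float] = 0.0
    residue_class: frozenset[str] = HYDROPHOBIC_CLASS
    seed: int = 0
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        self.class_freq = np.broadcast_to(
            np.asarray(self.class_freq, dtype=float), (self.length,)
        ).copy()
        self.gap_prob = np.broadcast_to(
            np.asarray(self.gap_prob, dtype=float), (self.length,)
        ).copy()
        if ((self.class_freq < 0) | (self.class_freq > 1)).any():
            raise ValueError("class_freq must lie in [0, 1]")
        if ((self.gap_prob < 0) | (self.gap_prob > 1)).any():
            raise ValueError("gap_prob must lie in [0, 1]")
        if self.n_rows < 1 or self.length < 1:
            raise ValueError("n_rows and length must be >= 1")


def gen_msa(spec: MsaSpec) -> tuple[Alignment, dict]:
    """Draw an alignment with per-column class composition.

    Each cell is a gap with probability gap_prob, otherwise a residue from
    the class set with probability class_freq (uniform within the set) and a
    uniform non-class residue otherwise. The reference row (row 0) is
    gap-free.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, "msa"))
    class_letters = sorted(spec.residue_class)
    nonclass_letters = sorted(STANDARD_AA - spec.residue_class)
    mat = np.empty((spec.n_rows, spec.length), dtype="<U1")
    for j in range(spec.length):
        is_class = rng.random(spec.n_rows) < spec.class_freq[j]
        col = np.where(
            is_class,
            rng.choice(class_letters, size=spec.n_rows),
            rng.choice(nonclass_letters, size=spec.n_rows),
        )
        gaps = rng.random(spec.n_rows) < spec.gap_prob[j]
        gaps[0] = False  # reference stays gap-free
        col[gaps] = "-"
        mat[:, j] = col
    ids = [spec.reference_id] + [f"seq{i:04d}" for i in range(1, spec.n_rows)]
    aln = Alignment(
        ids=ids, rows=["".join(r) for r in mat], reference_id=spec.reference_id
    )
    truth = {
        "class_freq": spec.class_freq.copy(),
        "gap_prob": spec.gap_prob.copy(),
        "residue_class": set(spec.residue_class),
    }
    return aln, truth


# ---------------------------------------------------------------------------
# backbones and trajectories


def build_backbone(
    phi: float | Sequence[float],
    psi: float | Sequence[float],
    n_residues: int | None = None,
    omega: float | Sequence[float] = 180.0,
    residue_name: str = "ALA",
    chain: str = "A",
    frame_index: int = 0,
) -> StructureFrame:
    """Peptide backbone (N, CA, C, O) from dihedrals with standard geometry.

    ``phi[0]`` and the ω of the final peptide bond are not geometrically
    meaningful but must still be supplied (scalar inputs broadcast).
    Reconstructing dihedrals from the result returns the inputs.
    """
    if n_residues is None:
        n_residues = max(np.size(phi), np.size(psi))
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    phi = np.broadcast_to(np.asarray(phi, float), (n_residues,))
    psi = np.broadcast_to(np.asarray(psi, float), (n_residues,))
    omega = np.broadcast_to(np.asarray(omega, float), (n_residues,))

    N = np.empty((n_residues, 3))
    CA = np.empty((n_residues, 3))
    C = np.empty((n_residues, 3))
    O = np.empty((n_residues, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_residues):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega[i - 1])
        C[i] = place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])
    for i in range(n_residues):
        O[i] = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] - 180.0)

    coords = np.empty((4 * n_residues, 3))
    names, resids = [], []
    for i in range(n_residues):
        coords[4 * i : 4 * i + 4] = [N[i], CA[i], C[i], O[i]]
        names += ["N", "CA", "C", "O"]
        resids += [i + 1] * 4
    n_atoms = 4 * n_residues
    return StructureFrame(
        atom_names=np.array(names),
        residue_numbers=np.array(resids, dtype=int),
        residue_names=np.full(n_atoms, residue_name),
        chains=np.full(n_atoms, chain),
        coords=coords,
        frame_index=frame_index,
    )


@dataclass
class HelixSpec:
    """α-helical trajectory with controlled per-residue unwinding.

    ``unwind`` maps 1-based residue numbers to the probability that a frame
    has that residue's dihedrals redrawn from the extended basin
    (per-frame Bernoulli draws; ``exact_counts`` instead unwinds exactly
    ``round(fraction × n_frames)`` frames). The sidecar truth records the
    realised unwinding, so it is exact either way. Noise defaults to zero
    so the truth maps one-to-one onto the assignment rule; with noise it
    becomes approximate.
    """

    n_residues: int = 30
    n_frames: int = 100
    n_replicas: int = 3
    unwind: Mapping[int, float] = field(default_factory=dict)
    dihedral_noise_sd: float = 0.0  # degrees
    coord_noise_sd: float = 0.0  # Å
    seed: int = 0
    replica_seeds: Sequence[int] | None = None  # override for replica streams
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5 for any helix assignment")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ValueError("n_frames and n_replicas must be >= 1")
        if self.dihedral_noise_sd < 0 or self.coord_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for r, f in self.unwind.items():
            if not 1 <= int(r) <= self.n_residues:
                raise ValueError(f"unwind residue {r} outside chain")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"unwind fraction for residue {r} not in [0, 1]")


def expected_helical_mask(n_residues: int, unwound: frozenset[int] | set[int]) -> np.ndarray:
    """Which residues the α-helix rule assigns H when ``unwound`` residues
    sit in the extended basin and everything else is ideal helix.

    Replays the i→i+4 turn bookkeeping combinatorially: a turn starting at
    residue k (1-based, k ≤ n−4) survives unless an unwound residue lies in
    k+1..k+3 (the dihedrals its hydrogen-bond geometry spans); residue j is
    helical when two consecutive surviving turns cover it.
    """
    n = n_residues
    turn = np.zeros(n + 1, dtype=bool)  # 1-based, turn[k] for k in 1..n-4
    for k in range(1, n - 3):
        turn[k] = not any(k + 1 <= i <= k + 3 for i in unwound)
    helical = np.zeros(n + 1, dtype=bool)
    for k in range(2, n - 3):
        if turn[k - 1] and turn[k]:
            helical[k : k + 4] = True
    return helical[1:]


def gen_helix_trajectory(spec: HelixSpec) -> tuple[list[Trajectory], dict]:
    """Replica trajectories of an α-helix with prescribed unwinding.

    Flagged residues have their φ/ψ redrawn uniformly from the extended
    basin in a Bernoulli-selected (or exact-count) subset of frames. The
    sidecar reports the per-residue helical fractions the hydrogen-bond
    assignment rule yields for the realised unwinding.
    """
    trajs: list[Trajectory] = []
    per_replica_truth = []
    for rep in range(spec.n_replicas):
        if spec.replica_seeds is not None:
            rep_seed = int(spec.replica_seeds[rep])
        else:
            rep_seed = derive_seed(spec.seed, f"helix-replica-{rep}")
        rng = np.random.default_rng(rep_seed)

        unwound_frames: dict[int, set[int]] = {}
        for residue, fraction in sorted(spec.unwind.items()):
            if spec.exact_counts:
                k = int(round(fraction * spec.n_frames))
                chosen = rng.choice(spec.n_frames, size=k, replace=False)
            else:
                chosen = np.nonzero(rng.random(spec.n_frames) < fraction)[0]
            unwound_frames[int(residue)] = set(int(c) for c in chosen)

        frames = []
        truth_counts = np.zeros(spec.n_residues)
        for f in range(spec.n_frames):
            phi = np.full(spec.n_residues, HELIX_PHI)
            psi = np.full(spec.n_residues, HELIX_PSI)
            unwound_here = {
                r for r, frames_set in unwound_frames.items() if f in frames_set
            }
            for r in unwound_here:
                phi[r - 1] = rng.uniform(*UNWOUND_PHI_RANGE)
                psi[r - 1] = rng.uniform(*UNWOUND_PSI_RANGE)
            if spec.dihedral_noise_sd > 0:
                phi = phi + rng.normal(0, spec.dihedral_noise_sd, spec.n_residues)
                psi = psi + rng.normal(0, spec.dihedral_noise_sd, spec.n_residues)
            frame = build_backbone(phi, psi, spec.n_residues, frame_index=f)
            if spec.coord_noise_sd > 0:
                frame.coords = frame.coords + rng.normal(
                    0, spec.coord_noise_sd, frame.coords.shape
                )
            frames.append(frame)
            truth_counts += expected_helical_mask(spec.n_residues, unwound_here)
        trajs.append(Trajectory(frames=frames, replica_id=f"rep{rep}"))
        per_replica_truth.append(truth_counts / spec.n_frames)

    truth_arr = np.vstack(per_replica_truth)
    truth = {
        "residue_numbers": np.arange(1, spec.n_residues + 1),
        "per_replica_fraction": truth_arr,
        "mean_fraction": truth_arr.mean(axis=0),
        "exact": spec.dihedral_noise_sd == 0 and spec.coord_noise_sd == 0,
    }
    return trajs, truth


# ---------------------------------------------------------------------------
# predictor tracks


def gen_topology_tracks(
    segments: Sequence[tuple[int, int]],
    n_residues: int,
    n_predictors: int = 4,
    flip_prob: float = 0.03,
    seed: int = 0,
) -> tuple[list[TopologyTrack], dict]:
    """Binary predictor tracks around true TM segments, with label noise.

    Each predictor independently flips each residue's mark with
    ``flip_prob``, emulating disagreement between prediction servers.
    """
    rng = np.random.default_rng(derive_seed(seed, "topology-tracks"))
    true = np.zeros(n_residues, dtype=bool)
    for s, e in segments:
        if not 1 <= s <= e <= n_residues:
            raise ValueError(f"segment ({s}, {e}) outside 1..{n_residues}")
        true[s - 1 : e] = True
    tracks = []
    for p in range(n_predictors):
        flips = rng.random(n_residues) < flip_prob
        tracks.append(
            TopologyTrack(predictor_name=f"predictor{p + 1}", labels=true ^ flips)
        )
    return tracks, {"segments": list(segments), "membership": true}


# ---------------------------------------------------------------------------
# ligand contact and distance traces


def gen_contact_trace(
    n_frames: int = 100,
    target_fraction: float = 0.21,
    cutoff: float = 6.0,
    seed: int = 0,
    contact_residue: int = 5,
    n_residues: int = 10,
) -> tuple[Trajectory, dict]:
    """Trajectory with a ligand pseudo-atom contacting one residue in
    exactly ``round(target_fraction × n_frames)`` frames.

    In contact frames the ligand sits at half the cutoff from the residue's
    Cα; otherwise five cutoffs away — unambiguous under strict-inequality
    contact counting.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(derive_seed(seed, "contact-trace"))
    n_contact = int(round(target_fraction * n_frames))
    contact_frames = set(
        int(i) for i in rng.choice(n_frames, size=n_contact, replace=False)
    )
    protein = build_backbone(HELIX_PHI, HELIX_PSI, n_residues)
    ca_idx = protein.select(resids=contact_residue, names="CA")[0]
    ca = protein.coords[ca_idx]

    frames = []
    for f in range(n_frames):
        offset = 0.5 * cutoff if f in contact_frames else 5.0 * cutoff
        lig_xyz = ca + np.array([offset, 0.0, 0.0])
        frames.append(
            StructureFrame(
                atom_names=np.append(protein.atom_names, "C1"),
                residue_numbers=np.append(protein.residue_numbers, 900),
                residue_names=np.append(protein.residue_names, "LIG"),
                chains=np.append(protein.chains, "L"),
                coords=np.vstack([protein.coords, lig_xyz]),
                frame_index=f,
            )
        )
    traj = Trajectory(frames=frames, replica_id="contact")
    truth = {
        "contact_residue": contact_residue,
        "fraction": n_contact / n_frames,
        "contact_frames": sorted(contact_frames),
        "ligand_selection": {"resnames": "LIG"},
    }
    return traj, truth


def gen_salt_bridge_trace(
    n_frames: int = 100,
    occupancy: float = 0.35,
    threshold: float = 3.5,
    below: float = 3.0,
    above: float = 5.0,
    seed: int = 0,
    distances: Sequence[float] | None = None,
) -> tuple[Trajectory, dict]:
    """Donor–acceptor trace with prescribed sub-threshold occupancy.

    Acceptors are carboxylate oxygens (OD1/OD2 of an aspartate), donors the
    amino hydrogens of a lysine; the per-frame minimum distance is ``below``
    in exactly ``round(occupancy × n_frames)`` frames and ``above``
    otherwise, unless an explicit ``distances`` sequence is given.
    """
    if distances is None:
        if not (0 < below < threshold < above):
            raise ValueError("need below < threshold < above")
        rng = np.random.default_rng(derive_seed(seed, "salt-bridge"))
        n_below = int(round(occupancy * n_frames))
        close = set(int(i) for i in rng.choice(n_frames, size=n_below, replace=False))
        dist_arr = np.array([below if f in close else above for f in range(n_frames)])
    else:
        dist_arr = np.asarray(distances, dtype=float)
        n_frames = len(dist_arr)
    if (dist_arr <= 0).any():
        raise ValueError("distances must be > 0")

    od1 = np.array([0.0, 0.0, 0.0])
    od2 = np.array([2.2, 0.0, 0.0])
    frames = []
    for f, d in enumerate(dist_arr):
        hz1 = np.array([-d, 0.0, 0.0])  # closest pair: HZ1–OD1, distance d
        hz2 = hz1 + np.array([-0.6, 0.8, 0.0])
        hz3 = hz1 + np.array([-0.6, -0.8, 0.0])
        frames.append(
            StructureFrame(
                atom_names=np.array(["OD1", "OD2", "HZ1", "HZ2", "HZ3"]),
                residue_numbers=np.array([670, 670, 694, 694, 694]),
                residue_names=np.array(["ASP", "ASP", "LYS", "LYS", "LYS"]),
                chains=np.full(5, "A"),
                coords=np.vstack([od1, od2, hz1, hz2, hz3]),
                frame_index=f,
            )
        )
    traj = Trajectory(frames=frames, replica_id="saltbridge")
    sd = float(np.std(dist_arr, ddof=1)) if dist_arr.size > 1 else 0.0
    truth = {
        "occupancy": float((dist_arr < threshold).mean()),
        "mean": float(dist_arr.mean()),
        "sd": sd,
        "threshold": threshold,
    }
    return traj, truth


def gen_spherical_pocket(
    radius: float = 8.0, n_atoms: int = 300, center: Sequence[float] = (0.0, 0.0, 0.0)
) -> StructureFrame:
    """A smooth closed pocket: carbon atoms on a Fibonacci sphere shell.

    The enclosed probe-accessible cavity is approximately the sphere of
    radius (radius − r_vdW − r_probe); useful for grid-convergence checks.
    """
    if radius <= 0 or n_atoms < 4:
        raise ValueError("radius must be > 0 and n_atoms >= 4")
    k = np.arange(n_atoms)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_atoms
    r_xy = np.sqrt(1.0 - z**2)
    theta = golden * k
    xyz = radius * np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    xyz += np.asarray(center, dtype=float)
    return StructureFrame(
        atom_names=np.full(n_atoms, "C"),
        residue_numbers=np.arange(1, n_atoms + 1),
        residue_names=np.full(n_atoms, "SPH"),
        chains=np.full(n_atoms, "P"),
        coords=xyz,
    )


# ---------------------------------------------------------------------------
# membrane boxes and dose-response curves


def gen_lipid_boxes(
    n_frames: int = 100,
    area_per_lipid: float = 65.58,
    n_lipids_total: int = 200,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Frames whose box dimensions encode a target area per lipid.

    Lateral box lengths are set so that box_x·box_y / (n_lipids_total / 2)
    equals the target, with optional Gaussian jitter on the per-frame area.
    """
    if n_lipids_total <= 0 or n_lipids_total % 2:
        raise ValueError("n_lipids_total must be even and > 0")
    rng = np.random.default_rng(derive_seed(seed, "lipid-boxes"))
    per_leaflet = n_lipids_total // 2
    areas = area_per_lipid + rng.normal(0.0, jitter_sd, n_frames)
    if (areas <= 0).any():
        raise ValueError("jitter produced non-positive areas")
    frames = []
    for f, apl in enumerate(areas):
        side = float(np.sqrt(apl * per_leaflet))
        frames.append(
            StructureFrame(
                atom_names=np.array(["P"]),
                residue_numbers=np.array([1]),
                residue_names=np.array(["POP"]),
                chains=np.array(["M"]),
                coords=np.zeros((1, 3)),
                frame_index=f,
                box=np.array([side, side, 100.0]),
            )
        )
    traj = Trajectory(frames=frames, replica_id="membrane")
    return traj, {"area_per_lipid": float(np.mean(areas)), "target": area_per_lipid}


def gen_dose_response(
    pic50: float,
    hill: float = -1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    experiment_id: str = "exp0",
) -> tuple[DoseResponse, dict]:
    """Competition curve from the 4PL forward model.

    ``noise_sd`` is multiplicative (0.01 = 1% Gaussian noise on each
    signal). Default concentrations: 10 points log-spaced over ±3 decades
    around the IC50.
    """
    log_ic50 = -pic50
    if concentrations is None:
        concentrations = np.logspace(log_ic50 - 3.0, log_ic50 + 3.0, 10)
    x = np.asarray(concentrations, dtype=float)
    if (x <= 0).any():
        raise ValueError("concentrations must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = four_parameter_logistic(x, top, bottom, log_ic50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(derive_seed(seed, f"dose-{experiment_id}"))
        y = y * (1.0 + rng.normal(0.0, noise_sd, y.shape))
    data = DoseResponse(
        concentrations=x, signal=y, b0=float(top), experiment_id=experiment_id
    )
    truth = {"pIC50": pic50, "hill": hill, "top": top, "bottom": bottom}
    return data, truth
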