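"""Backbone-hydrogen-bond secondary-structure assignment and helicity profiles.

Assignment follows the Kabsch–Sander electrostatic model: the CO group of
residue a and the NH group of residue d form a hydrogen bond when

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol < -0.5

with distances in Å. Amide hydrogens are reconstructed 1.0 Å from N along
the preceding peptide C=O direction; the first residue of a chain has no H
and proline N is never a donor. An n-turn at residue i is a bond
CO(i)→NH(i+n); two consecutive 4-turns (at i-1 and i) mark residues
i..i+3 as α-helix (H). 3-10 (G) and π (I) helices follow the same pattern
with 3- and 5-turns. Residues inside a lone turn are coded T, everything
else '-'. β-sheet bookkeeping is intentionally out of scope.

"Helicity conservation" of a residue is the fraction of trajectory frames in
which its code is helical; replica mean ± SD against a conservation
criterion (default 60%) summarises how well a modelled helix holds up in
simulation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pdbio import StructureFrame, Trajectory

__all__ = [
    "SSAssignment",
    "HelicityProfile",
    "MissingBackboneError",
    "assign_secondary_structure",
    "assignment_matrix",
    "helicity_profile",
]

#: Kabsch–Sander prefactor: partial charges 0.42 e and 0.20 e times 332.
_KS_FACTOR = 0.084 * 332.0
_HBOND_CUTOFF = -0.5  # kcal/mol
_CHAIN_BREAK = 2.5  # Å on the C(i)-N(i+1) peptide bond
_MIN_DIST = 0.5  # Å; closer contacts are treated as clashes (bond assumed)


class MissingBackboneError(ValueError):
    """Raised when residues lack the N/CA/C/O atoms needed for assignment."""


@dataclass
class SSAssignment:
    """Per-residue secondary-structure codes for one frame."""

    residue_numbers: np.ndarray
    chains: np.ndarray
    codes: np.ndarray  # one of H, G, I, T, '-'

    def fraction(self, codes: Iterable[str] = ("H",)) -> float:
        return float(np.isin(self.codes, list(codes)).mean())


@dataclass
class HelicityProfile:
    """Per-residue helical-frame fractions per replica, with mean ± SD."""

    residue_numbers: np.ndarray
    replica_ids: list[str]
    per_replica: np.ndarray  # (n_replicas, n_residues)
    mean: np.ndarray
    sd: np.ndarray  # ddof = 1 across replicas; 0 for a single replica

    def conserved(self, criterion: float = 0.60) -> np.ndarray:
        """Boolean mask of residues meeting the conservation criterion.

        The boundary counts as conserved (>= criterion).
        """
        return self.mean >= criterion

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"residue": self.residue_numbers})
        for rid, row in zip(self.replica_ids, self.per_replica):
            df[f"fraction_{rid}"] = row
        df["mean"] = self.mean
        df["sd"] = self.sd
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _backbone_table(frame: StructureFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Residues with a CA atom, ordered by (chain, resid), plus backbone coords."""
    keys: list[tuple[str, int]] = []
    seen = set()
    for ch, rn, an in zip(frame.chains, frame.residue_numbers, frame.atom_names):
        k = (str(ch), int(rn))
        if an == "CA" and k not in seen:
            seen.add(k)
            keys.append(k)
    keys.sort()
    if not keys:
        raise MissingBackboneError("no residues with CA atoms in frame")

    index: dict[tuple[str, int, str], int] = {}
    for i, (ch, rn, an) in enumerate(
        zip(frame.chains, frame.residue_numbers, frame.atom_names)
    ):
        index.setdefault((str(ch), int(rn), str(an)), i)

    coords = {}
    missing = []
    for k in keys:
        ch, rn = k
        try:
            coords[k] = {
                an: frame.coords[index[(ch, rn, an)]] for an in ("N", "CA", "C", "O")
            }
        except KeyError:
            missing.append(k)
    if missing:
        raise MissingBackboneError(
            f"residues missing backbone N/CA/C/O atoms: {missing}"
        )
    resnames = {}
    for ch, rn, name in zip(frame.chains, frame.residue_numbers, frame.residue_names):
        resnames.setdefault((str(ch), int(rn)), str(name))
    chains = np.array([k[0] for k in keys])
    resids = np.array([k[1] for k in keys], dtype=int)
    return chains, resids, np.array([resnames[k] for k in keys]), coords | {"_keys": keys}


def _segments(chains: np.ndarray, keys: list, coords: dict) -> list[np.ndarray]:
    """Split the residue list into covalently continuous chain segments."""
    segs: list[list[int]] = [[0]]
    for i in range(1, len(keys)):
        same_chain = chains[i] == chains[i - 1]
        if same_chain:
            d = np.linalg.norm(coords[keys[i]]["N"] - coords[keys[i - 1]]["C"])
            if d <= _CHAIN_BREAK:
                segs[-1].append(i)
                continue
        segs.append([i])
    return [np.array(s, dtype=int) for s in segs]


def _hbond_energy(c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return -9.9
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(frame: StructureFrame) -> SSAssignment:
    """Assign helical secondary structure to every backbone-complete residue."""
    chains, resids, resnames, coords = _backbone_table(frame)
    keys = coords.pop("_keys")
    n = len(keys)
    codes = np.full(n, "-", dtype="<U1")

    for seg in _segments(chains, keys, coords):
        m = len(seg)
        # reconstructed amide H per residue in segment (None where no donor)
        hpos: list[np.ndarray | None] = [None] * m
        for j in range(1, m):
            if resnames[seg[j]] == "PRO":
                continue
            prev = coords[keys[seg[j - 1]]]
            vec = prev["C"] - prev["O"]
            vec = vec / np.linalg.norm(vec)
            hpos[j] = coords[keys[seg[j]]]["N"] + vec

        def hbond(a: int, d: int) -> bool:
            """CO of segment position a donates to NH of segment position d."""
            if d < 0 or d >= m or hpos[d] is None:
                return False
            ca_ = coords[keys[seg[a]]]
            nd = coords[keys[seg[d]]]["N"]
            return _hbond_energy(ca_["C"], ca_["O"], nd, hpos[d]) < _HBOND_CUTOFF

        turn = {k: np.zeros(m, dtype=bool) for k in (3, 4, 5)}
        for k in (3, 4, 5):
            for a in range(m - k):
                turn[k][a] = hbond(a, a + k)

        helix = {k: np.zeros(m, dtype=bool) for k in (3, 4, 5)}
        for k in (3, 4, 5):
            for i in range(1, m - k):
                if turn[k][i - 1] and turn[k][i]:
                    helix[k][i : i + k] = True

        in_turn = np.zeros(m, dtype=bool)
        for k in (3, 4, 5):
            for a in range(m - k):
                if turn[k][a]:
                    in_turn[a + 1 : a + k] = True

        seg_codes = np.full(m, "-", dtype="<U1")
        seg_codes[in_turn] = "T"
        seg_codes[helix[5]] = "I"
        seg_codes[helix[3]] = "G"
        seg_codes[helix[4]] = "H"
        codes[seg] = seg_codes

    return SSAssignment(residue_numbers=resids, chains=chains, codes=codes)


def assignment_matrix(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Codes for every frame: returns (residue_numbers, frames × residues)."""
    first = assign_secondary_structure(traj.frames[0])
    mat = np.empty((traj.n_frames, len(first.residue_numbers)), dtype="<U1")
    mat[0] = first.codes
    for i, fr in enumerate(traj.frames[1:], start=1):
        ass = assign_secondary_structure(fr)
        if not np.array_equal(ass.residue_numbers, first.residue_numbers):
            raise ValueError(f"frame {i} has a different residue range")
        mat[i] = ass.codes
    return first.residue_numbers, mat


def write_assignment_matrix(traj: Trajectory, path: str | Path) -> None:
    """Plain-text frames × residues code matrix (one row per frame)."""
    resids, mat = assignment_matrix(traj)
    with open(path, "w") as fh:
        fh.write("# residues: " + " ".join(map(str, resids.tolist())) + "\n")
        for row in mat:
            fh.write("".join(row.tolist()) + "\n")


def helicity_profile(
    trajs: Sequence[Trajectory], helical_codes: Iterable[str] = ("H",)
) -> HelicityProfile:
    """Fraction of frames each residue is helical, per replica and pooled.

    The SD across replicas uses the n−1 denominator; a single replica
    reports SD 0.
    """
    if not trajs:
        raise ValueError("at least one replica is required")
    helical = list(helical_codes)
    resids0: np.ndarray | None = None
    fractions = []
    for traj in trajs:
        resids, mat = assignment_matrix(traj)
        if resids0 is None:
            resids0 = resids
        elif not np.array_equal(resids, resids0):
            raise ValueError(
                f"replica {traj.replica_id} covers a different residue range"
            )
        fractions.append(np.isin(mat, helical).mean(axis=0))
    per_replica = np.vstack(fractions)
    sd = (
        np.std(per_replica, axis=0, ddof=1)
        if per_replica.shape[0] > 1
        else np.zeros(per_replica.shape[1])
    )
    return HelicityProfile(
        residue_numbers=resids0,
        replica_ids=[t.replica_id for t in trajs],
        per_replica=per_replica,
        mean=per_replica.mean(axis=0),
        sd=sd,
    )
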