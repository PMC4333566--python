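"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written with plain Python loops and their own
geometry, sharing no code with the package internals they verify.
"""
from __future__ import annotations

import math
from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# rotation-grid RMSD


def _euler_rotations(step_deg: float) -> np.ndarray:
    """Z-Y-Z Euler-angle grid of rotation matrices."""
    alphas = np.arange(0.0, 360.0, step_deg)
    betas = np.arange(0.0, 180.0 + 0.5 * step_deg, step_deg)
    gammas = np.arange(0.0, 360.0, step_deg)
    mats = []
    for a, b, g in product(np.radians(alphas), np.radians(betas), np.radians(gammas)):
        ca, sa = math.cos(a), math.sin(a)
        cb, sb = math.cos(b), math.sin(b)
        cg, sg = math.cos(g), math.sin(g)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
        mats.append(rz1 @ ry @ rz2)
    return np.array(mats)


def grid_min_rmsd(
    mobile: np.ndarray, reference: np.ndarray, coarse_step: float = 12.0
) -> tuple[float, float]:
    """Brute-force minimum RMSD over a dense rotation grid with refinement.

    Returns (rmsd, tolerance) where tolerance bounds how far the grid
    minimum can sit above the true continuous minimum: a rotation within
    angular resolution delta of the optimum displaces a centered point of
    norm r by at most 2 r sin(delta/2).
    """
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def best_over(rotations: np.ndarray) -> tuple[float, np.ndarray]:
        moved = np.einsum("rij,nj->rni", rotations, P)
        rmsds = np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=-1), axis=-1))
        k = int(np.argmin(rmsds))
        return float(rmsds[k]), rotations[k]

    best, R0 = best_over(_euler_rotations(coarse_step))
    # local refinement: compose small rotations about each axis with R0
    fine_step = 1.0
    offsets = np.radians(np.arange(-coarse_step, coarse_step + 0.5, fine_step))
    small = []
    for ax, ay, az in product(offsets, offsets[:: max(1, len(offsets) // 9)], offsets):
        cx, sx = math.cos(ax), math.sin(ax)
        cy, sy = math.cos(ay), math.sin(ay)
        cz, sz = math.cos(az), math.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        small.append(rz @ ry @ rx @ R0)
    refined, _ = best_over(np.array(small))
    best = min(best, refined)

    r_max = float(np.linalg.norm(P, axis=1).max())
    # refinement leaves at most ~3 deg of residual angular error per axis
    delta = math.radians(3.0)
    tol = 2.0 * r_max * math.sin(delta / 2.0) + 1e-9
    return best, tol


# ---------------------------------------------------------------------------
# per-column conservation counting


def brute_conservation(
    rows: list[str], ref_index: int, residue_class: set[str], gap_policy: str
) -> list[dict]:
    """Per-reference-position counts done the long way."""
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    ref = rows[ref_index]
    out = []
    for col in range(len(ref)):
        if ref[col] in "-.":
            continue
        column = [r[col] for r in rows]
        nongap = [c for c in column if c not in "-."]
        denom = len(rows) if gap_policy == "all_rows" else len(nongap)
        counts: dict[str, int] = {}
        for c in column:
            if c in standard:
                counts[c] = counts.get(c, 0) + 1
        if counts:
            top = max(counts.values())
            modal = sorted(c for c, k in counts.items() if k == top)[0]
            n_modal = counts[modal]
        else:
            modal, n_modal = "-", 0
        n_class = sum(1 for c in column if c in residue_class)
        out.append(
            {
                "modal": modal,
                "identity_pct": 100.0 * n_modal / denom if denom else 0.0,
                "class_pct": 100.0 * n_class / denom if denom else 0.0,
            }
        )
    return out


# ---------------------------------------------------------------------------
# run merging for topology consensus


def brute_consensus_segments(
    qualifying: list[bool], min_len: int, max_gap: int
) -> list[tuple[int, int]]:
    """Reference run-merger: scan runs, merge across short gaps, filter."""
    runs = []
    i = 0
    n = len(qualifying)
    while i < n:
        if qualifying[i]:
            j = i
            while j + 1 < n and qualifying[j + 1]:
                j += 1
            runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s + 1 >= min_len]


# ---------------------------------------------------------------------------
# Kabsch–Sander hydrogen-bond assignment (α-helix only)


def ks_alpha_codes(
    N: np.ndarray, CA: np.ndarray, C: np.ndarray, O: np.ndarray,
    proline: set[int] | None = None,
) -> list[str]:
    """Independent Kabsch–Sander α-helix assignment for a single chain.

    Reconstructs amide hydrogens from the previous peptide C=O, evaluates
    the electrostatic hydrogen-bond energy pairwise with explicit loops, and
    marks residues covered by two consecutive i→i+4 turns as 'H'.
    """
    proline = proline or set()
    n = len(N)

    def dist(p, q):
        return math.sqrt(sum((float(p[k]) - float(q[k])) ** 2 for k in range(3)))

    H: list[np.ndarray | None] = [None] * n
    for i in range(1, n):
        if i in proline:
            continue
        co = C[i - 1] - O[i - 1]
        co = co / math.sqrt(float(np.dot(co, co)))
        H[i] = N[i] + co

    def hbond(a: int, d: int) -> bool:
        if H[d] is None:
            return False
        r_on = dist(O[a], N[d])
        r_ch = dist(C[a], H[d])
        r_oh = dist(O[a], H[d])
        r_cn = dist(C[a], N[d])
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return True
        e = 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        return e < -0.5

    turn4 = [a + 4 < n and hbond(a, a + 4) for a in range(n)]
    codes = ["-"] * n
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            for j in range(i, i + 4):
                codes[j] = "H"
    return codes
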