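"""Internal-coordinate geometry primitives shared by the builders and analyses.

All coordinates are in Ångström, all angles in degrees unless noted.
"""
from __future__ import annotations

import numpy as np

__all__ = ["bond_angle", "dihedral", "place_atom"]


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a–b–c–d in degrees, in (-180, 180]."""
    b0 = np.asarray(a, float) - b
    b1 = np.asarray(c, float) - b
    b2 = np.asarray(d, float) - c
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # arctan2 returns (-180, 180]; normalise -180 to +180 for a stable round trip
    return float(180.0 if ang <= -180.0 + 1e-12 else ang)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d given the three preceding atoms a–b–c (natural extension
    reference frame).

    d is at ``bond_length`` from c, with angle b–c–d = ``angle`` and torsion
    a–b–c–d = ``torsion``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle)
    chi = np.radians(torsion)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
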