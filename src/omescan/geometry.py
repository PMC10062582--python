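"""Internal-coordinate geometry: dihedrals, bond angles, and atom placement.

All angles are in degrees, all lengths in Å. Dihedrals follow the IUPAC sign
convention and are reported in the half-open interval (-180, 180].
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

__all__ = ["bond_angle", "dihedral", "normalize_angle", "place_internal"]

_COLLINEAR_TOL = 1e-8


def normalize_angle(angle_deg: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    a = float(angle_deg) % 360.0
    if a > 180.0:
        a -= 360.0
    if a == -180.0:
        a = 180.0
    return a


def bond_angle(p0, p1, p2) -> float:
    """Angle at ``p1`` formed by ``p0-p1-p2``, in degrees."""
    u = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    v = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("zero-length bond vector in angle computation")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of ``p0-p1-p2-p3`` in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0 or np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("degenerate (collinear) atoms in dihedral computation")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1) / nb1
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def place_internal(a, b, c, bond_length: float, bond_angle_deg: float,
                   torsion_deg: float) -> np.ndarray:
    """Place atom ``d`` from internal coordinates relative to frame ``a, b, c``.

    The returned position satisfies |d - c| = ``bond_length``, the b-c-d angle
    equals ``bond_angle_deg`` and the a-b-c-d dihedral equals ``torsion_deg``
    (natural extension reference frame construction).

    Raises :class:`GeometryError` when a, b, c are collinear or coincident, in
    which case the torsion is undefined.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc == 0.0 or np.linalg.norm(ab) == 0.0:
        raise GeometryError("coincident reference atoms")
    bc_hat = bc / nbc
    n = np.cross(ab, bc_hat)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL * np.linalg.norm(ab):
        raise GeometryError("collinear reference atoms: torsion frame undefined")
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)

    theta = np.radians(bond_angle_deg)
    phi = np.radians(torsion_deg)
    # local displacement in the (bc, m, n) frame
    d_local = bond_length * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat
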