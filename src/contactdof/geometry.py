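"""Internal-coordinate backbone geometry.

Atoms are placed by the natural extension reference frame (NeRF)
construction: given three previously placed atoms A-B-C, atom D is placed at
a given bond length |C-D|, bond angle B-C-D and torsion A-B-C-D.  All
routines are vectorized over frames: positions are arrays of shape (F, 3).

Bond lengths and angles are standard peptide values; they are fixed
constants of the builder, not fitted quantities.
"""

from __future__ import annotations

import numpy as np

# backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.526
BOND_CB_SG = 1.810
BOND_C_CH3 = 1.507   # ACE methyl-carbonyl
BOND_N_CH3 = 1.449   # NME N-methyl

ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
OMEGA = 180.0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def place_atom(a, b, c, bond: float, angle_deg, torsion_deg) -> np.ndarray:
    """Place D given A, B, C with bond |CD|, angle B-C-D, torsion A-B-C-D.

    ``a``, ``b``, ``c`` are (..., 3) arrays; ``angle_deg`` / ``torsion_deg``
    may be scalars or arrays broadcastable to the leading shape.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    chi = np.deg2rad(np.asarray(torsion_deg, dtype=float))

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(chi),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = _unit(b1)
    v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
    w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1u, v) * w, axis=-1)
    ang = np.rad2deg(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def angle(p0, p1, p2) -> np.ndarray:
    """Bond angle p0-p1-p2 in degrees."""
    u = _unit(np.asarray(p0, float) - np.asarray(p1, float))
    v = _unit(np.asarray(p2, float) - np.asarray(p1, float))
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.rad2deg(np.arccos(cosang))


def sp2_substituent(center, n1, n2, bond: float) -> np.ndarray:
    """Third substituent of a planar sp2 center, opposite the bisector of n1/n2.

    Used for carbonyl O (center = C, n1 = CA, n2 = next N) and for amide H
    placed on the H-N-(C,CA) bisector.
    """
    u = _unit(np.asarray(n1, float) - np.asarray(center, float))
    v = _unit(np.asarray(n2, float) - np.asarray(center, float))
    return center - bond * _unit(u + v)


def tetrahedral_cb(n, ca, c, bond: float = BOND_CA_CB) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C (L-amino-acid chirality)."""
    b = np.asarray(ca, float) - np.asarray(n, float)
    cvec = np.asarray(c, float) - np.asarray(ca, float)
    a = np.cross(b, cvec)
    raw = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec
    return ca + bond * _unit(raw)
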