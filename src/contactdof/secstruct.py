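"""Kabsch-Sander secondary-structure assignment (8-state DSSP alphabet).

Backbone hydrogen bonds are detected with the Kabsch-Sander electrostatic
model: placing partial charges on the C=O and N-H groups, the bond energy is

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

and a bond is assigned when E < -0.5 kcal/mol.  From the bond pattern the
standard states are derived: n-turns (CO(i)...HN(i+n), n = 3, 4, 5) give the
three helix states G/H/I (minimal helices = two consecutive n-turns),
bridge patterns give strand states E (ladder) and B (isolated bridge),
remaining turn positions give T, and a backbone bend (virtual CA angle
kappa > 70 deg) gives S; everything else is none ('-').

Overlaps are resolved with the canonical priority H > E > B > G > I > T > S.
Cap units (ACE/NME) receive no state -- DSSP states are defined for
amino-acid residues -- and by default are also invisible to the
hydrogen-bond search, matching how reference DSSP implementations treat
non-standard residues; pass ``cap_hbonds=True`` to let the acetyl carbonyl
accept and the N-methylamide donate.

When an amide H is absent (proline excluded -- it cannot donate) it is
reconstructed 1.0 A from N, anti-parallel to the preceding carbonyl C=O,
the standard DSSP reconstruction.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import Ensemble, Topology

__all__ = [
    "STATES",
    "HELIX_STATES",
    "assign_ss",
    "ss_fractions",
    "helical_fraction",
    "DsspTransformer",
]

#: the 8-state alphabet: three helices, two strands, turn, bend, none
STATES = ("H", "G", "I", "E", "B", "T", "S", "-")
HELIX_STATES = ("H", "G", "I")

_Q1Q2_F = 0.084 * 332.0   # Kabsch-Sander coupling constant, kcal/mol * A
_E_CUT = -0.5             # H-bond energy threshold, kcal/mol
_KAPPA_CUT = 70.0         # bend angle threshold, degrees


def _backbone_arrays(ensemble_coords: np.ndarray, topology: Topology):
    """Per-unit backbone coordinates, shape (F, U, 3); NaN where absent."""
    F = ensemble_coords.shape[0]
    U = topology.n_units
    out = {k: np.full((F, U, 3), np.nan) for k in ("N", "H", "CA", "C", "O")}
    for internal in range(1, U + 1):
        for name in ("N", "H", "CA", "C", "O"):
            ai = topology.find_atom(internal, name)
            if ai is not None:
                out[name][:, internal - 1, :] = ensemble_coords[:, ai, :]
    # reconstruct missing amide H (not for proline, which cannot donate)
    for internal in range(2, U + 1):
        k = internal - 1
        unit = topology.units[topology.unit_by_internal_index(internal)]
        if unit.name == "PRO":
            continue
        have_h = not np.isnan(out["H"][0, k, 0])
        have_n = not np.isnan(out["N"][0, k, 0])
        prev_ok = not np.isnan(out["C"][0, k - 1, 0])
        if not have_h and have_n and prev_ok:
            co = out["C"][:, k - 1] - out["O"][:, k - 1]
            co /= np.linalg.norm(co, axis=-1, keepdims=True)
            out["H"][:, k] = out["N"][:, k] + co
    return out


def _hbond_matrix(bb: dict[str, np.ndarray],
                  cap_hbonds: bool = False) -> np.ndarray:
    """Boolean (F, U, U): hbond[f, i, j] = CO(i) accepts from NH(j).

    With ``cap_hbonds=False`` (default) the terminal caps are invisible to
    the hydrogen-bond search, matching how reference DSSP implementations
    treat non-standard residues; with ``True`` the acetyl carbonyl may
    accept and the N-methylamide may donate.
    """
    O, C = bb["O"], bb["C"]
    N, H = bb["N"], bb["H"]
    F, U, _ = O.shape

    def dist(a, b):  # (F, U, 1, 3) vs (F, 1, U, 3)
        return np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        e = _Q1Q2_F * (1.0 / dist(O, N) + 1.0 / dist(C, H)
                       - 1.0 / dist(O, H) - 1.0 / dist(C, N))
    hb = e < _E_CUT
    hb &= ~np.isnan(e)
    # exclude self and the shared peptide bond between neighbors
    i_idx = np.arange(U)
    near = np.abs(i_idx[:, None] - i_idx[None, :]) <= 1
    hb &= ~near[None, :, :]
    if not cap_hbonds:
        hb[:, 0, :] = False       # ACE cannot accept
        hb[:, :, U - 1] = False   # NME cannot donate
    return hb


def _turns(hb: np.ndarray, n: int) -> np.ndarray:
    """turn_n[f, i]: CO(i) -> NH(i+n) bond (False where i+n out of range)."""
    F, U, _ = hb.shape
    t = np.zeros((F, U), dtype=bool)
    if U > n:
        idx = np.arange(U - n)
        t[:, :U - n] = hb[:, idx, idx + n]
    return t


def _helix_mask(turn: np.ndarray, n: int) -> np.ndarray:
    """Minimal n-helix: two consecutive n-turns at i-1, i cover i..i+n-1."""
    F, U = turn.shape
    start = np.zeros((F, U), dtype=bool)
    start[:, 1:] = turn[:, 1:] & turn[:, :-1]
    mask = np.zeros((F, U), dtype=bool)
    for off in range(min(n, U)):
        src = start[:, : U - off] if off else start
        mask[:, off:] |= src
    return mask


def _bridges(hb: np.ndarray) -> np.ndarray:
    """Boolean (F, U, U) bridge matrix (parallel or antiparallel), |i-j|>=3."""
    F, U, _ = hb.shape

    def sh(a, di, dj):
        """hb shifted so entry (i, j) reads hb[i+di, j+dj]; False off-grid."""
        out = np.zeros_like(a)
        si = slice(max(0, -di), U - max(0, di))
        sj = slice(max(0, -dj), U - max(0, dj))
        ti = slice(max(0, di), U - max(0, -di))
        tj = slice(max(0, dj), U - max(0, -dj))
        out[:, si, sj] = a[:, ti, tj]
        return out

    hbT = np.swapaxes(hb, 1, 2)  # hbT[i, j] = NH(i) bonded from CO(j)
    par = (sh(hb, -1, 0) & sh(hbT, +1, 0)) | (sh(hbT, 0, -1) & sh(hb, 0, +1))
    anti = (hb & hbT) | (sh(hb, -1, +1) & sh(hbT, +1, -1))
    bridge = par | anti
    i_idx = np.arange(U)
    far = np.abs(i_idx[:, None] - i_idx[None, :]) >= 3
    bridge &= far[None, :, :]
    return bridge


def _strand_masks(hb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(is_E, is_B): extended-ladder and isolated-bridge residue masks."""
    bridge = _bridges(hb)
    F, U, _ = bridge.shape

    def roll2(a, di, dj):
        out = np.zeros_like(a)
        si = slice(max(0, -di), U - max(0, di))
        sj = slice(max(0, -dj), U - max(0, dj))
        ti = slice(max(0, di), U - max(0, -di))
        tj = slice(max(0, dj), U - max(0, -dj))
        out[:, si, sj] = a[:, ti, tj]
        return out

    ladder = bridge & (roll2(bridge, -1, -1) | roll2(bridge, 1, 1)
                       | roll2(bridge, -1, 1) | roll2(bridge, 1, -1))
    is_e = ladder.any(axis=2)
    is_b = bridge.any(axis=2) & ~is_e
    return is_e, is_b


def _turn_mask(hb: np.ndarray) -> np.ndarray:
    """T at interior positions of any 3/4/5-turn."""
    F, U, _ = hb.shape
    mask = np.zeros((F, U), dtype=bool)
    for n in (3, 4, 5):
        t = _turns(hb, n)
        for off in range(1, min(n, U)):
            mask[:, off:] |= t[:, : U - off]
    return mask


def _bend_mask(bb: dict[str, np.ndarray]) -> np.ndarray:
    """Bend: virtual-CA kappa angle above 70 degrees."""
    CA = bb["CA"]
    F, U, _ = CA.shape
    mask = np.zeros((F, U), dtype=bool)
    if U < 5:
        return mask
    u = CA[:, 2:-2] - CA[:, :-4]     # CA(i) - CA(i-2)
    v = CA[:, 4:] - CA[:, 2:-2]      # CA(i+2) - CA(i)
    with np.errstate(invalid="ignore"):
        cosang = np.sum(u * v, axis=-1) / (
            np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    kappa = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    mask[:, 2:-2] = kappa > _KAPPA_CUT
    mask &= ~np.isnan(CA[..., 0])
    return mask


def assign_ss(ensemble: Ensemble | np.ndarray,
              topology: Optional[Topology] = None,
              cap_hbonds: bool = False) -> np.ndarray:
    """Per-frame, per-unit state labels, shape (F, n_units), dtype '<U1'.

    Accepts an Ensemble, or a single frame / coordinate array together with
    its topology.  Cap units always receive '-'.
    """
    if isinstance(ensemble, Ensemble):
        coords, topology = ensemble.coords, ensemble.topology
    else:
        if topology is None:
            raise ValueError("topology required when passing raw coordinates")
        coords = np.asarray(ensemble, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    U = topology.n_units
    for internal in range(2, U):
        for name in ("N", "CA", "C", "O"):
            if topology.find_atom(internal, name) is None:
                raise ValueError(
                    f"unit {internal} is missing backbone atom {name}"
                )

    bb = _backbone_arrays(coords, topology)
    hb = _hbond_matrix(bb, cap_hbonds)

    is_h = _helix_mask(_turns(hb, 4), 4)
    is_g = _helix_mask(_turns(hb, 3), 3)
    is_i = _helix_mask(_turns(hb, 5), 5)
    is_e, is_b = _strand_masks(hb)
    is_t = _turn_mask(hb)
    is_s = _bend_mask(bb)

    F = coords.shape[0]
    labels = np.full((F, U), "-", dtype="<U1")
    for mask, letter in [(is_s, "S"), (is_t, "T"), (is_i, "I"), (is_g, "G"),
                         (is_b, "B"), (is_e, "E"), (is_h, "H")]:
        labels[mask] = letter
    # caps are structureless by convention
    labels[:, 0] = "-"
    labels[:, U - 1] = "-"
    return labels


def ss_fractions(ensemble: Ensemble,
                 analysis_stride_ps: Optional[float] = 10.0) -> pd.DataFrame:
    """Empirical per-residue distribution over the 8 states.

    Rows are internal indices; columns the 8 state labels; each row sums
    to 1.
    """
    step = 1
    if analysis_stride_ps is not None:
        step = ensemble.analysis_step(analysis_stride_ps)
    sub = ensemble.coords[::step]
    if sub.shape[0] == 0:
        raise ValueError("stride leaves no frames to analyze")
    labels = assign_ss(sub, ensemble.topology)
    U = labels.shape[1]
    frac = np.zeros((U, len(STATES)))
    for s, state in enumerate(STATES):
        frac[:, s] = (labels == state).mean(axis=0)
    return pd.DataFrame(frac, columns=list(STATES),
                        index=pd.RangeIndex(1, U + 1, name="internal_index"))


def helical_fraction(fractions: pd.DataFrame,
                     interior: tuple[int, int] = (4, 19)) -> float:
    """Mean helical (H+G+I) fraction over interior internal indices."""
    lo, hi = interior
    sub = fractions.loc[lo:hi, list(HELIX_STATES)]
    return float(sub.sum(axis=1).mean())


class DsspTransformer(TransformerMixin, BaseEstimator):
    """Transformer mapping an Ensemble to its (F, n_units) label matrix."""

    def __init__(self, analysis_stride_ps: Optional[float] = None):
        self.analysis_stride_ps = analysis_stride_ps

    def fit(self, X: Ensemble, y=None) -> "DsspTransformer":
        self.n_units_ = X.topology.n_units
        return self

    def transform(self, X: Ensemble) -> np.ndarray:
        step = 1
        if self.analysis_stride_ps is not None:
            step = X.analysis_step(self.analysis_stride_ps)
        return assign_ss(X.coords[::step], X.topology)
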