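"""Synthetic capped-peptide conformational ensembles.

This module stands in for MD sampling: it builds ideal-geometry peptide
backbones at prescribed (phi, psi) dihedrals and draws helix-coil ensembles
from a cooperative two-state model, optionally decorating the central
cysteine with a fragment-labeled pseudo-ligand whose B-ring can be biased
toward a chosen residue.

The representation is backbone + amide H + one C-beta pseudo-atom per
residue (plus an S-gamma pseudo-atom on Cys, the ligand attachment point).
Side-chain rotamers are deliberately not modeled; contacts and secondary
structure only need backbone geometry plus approximate side-chain reach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import AA3, Atom, Ensemble, SegmentSpec, Topology, Unit
from . import geometry as geo

__all__ = [
    "DihedralProfile",
    "HelixCoilModel",
    "PseudoLigand",
    "ContactBias",
    "build_peptide",
    "build_frames",
    "make_topology",
    "sample_states",
    "sample_helix_coil",
    "attach_pseudo_ligand",
    "generate_liganded",
]

#: named (phi, psi) presets in degrees
PRESETS = {
    "helix": (-57.0, -47.0),      # ideal alpha-helix
    "extended": (-139.0, 135.0),  # fully extended beta-strand
    "coil": (-75.0, 150.0),       # polyproline-II-like single conformer
}

# rectangular Ramachandran basins for coil sampling: (phi_lo, phi_hi,
# psi_lo, psi_hi, weight).  Both basins keep phi < 0 (alpha-L excluded) and
# avoid the alpha-R well closely enough that coil states break helical
# hydrogen bonding.
COIL_BASINS = (
    (-160.0, -60.0, 90.0, 175.0, 0.6),   # beta / PPII
    (-160.0, -60.0, -50.0, 30.0, 0.4),   # broad bridge region
)


@dataclass(frozen=True)
class DihedralProfile:
    """Per-residue backbone dihedrals in degrees."""

    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        if phi.shape != psi.shape:
            raise ValueError("phi and psi must have equal length")
        for name, a in (("phi", phi), ("psi", psi)):
            if np.any((a <= -180.0) | (a > 180.0)):
                raise ValueError(f"{name} angles must lie in (-180, 180]")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "psi", psi)

    @classmethod
    def preset(cls, name: str, n_residues: int) -> "DihedralProfile":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        phi0, psi0 = PRESETS[name]
        return cls(np.full(n_residues, phi0), np.full(n_residues, psi0))

    @property
    def n_residues(self) -> int:
        return len(self.phi)


@dataclass(frozen=True)
class HelixCoilModel:
    """Cooperative two-state (helix/coil) model along the sequence.

    ``p_helix`` is the marginal per-residue probability of the helical
    state; ``cooperativity`` c in [0, 1) correlates neighboring residues
    through a two-state Markov chain along the chain
    (P(h_i | h_{i-1}) = p_i + c (1 - p_i), P(h_i | c_{i-1}) = p_i (1 - c)),
    which preserves the requested marginals while producing contiguous
    helical runs, the discrete analogue of helix-coil cooperativity.

    The default c = 0.5 is a calibration point: helical runs must be long
    enough (mean ~3-4 residues at moderate p) that the DSSP alpha state can
    recover the marginal helicity, while the frame-to-frame variance of
    total helicity stays small enough that ensembles differing in p remain
    separable in a contact-DOF projection.  Larger c makes single frames of
    low- and high-p ensembles indistinguishable; smaller c fragments runs
    below the four-residue DSSP helix threshold.
    """

    p_helix: float | Sequence[float] = 0.7
    cooperativity: float = 0.5
    n_frames: int = 1000
    seed: int = 0

    def marginals(self, n_residues: int) -> np.ndarray:
        p = np.asarray(self.p_helix, dtype=float)
        if p.ndim == 0:
            p = np.full(n_residues, float(p))
        if p.shape != (n_residues,):
            raise ValueError(f"p_helix must be scalar or length {n_residues}")
        if np.any((p < 0.0) | (p > 1.0)):
            raise ValueError("helical probabilities must lie in [0, 1]")
        if not (0.0 <= self.cooperativity < 1.0):
            raise ValueError("cooperativity must lie in [0, 1)")
        return p


# ---------------------------------------------------------------------------
# topology / builder
# ---------------------------------------------------------------------------

def _element(atom_name: str) -> str:
    if atom_name.startswith("CH3"):
        return "C"
    return atom_name[0]


def _residue_atom_names(aa: str) -> list[str]:
    names = ["N"]
    if aa != "P":
        names.append("H")
    names.append("CA")
    if aa != "G":
        names.append("CB")
    if aa == "C":
        names.append("SG")
    names += ["C", "O"]
    return names


def make_topology(spec: SegmentSpec) -> Topology:
    """Topology of the capped, unliganded peptide."""
    units = [Unit(1, "ACE", None)]
    for k, aa in enumerate(spec.sequence):
        units.append(Unit(k + 2, AA3[aa], spec.start_position + k))
    units.append(Unit(spec.n_residues + 2, "NME", None))

    atoms: list[Atom] = []
    for ui, unit in enumerate(units):
        if unit.name == "ACE":
            names = ["CH3", "C", "O"]
        elif unit.name == "NME":
            names = ["N", "H", "CH3"]
        else:
            names = _residue_atom_names(spec.sequence[ui - 1])
        atoms += [Atom(n, _element(n), ui) for n in names]
    return Topology(units=units, atoms=atoms, segment=spec)


def build_frames(spec: SegmentSpec, phi: np.ndarray, psi: np.ndarray
                 ) -> tuple[np.ndarray, Topology]:
    """Build F frames at the given dihedrals, vectorized over frames.

    ``phi``/``psi`` have shape (F, n_residues); returns coordinates of shape
    (F, n_atoms, 3) in Angstrom and the shared topology.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    n = spec.n_residues
    if phi.shape != psi.shape or phi.shape[1] != n:
        raise ValueError(
            f"dihedral arrays must have shape (F, {n}); got {phi.shape}"
        )
    F = phi.shape[0]
    top = make_topology(spec)

    pos: dict[tuple[int, str], np.ndarray] = {}

    # ACE cap seeds the chain in the z=0 plane
    ch3 = np.zeros((F, 3))
    c_ace = np.tile([geo.BOND_C_CH3, 0.0, 0.0], (F, 1))
    theta = np.deg2rad(180.0 - 116.6)
    n_first = c_ace + geo.BOND_C_N * np.array([np.cos(theta), np.sin(theta), 0.0])
    pos[(0, "CH3")], pos[(0, "C")] = ch3, c_ace

    prev_prev, prev_c, n_cur = ch3, c_ace, n_first
    for i in range(n):
        ui = i + 1
        aa = spec.sequence[i]
        ca = geo.place_atom(prev_prev, prev_c, n_cur,
                            geo.BOND_N_CA, geo.ANGLE_C_N_CA, geo.OMEGA)
        c = geo.place_atom(prev_c, n_cur, ca,
                           geo.BOND_CA_C, geo.ANGLE_N_CA_C, phi[:, i])
        pos[(ui, "N")], pos[(ui, "CA")], pos[(ui, "C")] = n_cur, ca, c
        if aa != "P":
            pos[(ui, "H")] = geo.sp2_substituent(n_cur, prev_c, ca, geo.BOND_N_H)
        if aa != "G":
            cb = geo.tetrahedral_cb(n_cur, ca, c)
            pos[(ui, "CB")] = cb
            if aa == "C":
                pos[(ui, "SG")] = cb + geo.BOND_CB_SG * geo._unit(cb - ca)
        n_next = geo.place_atom(n_cur, ca, c,
                                geo.BOND_C_N, geo.ANGLE_CA_C_N, psi[:, i])
        pos[(ui, "O")] = geo.sp2_substituent(c, ca, n_next, geo.BOND_C_O)
        prev_prev, prev_c, n_cur = ca, c, n_next

    # NME cap; also fixes the ACE carbonyl O
    ui = n + 1
    ch3_nme = geo.place_atom(prev_prev, prev_c, n_cur,
                             geo.BOND_N_CH3, geo.ANGLE_C_N_CA, geo.OMEGA)
    pos[(ui, "N")] = n_cur
    pos[(ui, "H")] = geo.sp2_substituent(n_cur, prev_c, ch3_nme, geo.BOND_N_H)
    pos[(ui, "CH3")] = ch3_nme
    pos[(0, "O")] = geo.sp2_substituent(c_ace, ch3, n_first, geo.BOND_C_O)

    coords = np.empty((F, top.n_atoms, 3))
    for ai, atom in enumerate(top.atoms):
        coords[:, ai, :] = pos[(atom.unit, atom.name)]
    return coords, top


def build_peptide(spec: SegmentSpec, dihedrals: DihedralProfile | str
                  ) -> tuple[np.ndarray, Topology]:
    """Build a single frame; returns ((n_atoms, 3) coordinates, Topology)."""
    if isinstance(dihedrals, str):
        dihedrals = DihedralProfile.preset(dihedrals, spec.n_residues)
    if dihedrals.n_residues != spec.n_residues:
        raise ValueError(
            f"dihedral profile has {dihedrals.n_residues} residues, "
            f"segment has {spec.n_residues}"
        )
    coords, top = build_frames(spec, dihedrals.phi[None, :], dihedrals.psi[None, :])
    return coords[0], top


# ---------------------------------------------------------------------------
# helix-coil sampling
# ---------------------------------------------------------------------------

def sample_states(p: np.ndarray, cooperativity: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw boolean helix states, shape (F, n), from the Markov model.

    ``p`` is (F, n) per-frame, per-residue marginal helical probability.
    """
    p = np.asarray(p, dtype=float)
    F, n = p.shape
    c = cooperativity
    states = np.zeros((F, n), dtype=bool)
    u = rng.random((F, n))
    states[:, 0] = u[:, 0] < p[:, 0]
    for i in range(1, n):
        p_cond = np.where(states[:, i - 1],
                          p[:, i] + c * (1.0 - p[:, i]),
                          p[:, i] * (1.0 - c))
        states[:, i] = u[:, i] < p_cond
    return states


def _dihedrals_from_states(states: np.ndarray, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Helix states get ideal helix dihedrals; coil states draw from the
    rectangular Ramachandran basins."""
    F, n = states.shape
    phi0, psi0 = PRESETS["helix"]
    phi = np.full((F, n), phi0)
    psi = np.full((F, n), psi0)

    coil = ~states
    m = int(coil.sum())
    if m:
        w = np.array([b[4] for b in COIL_BASINS])
        which = rng.choice(len(COIL_BASINS), size=m, p=w / w.sum())
        lo_phi = np.array([b[0] for b in COIL_BASINS])[which]
        hi_phi = np.array([b[1] for b in COIL_BASINS])[which]
        lo_psi = np.array([b[2] for b in COIL_BASINS])[which]
        hi_psi = np.array([b[3] for b in COIL_BASINS])[which]
        phi[coil] = lo_phi + rng.random(m) * (hi_phi - lo_phi)
        psi[coil] = lo_psi + rng.random(m) * (hi_psi - lo_psi)
    return phi, psi


def sample_helix_coil(spec: SegmentSpec, model: HelixCoilModel,
                      stride_ps: float = 10.0) -> Ensemble:
    """Draw a helix-coil ensemble; reproducible for a fixed model seed.

    The returned ensemble carries the drawn boolean state matrix as
    ``ensemble.helix_states`` (shape (n_frames, n_residues)) so that
    realized state frequencies can be audited directly.
    """
    if model.n_frames < 1:
        raise ValueError("frame count must be >= 1")
    p = model.marginals(spec.n_residues)
    rng = np.random.default_rng(model.seed)
    states = sample_states(np.tile(p, (model.n_frames, 1)),
                           model.cooperativity, rng)
    phi, psi = _dihedrals_from_states(states, rng)
    coords, top = build_frames(spec, phi, psi)
    ens = Ensemble(topology=top, coords=coords, stride_ps=stride_ps)
    ens.helix_states = states
    return ens


# ---------------------------------------------------------------------------
# pseudo-ligand
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PseudoLigand:
    """Three fragment-labeled pseudo-atom groups chained off the Cys S-gamma.

    The geometry is schematic: a short stem, then the A-ring, then the
    B-ring at the far end, emulating the reach (roughly 10 A) of a dual-ring
    covalent ligand without modeling its chemistry atom for atom.
    """

    stem_atoms: tuple[str, ...] = ("ST1", "ST2")
    a_ring_atoms: tuple[str, ...] = ("AR1", "AR2", "AR3")
    b_ring_atoms: tuple[str, ...] = ("BR1", "BR2", "BR3")
    spacing: float = 1.7

    def atom_names(self) -> list[tuple[str, str]]:
        out = [(n, "stem") for n in self.stem_atoms]
        out += [(n, "A-ring") for n in self.a_ring_atoms]
        out += [(n, "B-ring") for n in self.b_ring_atoms]
        return out


@dataclass(frozen=True)
class ContactBias:
    """Place the B-ring in contact with one residue in a fraction of frames."""

    target_internal_index: int
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("bias fraction must lie in [0, 1]")


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _ligand_coords_away(sg: np.ndarray, centroid: np.ndarray, scale: float
                        ) -> np.ndarray:
    """Chain pointing radially away from the peptide centroid."""
    u = sg - centroid
    u = u / np.linalg.norm(u)
    perp = _perpendicular(u)
    d = np.array([1.8, 3.4, 5.0, 6.2, 6.2, 8.0, 9.2, 9.2]) * scale
    off = np.array([0.0, 0.0, 0.0, 1.2, -1.2, 0.0, 1.2, -1.2])
    return sg + d[:, None] * u + off[:, None] * perp


def _ligand_coords_toward(sg: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Chain reaching from SG toward a target atom, B-ring in contact."""
    d = target - sg
    L = np.linalg.norm(d)
    u = d / L if L > 1e-9 else np.array([1.0, 0.0, 0.0])
    b1 = target - 2.8 * u if L >= 4.0 else sg + max(L - 2.8, 0.8) * u
    w = b1 - sg
    Lw = np.linalg.norm(w)
    uw = w / Lw if Lw > 1e-9 else u
    perp = _perpendicular(uw)
    s1 = sg + min(1.7, 0.3 * Lw) * uw
    s2 = sg + min(3.4, 0.5 * Lw) * uw
    a_mid = sg + 0.7 * Lw * uw
    return np.stack([
        s1, s2,
        a_mid, a_mid + 1.2 * perp, a_mid - 1.2 * perp,
        b1, b1 + 1.2 * perp, b1 - 1.2 * perp,
    ])


def attach_pseudo_ligand(
    ensemble: Ensemble,
    ligand: PseudoLigand = PseudoLigand(),
    bias: Optional[ContactBias] = None,
    seed: int = 0,
    biased_flags: Optional[np.ndarray] = None,
    cutoff: float = 4.2,
) -> Ensemble:
    """Attach the fragment-labeled pseudo-ligand to the central Cys.

    When ``bias`` is given, the B-ring is placed within the contact cutoff
    of the target residue's CA in a Bernoulli(``bias.fraction``) subset of
    frames (or exactly the frames flagged in ``biased_flags``); otherwise it
    points away from the peptide.
    """
    top = ensemble.topology
    if top.has_ligand:
        raise ValueError("ensemble already carries a ligand")
    spec = top.segment
    if spec is None:
        raise ValueError("topology lacks a segment spec")
    center = spec.center_internal_index
    sg_idx = top.find_atom(center, "SG")
    if sg_idx is None:
        raise ValueError(
            "attachment site absent: central residue has no SG atom "
            "(central residue must be Cys)"
        )

    F = ensemble.n_frames
    if bias is not None:
        if biased_flags is None:
            rng = np.random.default_rng(seed)
            biased_flags = rng.random(F) < bias.fraction
        biased_flags = np.asarray(biased_flags, dtype=bool)
        if biased_flags.shape != (F,):
            raise ValueError("biased_flags must have one flag per frame")
        target_unit = top.unit_by_internal_index(bias.target_internal_index)
        target_ca = top.find_atom(bias.target_internal_index, "CA")
        target_atoms = top.atom_indices(target_unit)
    else:
        biased_flags = np.zeros(F, dtype=bool)
        target_ca = None
        target_atoms = None

    lig_names = ligand.atom_names()
    n_lig = len(lig_names)
    b_local = np.array([i for i, (_, f) in enumerate(lig_names) if f == "B-ring"])

    pep_coords = ensemble.coords
    lig_coords = np.empty((F, n_lig, 3))
    for f in range(F):
        sg = pep_coords[f, sg_idx]
        if biased_flags[f]:
            lig_coords[f] = _ligand_coords_toward(sg, pep_coords[f, target_ca])
        else:
            centroid = pep_coords[f].mean(axis=0)
            for scale in (1.0, 1.5, 2.0):
                xyz = _ligand_coords_away(sg, centroid, scale)
                if target_atoms is None:
                    break
                dmin = np.min(np.linalg.norm(
                    xyz[b_local][:, None, :] - pep_coords[f, target_atoms][None],
                    axis=-1))
                if dmin > cutoff + 0.8:
                    break
            lig_coords[f] = xyz

    lig_unit_idx = len(top.units)
    units = top.units + [Unit(None, "LIG", None)]
    atoms = top.atoms + [
        Atom(name, "S" if frag == "stem" else "C", lig_unit_idx, fragment=frag)
        for name, frag in lig_names
    ]
    new_top = Topology(units=units, atoms=atoms, segment=spec)
    coords = np.concatenate([pep_coords, lig_coords], axis=1)
    out = Ensemble(topology=new_top, coords=coords,
                   stride_ps=ensemble.stride_ps, label=ensemble.label)
    if hasattr(ensemble, "helix_states"):
        out.helix_states = ensemble.helix_states
    out.biased_flags = biased_flags
    return out


def generate_liganded(
    spec: SegmentSpec,
    model: HelixCoilModel,
    bias: ContactBias,
    ligand: PseudoLigand = PseudoLigand(),
    helix_penalty: float = 0.6,
    window: int = 1,
    stride_ps: float = 10.0,
) -> Ensemble:
    """Liganded scenario: B-ring contact locally melts the helix.

    In frames where the B-ring engages the target residue, the marginal
    helical probability of residues within ``window`` of the target and of
    the attachment Cys is scaled by (1 - ``helix_penalty``), coupling the
    ligand contact to local helix destabilization.  The same Bernoulli draw
    controls both the state sampling and the ligand placement, so structural
    and contact signatures are consistent frame by frame.
    """
    if not (0.0 <= helix_penalty <= 1.0):
        raise ValueError("helix_penalty must lie in [0, 1]")
    p = model.marginals(spec.n_residues)
    rng = np.random.default_rng(model.seed)
    F = model.n_frames
    flags = rng.random(F) < bias.fraction

    pmat = np.tile(p, (F, 1))
    touched = []
    for internal in (bias.target_internal_index, spec.center_internal_index):
        res = internal - 2  # internal index -> 0-based residue position
        touched += [r for r in range(res - window, res + window + 1)
                    if 0 <= r < spec.n_residues]
    pmat[np.ix_(flags, sorted(set(touched)))] *= (1.0 - helix_penalty)

    states = sample_states(pmat, model.cooperativity, rng)
    phi, psi = _dihedrals_from_states(states, rng)
    coords, top = build_frames(spec, phi, psi)
    ens = Ensemble(topology=top, coords=coords, stride_ps=stride_ps)
    ens.helix_states = states
    return attach_pseudo_ligand(ens, ligand, bias=bias, biased_flags=flags)
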