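"""Core containers for capped-peptide ensembles.

The indexing convention used throughout the package mirrors the one used in
the source MD study design: a 21-residue peptide segment is flanked by an
N-terminal acetyl (ACE) and a C-terminal N-methylamide (NME) cap, giving 23
"indexed units".  Internal indices are 1-based and include the caps, so the
N-terminal cap is unit 1, the first amino acid unit 2, the central cysteine
of a 21-mer unit 12, and the C-terminal cap unit 23.  Sequence positions are
UniProt-style 1-based positions in the parent protein (e.g. C406 of the
androgen receptor AF1 region).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

ACE = "ACE"
NME = "NME"

#: three-letter codes for the twenty amino acids, keyed by one-letter code
AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}


@dataclass(frozen=True)
class SegmentSpec:
    """A capped peptide segment cut from a parent sequence.

    Parameters
    ----------
    center_position : int
        Sequence position of the central residue (the ligatable Cys in the
        liganded systems, e.g. 406).
    sequence : str
        One-letter residue string of length ``2 * flank + 1``.
    flank : int
        Number of residues on each side of the center (default 10, giving a
        21-mer).
    """

    center_position: int
    sequence: str
    flank: int = 10

    def __post_init__(self) -> None:
        n = 2 * self.flank + 1
        if len(self.sequence) != n:
            raise ValueError(
                f"sequence length {len(self.sequence)} != 2*flank+1 = {n}"
            )
        bad = set(self.sequence.upper()) - set(AA3)
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def n_residues(self) -> int:
        return 2 * self.flank + 1

    @property
    def n_units(self) -> int:
        """Number of indexed units, caps included."""
        return self.n_residues + 2

    @property
    def start_position(self) -> int:
        return self.center_position - self.flank

    @property
    def end_position(self) -> int:
        return self.center_position + self.flank

    @property
    def center_internal_index(self) -> int:
        return self.flank + 2


@dataclass(frozen=True)
class Unit:
    """One indexed unit: a cap, an amino-acid residue, or the pseudo-ligand."""

    internal_index: Optional[int]  # None for the ligand unit
    name: str                      # 'ACE', 'NME', three-letter code, or 'LIG'
    seq_position: Optional[int]    # None for caps and ligand

    @property
    def is_cap(self) -> bool:
        return self.name in (ACE, NME)

    @property
    def is_ligand(self) -> bool:
        return self.internal_index is None

    @property
    def is_residue(self) -> bool:
        return not self.is_cap and not self.is_ligand


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    unit: int                       # index into Topology.units
    fragment: Optional[str] = None  # 'A-ring' | 'B-ring' | 'stem' for ligand atoms


FRAGMENTS = ("A-ring", "B-ring", "stem")


@dataclass
class Topology:
    """Ordered units and atoms of one peptide (plus optional pseudo-ligand).

    The atom order of the coordinate arrays follows ``atoms``.
    """

    units: list[Unit]
    atoms: list[Atom]
    segment: Optional[SegmentSpec] = None

    def __post_init__(self) -> None:
        idx = [u.internal_index for u in self.units if u.internal_index is not None]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("internal indices must be contiguous from 1")

    # -- selections ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_units(self) -> int:
        """Indexed units (caps + residues, ligand excluded)."""
        return sum(1 for u in self.units if not u.is_ligand)

    def atom_indices(self, unit: int) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.unit == unit],
                        dtype=int)

    def unit_by_internal_index(self, internal_index: int) -> int:
        for i, u in enumerate(self.units):
            if u.internal_index == internal_index:
                return i
        raise KeyError(f"no unit with internal index {internal_index}")

    def atoms_of_internal_index(self, internal_index: int) -> np.ndarray:
        """Peptide atoms of one indexed unit (ligand atoms excluded)."""
        u = self.unit_by_internal_index(internal_index)
        return np.array(
            [i for i, a in enumerate(self.atoms)
             if a.unit == u and a.fragment is None],
            dtype=int,
        )

    @property
    def ligand_unit(self) -> Optional[int]:
        for i, u in enumerate(self.units):
            if u.is_ligand:
                return i
        return None

    @property
    def has_ligand(self) -> bool:
        return self.ligand_unit is not None

    def fragment_atoms(self, fragment: str) -> np.ndarray:
        """Atom indices of a named ligand fragment ('A-ring', 'B-ring', 'stem')."""
        if fragment not in FRAGMENTS:
            raise ValueError(f"unknown fragment {fragment!r}")
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.fragment == fragment],
            dtype=int,
        )

    def find_atom(self, internal_index: int, name: str) -> Optional[int]:
        u = self.unit_by_internal_index(internal_index)
        for i, a in enumerate(self.atoms):
            if a.unit == u and a.name == name and a.fragment is None:
                return i
        return None


@dataclass
class Ensemble:
    """An ordered set of frames sharing one topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom.  ``stride_ps``
    is the time separation between consecutive stored frames; synthetic
    ensembles default to 10 ps so that the standard 10 ps analysis stride
    uses every frame.
    """

    topology: Topology
    coords: np.ndarray
    stride_ps: float = 10.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords carry {self.coords.shape[1]} atoms, topology "
                f"{self.topology.n_atoms}"
            )
        if self.stride_ps <= 0:
            raise ValueError("stride_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, item) -> "Ensemble":
        if isinstance(item, int):
            item = slice(item, item + 1)
        return replace(self, coords=self.coords[item])

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def analysis_step(self, analysis_stride_ps: float) -> int:
        """Frame step implementing a time-based analysis stride."""
        if analysis_stride_ps <= 0:
            raise ValueError("analysis stride must be positive")
        return max(1, int(round(analysis_stride_ps / self.stride_ps)))
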