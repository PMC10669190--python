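"""Ensemble, topology, and study-registry I/O.

Ensembles travel as fixed-column multi-model PDB (v3.3 subset: MODEL/ENDMDL
framing, no altlocs) with a JSON topology sidecar carrying the residue
table, sequence-position mapping, ligand fragment labels, and frame stride.
The PDB layer is backed by biotite; the sidecar is authoritative for
everything a PDB cannot express.

This module also owns the mapping between parent-sequence positions and the
1-based internal index that counts the N-terminal cap as unit 1 (so the
central Cys of a 21-mer is unit 12).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import AA1, Atom, Ensemble, SegmentSpec, Topology, Unit

__all__ = [
    "internal_index",
    "sequence_position",
    "write_ensemble",
    "read_ensemble",
    "StudyRegistry",
    "load_registry",
    "split_blocks",
    "discard_equilibration",
]


# ---------------------------------------------------------------------------
# index bookkeeping
# ---------------------------------------------------------------------------

def internal_index(seq_position: int, spec: SegmentSpec) -> int:
    """Internal (cap-inclusive, 1-based) index of a sequence position.

    For the 21-mer centered on C406 this maps 399 -> 5, 403 -> 9, 406 -> 12.
    """
    if not (spec.start_position <= seq_position <= spec.end_position):
        raise ValueError(
            f"position {seq_position} outside segment "
            f"[{spec.start_position}, {spec.end_position}]"
        )
    return seq_position - spec.start_position + 2


def sequence_position(internal: int, spec: SegmentSpec) -> int:
    """Inverse of :func:`internal_index`; defined for residue units only."""
    if not (2 <= internal <= spec.n_residues + 1):
        raise ValueError(
            f"internal index {internal} is a cap or outside the segment "
            f"(residues occupy 2..{spec.n_residues + 1})"
        )
    return spec.start_position + internal - 2


# ---------------------------------------------------------------------------
# PDB + sidecar
# ---------------------------------------------------------------------------

def _to_atom_array_stack(ensemble: Ensemble) -> struc.AtomArrayStack:
    top = ensemble.topology
    n_atoms = top.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n_atoms)
    res_ids = np.empty(n_atoms, dtype=int)
    res_names = np.empty(n_atoms, dtype="U5")
    atom_names = np.empty(n_atoms, dtype="U6")
    elements = np.empty(n_atoms, dtype="U2")
    hetero = np.zeros(n_atoms, dtype=bool)
    lig_res_id = top.n_units + 1
    for i, a in enumerate(top.atoms):
        unit = top.units[a.unit]
        res_ids[i] = unit.internal_index if unit.internal_index else lig_res_id
        res_names[i] = unit.name
        atom_names[i] = a.name
        elements[i] = a.element
        hetero[i] = unit.is_ligand
    stack.res_id = res_ids
    stack.res_name = res_names
    stack.atom_name = atom_names
    stack.element = elements
    stack.hetero = hetero
    stack.chain_id = np.full(n_atoms, "A", dtype="U4")
    stack.coord = np.asarray(ensemble.coords, dtype=np.float32)
    return stack


def _sidecar_dict(ensemble: Ensemble) -> dict:
    top = ensemble.topology
    units = []
    for ui, u in enumerate(top.units):
        units.append({
            "internal_index": u.internal_index,
            "name": u.name,
            "seq_position": u.seq_position,
            "atoms": [a.name for a in top.atoms if a.unit == ui],
        })
    lig = [
        {"name": a.name, "fragment": a.fragment}
        for a in top.atoms if a.fragment is not None
    ]
    seg = None
    if top.segment is not None:
        seg = {
            "center_position": top.segment.center_position,
            "flank": top.segment.flank,
            "sequence": top.segment.sequence,
        }
    return {
        "stride_ps": ensemble.stride_ps,
        "label": ensemble.label,
        "segment": seg,
        "units": units,
        "ligand_atoms": lig,
    }


def write_ensemble(ensemble: Ensemble, pdb_path: Union[str, Path],
                   sidecar_path: Optional[Union[str, Path]] = None) -> None:
    """Write a multi-model PDB plus JSON topology sidecar."""
    pdb_path = Path(pdb_path)
    if sidecar_path is None:
        sidecar_path = pdb_path.with_suffix(".topology.json")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(ensemble))
    pdb.write(str(pdb_path))
    Path(sidecar_path).write_text(json.dumps(_sidecar_dict(ensemble), indent=1))


def _validate_model_atom_counts(pdb_text: str) -> None:
    counts: list[int] = []
    current: Optional[int] = None
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = 0
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = 0
            current += 1
        elif rec == "ENDMDL":
            counts.append(current or 0)
            current = None
    if current:
        counts.append(current)
    if counts and any(c != counts[0] for c in counts):
        bad = next(m for m, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"inconsistent atom count across models: model {bad} has "
            f"{counts[bad - 1]} atoms, model 1 has {counts[0]}"
        )


def _topology_from_sidecar(side: dict) -> Topology:
    seg = None
    if side.get("segment"):
        s = side["segment"]
        seg = SegmentSpec(s["center_position"], s["sequence"], s["flank"])
    frag_by_name = {d["name"]: d["fragment"] for d in side.get("ligand_atoms", [])}
    units: list[Unit] = []
    atoms: list[Atom] = []
    for ui, u in enumerate(side["units"]):
        name = u["name"]
        if name not in ("ACE", "NME", "LIG") and name not in AA1:
            raise ValueError(f"unknown residue {name!r} in topology sidecar")
        units.append(Unit(u["internal_index"], name, u["seq_position"]))
        for an in u["atoms"]:
            frag = frag_by_name.get(an) if name == "LIG" else None
            element = "C" if an.startswith("CH3") else an[0]
            if frag == "stem":
                element = "S"
            atoms.append(Atom(an, element, ui, fragment=frag))
    return Topology(units=units, atoms=atoms, segment=seg)


def read_ensemble(pdb_path: Union[str, Path],
                  sidecar_path: Optional[Union[str, Path]] = None) -> Ensemble:
    """Read a multi-model PDB written by :func:`write_ensemble`.

    The sidecar is authoritative for unit identity, fragment labels, and
    stride; atom names and counts are cross-validated against the PDB.
    """
    pdb_path = Path(pdb_path)
    if sidecar_path is None:
        sidecar_path = pdb_path.with_suffix(".topology.json")
    text = pdb_path.read_text()
    _validate_model_atom_counts(text)
    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    side = json.loads(Path(sidecar_path).read_text())
    top = _topology_from_sidecar(side)
    if stack.array_length() != top.n_atoms:
        raise ValueError(
            f"PDB has {stack.array_length()} atoms per model, sidecar "
            f"topology has {top.n_atoms}"
        )
    pdb_names = list(stack.atom_name)
    side_names = [a.name for a in top.atoms]
    if pdb_names != side_names:
        raise ValueError("atom names in PDB and sidecar disagree")
    ens = Ensemble(
        topology=top,
        coords=np.asarray(stack.coord, dtype=float),
        stride_ps=float(side.get("stride_ps", 10.0)),
        label=side.get("label", ""),
    )
    return ens


# ---------------------------------------------------------------------------
# study registry
# ---------------------------------------------------------------------------

_VALID_CENTERS = (406, 327, 240)
_VALID_STARTS = ("H", "E")


@dataclass(frozen=True)
class SystemRecord:
    notation: str     # e.g. "XNN_4H"
    center: int       # 406 / 327 / 240
    start: str        # "H" (helical) / "E" (extended)
    ligand: Optional[str]  # XNN / XN0 / XNB / XEN / None (native)
    run_ns: int
    ion: Optional[str]
    n_water: int


class StudyRegistry:
    """The roster of simulated peptide systems (14 in the source design)."""

    def __init__(self, records: Sequence[SystemRecord]):
        notations = [r.notation for r in records]
        if len(set(notations)) != len(notations):
            raise ValueError("duplicate system notations in registry")
        for r in records:
            if r.center not in _VALID_CENTERS:
                raise ValueError(f"{r.notation}: invalid center {r.center}")
            if r.start not in _VALID_STARTS:
                raise ValueError(f"{r.notation}: invalid start code {r.start!r}")
        self._records = list(records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, notation: str) -> SystemRecord:
        for r in self._records:
            if r.notation == notation:
                return r
        raise KeyError(notation)

    def __contains__(self, notation: str) -> bool:
        return any(r.notation == notation for r in self._records)

    @property
    def notations(self) -> list[str]:
        return [r.notation for r in self._records]

    def filter(self, center: Optional[int] = None, start: Optional[str] = None,
               liganded: Optional[bool] = None) -> "StudyRegistry":
        recs = self._records
        if center is not None:
            recs = [r for r in recs if r.center == center]
        if start is not None:
            recs = [r for r in recs if r.start == start]
        if liganded is not None:
            recs = [r for r in recs if (r.ligand is not None) == liganded]
        return StudyRegistry(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self._records])


def load_registry(path: Optional[Union[str, Path]] = None) -> StudyRegistry:
    """Load a registry CSV; default is the packaged 14-system study design."""
    if path is None:
        with resources.files("contactdof.data").joinpath("registry.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if df.empty:
        return StudyRegistry([])
    records = []
    for row in df.itertuples(index=False):
        ligand = None if pd.isna(row.ligand) or row.ligand in ("-", "") else str(row.ligand)
        ion = None if pd.isna(row.ion) or row.ion in ("-", "") else str(row.ion)
        records.append(SystemRecord(
            notation=str(row.notation), center=int(row.center),
            start=str(row.start), ligand=ligand, run_ns=int(row.run_ns),
            ion=ion, n_water=int(row.n_water),
        ))
    return StudyRegistry(records)


# ---------------------------------------------------------------------------
# blocks / equilibration
# ---------------------------------------------------------------------------

def split_blocks(ensemble: Ensemble, n_blocks: int) -> list[Ensemble]:
    """Contiguous order-preserving partition into n blocks.

    Block sizes differ by at most one; earlier blocks take the remainder
    (101 frames in 2 blocks -> 51 + 50).  Block labels get the "_1", "_2"
    suffix convention.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if ensemble.n_frames < n_blocks:
        raise ValueError(
            f"cannot split {ensemble.n_frames} frames into {n_blocks} blocks"
        )
    if n_blocks == 1:
        return [ensemble]
    parts = np.array_split(np.arange(ensemble.n_frames), n_blocks)
    out = []
    for k, idx in enumerate(parts, start=1):
        blk = replace(ensemble, coords=ensemble.coords[idx],
                      label=f"{ensemble.label}_{k}" if ensemble.label else f"_{k}")
        if hasattr(ensemble, "helix_states"):
            blk.helix_states = ensemble.helix_states[idx]
        out.append(blk)
    return out


def discard_equilibration(ensemble: Ensemble, n_frames: int = 0) -> Ensemble:
    """Drop leading equilibration frames (default 0 for synthetic data)."""
    if n_frames < 0 or n_frames >= ensemble.n_frames:
        raise ValueError("n_frames must leave at least one frame")
    if n_frames == 0:
        return ensemble
    return replace(ensemble, coords=ensemble.coords[n_frames:])
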