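"""Residue-residue contact maps and contact degrees of freedom.

A contact between indexed units j and k is formed in a frame when any atom
of j lies within the distance cutoff (default 4.2 A, boundary inclusive) of
any atom of k.  Hydrogens count like any other atom; ligand atoms never
count toward their host residue.  The per-frame map is binary and
symmetric with the diagonal fixed at 1 by convention; the ensemble mean map
averages per-frame maps entrywise.  The strict upper triangle, flattened
row-major, provides the contact degrees of freedom: n(n-1)/2 of them, i.e.
253 for the 23-unit capped 21-mer.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .core import Ensemble, Topology, FRAGMENTS

__all__ = [
    "contact_map",
    "contact_maps",
    "mean_contact_map",
    "vectorize",
    "unvectorize",
    "pair_labels",
    "contact_vectors",
    "fragment_contact_profile",
    "ContactFeaturizer",
    "write_rle",
    "read_rle",
]


def _unit_slices(topology: Topology) -> list[np.ndarray]:
    """Peptide atom indices per indexed unit, in internal-index order."""
    groups = []
    for internal in range(1, topology.n_units + 1):
        idx = topology.atoms_of_internal_index(internal)
        if idx.size == 0:
            raise ValueError(f"unit {internal} has an empty atom set")
        groups.append(idx)
    return groups


def _min_dist_matrix(xyz: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Minimum inter-atom distance between every pair of atom groups."""
    n = len(groups)
    flat = np.concatenate(groups)
    starts = np.cumsum([0] + [len(g) for g in groups])[:-1]
    d = cdist(xyz[flat], xyz[flat])
    d = np.minimum.reduceat(d, starts, axis=0)
    d = np.minimum.reduceat(d, starts, axis=1)
    return d


def contact_map(frame: np.ndarray, topology: Topology,
                cutoff: float = 4.2) -> np.ndarray:
    """Binary symmetric contact map of one frame, diagonal 1."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (topology.n_atoms, 3):
        raise ValueError("frame does not match topology")
    groups = _unit_slices(topology)
    m = (_min_dist_matrix(frame, groups) <= cutoff).astype(np.uint8)
    np.fill_diagonal(m, 1)
    return m


def contact_maps(ensemble: Ensemble, cutoff: float = 4.2,
                 analysis_stride_ps: Optional[float] = None) -> np.ndarray:
    """Per-frame binary maps, shape (n_analyzed_frames, n, n)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    step = 1
    if analysis_stride_ps is not None:
        step = ensemble.analysis_step(analysis_stride_ps)
    frames = ensemble.coords[::step]
    if frames.shape[0] == 0:
        raise ValueError("stride leaves no frames to analyze")
    groups = _unit_slices(ensemble.topology)
    n = len(groups)
    out = np.empty((frames.shape[0], n, n), dtype=np.uint8)
    for f in range(frames.shape[0]):
        m = (_min_dist_matrix(frames[f], groups) <= cutoff).astype(np.uint8)
        np.fill_diagonal(m, 1)
        out[f] = m
    return out


def mean_contact_map(ensemble: Ensemble, cutoff: float = 4.2,
                     analysis_stride_ps: Optional[float] = 10.0) -> np.ndarray:
    """Ensemble-average (heat-map) contact map, entries in [0, 1]."""
    return contact_maps(ensemble, cutoff, analysis_stride_ps).mean(axis=0)


def vectorize(cmap: np.ndarray) -> np.ndarray:
    """Strict-upper-triangle row-major flattening: the contact DOFs."""
    cmap = np.asarray(cmap)
    if cmap.ndim != 2 or cmap.shape[0] != cmap.shape[1]:
        raise ValueError("contact map must be a square matrix")
    n = cmap.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return cmap[iu, ju]


def unvectorize(vec: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric map from its contact-DOF vector."""
    vec = np.asarray(vec)
    m = vec.shape[-1]
    round_n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if round_n * (round_n - 1) // 2 != m:
        raise ValueError(f"length {m} is not n(n-1)/2 for integer n")
    out = np.full((round_n, round_n), diagonal, dtype=float)
    iu, ju = np.triu_indices(round_n, k=1)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def pair_labels(n: int) -> list[str]:
    """Labels "(j,k)" (internal indices) for each contact DOF, in order."""
    iu, ju = np.triu_indices(n, k=1)
    return [f"({j + 1},{k + 1})" for j, k in zip(iu, ju)]


def contact_vectors(ensemble: Ensemble, cutoff: float = 4.2,
                    analysis_stride_ps: Optional[float] = None) -> np.ndarray:
    """Per-frame contact-DOF matrix, shape (F', n(n-1)/2)."""
    maps = contact_maps(ensemble, cutoff, analysis_stride_ps)
    n = maps.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return maps[:, iu, ju]


class ContactFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer turning an Ensemble into per-frame contact-DOF vectors.

    Stateless (``fit`` only records dimensionality); composes with sklearn
    pipelines feeding the embedding estimators.
    """

    def __init__(self, cutoff: float = 4.2,
                 analysis_stride_ps: Optional[float] = None):
        self.cutoff = cutoff
        self.analysis_stride_ps = analysis_stride_ps

    def fit(self, X: Ensemble, y=None) -> "ContactFeaturizer":
        n = X.topology.n_units
        self.n_units_ = n
        self.n_features_out_ = n * (n - 1) // 2
        return self

    def transform(self, X: Ensemble) -> np.ndarray:
        return contact_vectors(X, self.cutoff, self.analysis_stride_ps)


# ---------------------------------------------------------------------------
# ligand fragment profiles
# ---------------------------------------------------------------------------

def fragment_contact_profile(ensemble: Ensemble, cutoff: float = 4.2,
                             analysis_stride_ps: Optional[float] = 10.0
                             ) -> pd.DataFrame:
    """Percentage of frames each ligand fragment contacts each residue.

    Rows are internal indices 1..n_units; columns are "Cys" (the peptide
    atoms of the attachment residue itself, backbone and pseudo side chain
    alike) and the three ligand fragments.  Entries are contact ratio x 100.
    """
    top = ensemble.topology
    if not top.has_ligand:
        raise ValueError("ensemble topology carries no ligand fragment labels")
    spec = top.segment
    step = 1
    if analysis_stride_ps is not None:
        step = ensemble.analysis_step(analysis_stride_ps)
    frames = ensemble.coords[::step]
    if frames.shape[0] == 0:
        raise ValueError("stride leaves no frames to analyze")

    groups = _unit_slices(top)
    frag_atoms = {f: top.fragment_atoms(f) for f in FRAGMENTS}
    frag_atoms["Cys"] = top.atoms_of_internal_index(spec.center_internal_index)

    cols = ["Cys", "A-ring", "B-ring", "stem"]
    counts = {c: np.zeros(len(groups), dtype=int) for c in cols}
    for f in range(frames.shape[0]):
        xyz = frames[f]
        for c in cols:
            fa = frag_atoms[c]
            for r, ga in enumerate(groups):
                d = cdist(xyz[fa], xyz[ga]).min()
                if d <= cutoff:
                    counts[c][r] += 1
    nF = frames.shape[0]
    data = {c: 100.0 * counts[c] / nF for c in cols}
    return pd.DataFrame(data, index=pd.RangeIndex(1, len(groups) + 1,
                                                  name="internal_index"))


# ---------------------------------------------------------------------------
# compact run-length text format for per-frame binary maps
# ---------------------------------------------------------------------------

def write_rle(vectors: np.ndarray, path) -> None:
    """Write per-frame binary contact vectors as run-length text.

    One line per frame: the first run's bit value, a colon, then the
    comma-separated run lengths.  Example: ``0:5,2,246`` encodes five 0s,
    two 1s, then 246 zeros.
    """
    vectors = np.asarray(vectors, dtype=np.uint8)
    with open(path, "w") as fh:
        fh.write(f"# contact-dof run-length encoding, {vectors.shape[1]} bits/frame\n")
        for row in vectors:
            change = np.nonzero(np.diff(row))[0] + 1
            bounds = np.concatenate([[0], change, [len(row)]])
            runs = np.diff(bounds)
            fh.write(f"{int(row[0])}:" + ",".join(map(str, runs)) + "\n")


def read_rle(path) -> np.ndarray:
    """Inverse of :func:`write_rle`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            head, runs = line.strip().split(":")
            val = int(head)
            bits = []
            for r in runs.split(","):
                bits.append(np.full(int(r), val, dtype=np.uint8))
                val = 1 - val
            rows.append(np.concatenate(bits))
    return np.vstack(rows)
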