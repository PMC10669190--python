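"""Shared fixtures: one synthetic 21-mer segment and cached ensembles."""

import numpy as np
import pytest
from hypothesis import settings

from contactdof.core import SegmentSpec
from contactdof.generate import (HelixCoilModel, build_peptide,
                                 sample_helix_coil)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: synthetic stand-in for the 406-centered segment: Trp at internal index 5,
#: Ala at 9, Cys at 12 (the anchors of the study's indexing convention)
SEQ_406 = "GSAWAAQAYQCSEAGASAQAS"


@pytest.fixture(scope="session")
def spec406() -> SegmentSpec:
    return SegmentSpec(406, SEQ_406, 10)


@pytest.fixture(scope="session")
def helix_frame(spec406):
    return build_peptide(spec406, "helix")


@pytest.fixture(scope="session")
def extended_frame(spec406):
    return build_peptide(spec406, "extended")


@pytest.fixture(scope="session")
def hc_ensemble(spec406):
    """Mixed helix-coil ensemble, p = 0.7, 300 frames."""
    return sample_helix_coil(
        spec406, HelixCoilModel(p_helix=0.7, n_frames=300, seed=2024))


def brute_force_contact_map(frame: np.ndarray, topology,
                            cutoff: float = 4.2) -> np.ndarray:
    """All-pairs distance-scan oracle, independent of the contact kernel."""
    n = topology.n_units
    out = np.zeros((n, n), dtype=np.uint8)
    groups = [topology.atoms_of_internal_index(i) for i in range(1, n + 1)]
    for j in range(n):
        for k in range(n):
            if j == k:
                out[j, k] = 1
                continue
            found = 0
            for a in groups[j]:
                for b in groups[k]:
                    d = np.sqrt(((frame[a] - frame[b]) ** 2).sum())
                    if d <= cutoff:
                        found = 1
                        break
                if found:
                    break
            out[j, k] = found
    return out


def to_mdtraj(coords: np.ndarray, topology):
    """Convert an ensemble to an mdtraj Trajectory (nm) for oracle checks."""
    import mdtraj as md
    from mdtraj.core import element as elem

    elements = {"C": elem.carbon, "N": elem.nitrogen, "O": elem.oxygen,
                "S": elem.sulfur, "H": elem.hydrogen}
    top = md.Topology()
    chain = top.add_chain()
    residues = {ui: top.add_residue(u.name, chain)
                for ui, u in enumerate(topology.units)}
    for a in topology.atoms:
        top.add_atom(a.name, elements[a.element], residues[a.unit])
    if coords.ndim == 2:
        coords = coords[None]
    return md.Trajectory(coords / 10.0, top)
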