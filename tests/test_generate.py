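"""Peptide builder and helix-coil generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from contactdof.core import SegmentSpec
from contactdof.generate import (ContactBias, DihedralProfile, HelixCoilModel,
                                 PseudoLigand, attach_pseudo_ligand,
                                 build_peptide, sample_helix_coil)
from contactdof.geometry import dihedral


def _atom(top, xyz, internal, name):
    return xyz[top.find_atom(internal, name)]


class TestBuilder:
    def test_requested_dihedrals_are_realized(self, spec406):
        rng = np.random.default_rng(7)
        phi = rng.uniform(-179, 179, 21)
        psi = rng.uniform(-179, 179, 21)
        xyz, top = build_peptide(spec406, DihedralProfile(phi, psi))
        for i in range(21):
            internal = i + 2
            got_phi = dihedral(_atom(top, xyz, internal - 1, "C"),
                               _atom(top, xyz, internal, "N"),
                               _atom(top, xyz, internal, "CA"),
                               _atom(top, xyz, internal, "C"))
            got_psi = dihedral(_atom(top, xyz, internal, "N"),
                               _atom(top, xyz, internal, "CA"),
                               _atom(top, xyz, internal, "C"),
                               _atom(top, xyz, internal + 1, "N"))
            assert abs(float(got_phi) - phi[i]) < 1.0
            assert abs(float(got_psi) - psi[i]) < 1.0

    def test_single_residue_segment(self):
        spec = SegmentSpec(406, "C", flank=0)
        xyz, top = build_peptide(spec, DihedralProfile([-60.0], [140.0]))
        assert top.n_units == 3
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        assert d[np.triu_indices(len(xyz), 1)].min() > 0

    def test_helix_has_i_i4_hbond_geometry(self, helix_frame):
        # standard alpha-helix O(i)...N(i+4) must emerge from the builder
        xyz, top = helix_frame
        for internal in range(3, 18):
            d = np.linalg.norm(_atom(top, xyz, internal, "O")
                               - _atom(top, xyz, internal + 4, "N"))
            assert d < 3.5

    def test_extended_has_no_long_range_contacts(self, extended_frame):
        xyz, top = extended_frame
        for i in range(1, 24):
            ai = top.atoms_of_internal_index(i)
            for j in range(i + 3, 24):
                aj = top.atoms_of_internal_index(j)
                d = np.linalg.norm(xyz[ai][:, None] - xyz[aj][None], axis=-1)
                assert d.min() > 4.2

    def test_geometry_sanity(self, helix_frame):
        xyz, top = helix_frame
        # no clashes in the ideal helix
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        assert d[np.triu_indices(len(xyz), 1)].min() >= 0.5
        # bonded backbone atoms stay under 2 A
        for internal in range(2, 23):
            for pair in (("N", "CA"), ("CA", "C"), ("C", "O")):
                b = np.linalg.norm(_atom(top, xyz, internal, pair[0])
                                   - _atom(top, xyz, internal, pair[1]))
                assert b < 2.0

    def test_residue_count_mismatch_rejected(self, spec406):
        with pytest.raises(ValueError, match="residues"):
            build_peptide(spec406, DihedralProfile([-57.0] * 5, [-47.0] * 5))

    def test_angles_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            DihedralProfile([200.0], [0.0])
        with pytest.raises(ValueError, match="psi"):
            DihedralProfile([0.0], [-180.0])


class TestHelixCoil:
    def test_all_helix_matches_ideal_build(self, spec406, helix_frame):
        xyz, _ = helix_frame
        ens = sample_helix_coil(
            spec406, HelixCoilModel(p_helix=1.0, n_frames=10, seed=3))
        assert np.allclose(ens.coords, xyz[None], atol=1e-9)

    def test_state_frequency_matches_marginal(self, spec406):
        ens = sample_helix_coil(
            spec406, HelixCoilModel(p_helix=0.7, n_frames=2000, seed=11))
        freq = ens.helix_states.mean(axis=0)
        assert np.all(np.abs(freq[2:19] - 0.7) <= 0.03)

    def test_seeded_reproducibility(self, spec406):
        m = HelixCoilModel(p_helix=0.6, n_frames=50, seed=99)
        a = sample_helix_coil(spec406, m)
        b = sample_helix_coil(spec406, m)
        assert a.coords.tobytes() == b.coords.tobytes()

    def test_invalid_probability_rejected(self, spec406):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            sample_helix_coil(spec406,
                              HelixCoilModel(p_helix=1.2, n_frames=2))

    @given(p=st.floats(0.0, 1.0), c=st.floats(0.0, 0.99))
    def test_markov_chain_preserves_marginals(self, p, c):
        # analytic invariance of the two-state chain, checked by simulation
        from contactdof.generate import sample_states
        rng = np.random.default_rng(5)
        states = sample_states(np.full((4000, 8), p), c, rng)
        assert np.all(np.abs(states.mean(axis=0) - p) <= 0.05)


class TestPseudoLigand:
    def test_fragment_labels_present(self, hc_ensemble):
        lig = attach_pseudo_ligand(hc_ensemble)
        frags = [a.fragment for a in lig.topology.atoms if a.fragment]
        assert set(frags) == {"A-ring", "B-ring", "stem"}
        assert len(frags) == 8

    @pytest.mark.parametrize("fraction,tol", [(1.0, 0.0), (0.6, 4.0)])
    def test_bias_fraction_is_realized(self, spec406, fraction, tol):
        n_frames = 200 if fraction == 1.0 else 1000
        ens = sample_helix_coil(
            spec406, HelixCoilModel(p_helix=0.8, n_frames=n_frames, seed=21))
        lig = attach_pseudo_ligand(ens, bias=ContactBias(5, fraction), seed=4)
        b = lig.topology.fragment_atoms("B-ring")
        r5 = lig.topology.atoms_of_internal_index(5)
        hits = 0
        for f in range(lig.n_frames):
            d = np.linalg.norm(lig.coords[f][b][:, None]
                               - lig.coords[f][r5][None], axis=-1)
            hits += d.min() <= 4.2
        assert abs(100.0 * hits / lig.n_frames - 100.0 * fraction) <= tol

    def test_missing_attachment_site_rejected(self):
        spec = SegmentSpec(100, "A" * 21, 10)  # no central Cys, no SG
        ens = sample_helix_coil(spec, HelixCoilModel(n_frames=2, seed=0))
        with pytest.raises(ValueError, match="attachment site"):
            attach_pseudo_ligand(ens)

    def test_ligand_bonds_only_through_attachment(self, hc_ensemble):
        # every ligand atom stays within reach of the SG-anchored chain
        lig = attach_pseudo_ligand(hc_ensemble)
        sg = lig.topology.find_atom(12, "SG")
        la = [i for i, a in enumerate(lig.topology.atoms) if a.fragment]
        d = np.linalg.norm(lig.coords[:, la] - lig.coords[:, [sg]], axis=-1)
        assert d.max() < 25.0
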