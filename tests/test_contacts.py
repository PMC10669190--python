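"""Contact maps, contact DOFs, and fragment contact profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from contactdof.contacts import (ContactFeaturizer, contact_map, contact_maps,
                                 contact_vectors, fragment_contact_profile,
                                 mean_contact_map, pair_labels, read_rle,
                                 unvectorize, vectorize, write_rle)
from contactdof.core import SegmentSpec
from contactdof.generate import (ContactBias, HelixCoilModel,
                                 attach_pseudo_ligand, generate_liganded,
                                 sample_helix_coil)

from conftest import brute_force_contact_map


class TestContactMap:
    def test_kernel_equals_brute_force_scan(self, helix_frame, extended_frame,
                                            hc_ensemble):
        for xyz, top in (helix_frame, extended_frame):
            assert np.array_equal(contact_map(xyz, top),
                                  brute_force_contact_map(xyz, top))
        for f in range(0, hc_ensemble.n_frames, 60):
            assert np.array_equal(
                contact_map(hc_ensemble.coords[f], hc_ensemble.topology),
                brute_force_contact_map(hc_ensemble.coords[f],
                                        hc_ensemble.topology))

    def test_coincident_atoms_are_in_contact(self, helix_frame):
        xyz, top = helix_frame
        xyz = xyz.copy()
        a5 = top.atoms_of_internal_index(5)[0]
        a15 = top.atoms_of_internal_index(15)[0]
        xyz[a15] = xyz[a5]  # distance 0 <= cutoff
        m = contact_map(xyz, top)
        assert m[4, 14] == 1 and m[14, 4] == 1

    def test_helix_band_structure(self, helix_frame):
        m = contact_map(*helix_frame)
        for i in range(3, 16):  # internal units i, i+4 (0-based i-1)
            assert m[i - 1, i + 3] == 1
        for i in range(2, 12):
            assert m[i - 1, i + 7] == 0  # no i,i+8 contact in an alpha helix

    def test_extended_has_no_long_range_contacts(self, extended_frame):
        m = contact_map(*extended_frame)
        n = m.shape[0]
        for i in range(n):
            for j in range(i + 3, n):
                assert m[i, j] == 0

    def test_symmetric_binary_with_unit_diagonal(self, hc_ensemble):
        maps = contact_maps(hc_ensemble)
        assert np.array_equal(maps, np.swapaxes(maps, 1, 2))
        assert set(np.unique(maps)) <= {0, 1}
        assert np.all(maps[:, np.arange(23), np.arange(23)] == 1)

    def test_monotone_in_cutoff(self, hc_ensemble):
        small = contact_maps(hc_ensemble[:40], cutoff=4.2)
        large = contact_maps(hc_ensemble[:40], cutoff=5.5)
        assert np.all(small <= large)

    def test_invalid_inputs_rejected(self, helix_frame):
        xyz, top = helix_frame
        with pytest.raises(ValueError, match="cutoff"):
            contact_map(xyz, top, cutoff=0.0)
        with pytest.raises(ValueError, match="match"):
            contact_map(xyz[:-1], top)


class TestMeanMap:
    def test_identical_frames_give_single_frame_map(self, helix_frame):
        from contactdof.core import Ensemble
        xyz, top = helix_frame
        ens = Ensemble(top, np.repeat(xyz[None], 5, axis=0))
        assert np.array_equal(mean_contact_map(ens), contact_map(xyz, top))

    def test_half_mixture_gives_half(self, helix_frame, extended_frame):
        from contactdof.core import Ensemble
        xyz_h, top = helix_frame
        xyz_e, _ = extended_frame
        ens = Ensemble(top, np.stack([xyz_h, xyz_e]))
        m = mean_contact_map(ens)
        # (i, i+4) contact present in helix only -> mean 0.5
        assert m[4, 8] == 0.5

    def test_mean_matches_direct_count(self, hc_ensemble):
        m = mean_contact_map(hc_ensemble, analysis_stride_ps=None)
        counted = np.stack([
            brute_force_contact_map(hc_ensemble.coords[f],
                                    hc_ensemble.topology)
            for f in range(hc_ensemble.n_frames)]).mean(axis=0)
        for i in range(3, 18):
            assert abs(m[i, i + 4] - counted[i, i + 4]) <= 0.05
        assert np.allclose(m, m.T)
        assert m.min() >= 0 and m.max() <= 1

    def test_stride_leaving_no_frames_rejected(self, hc_ensemble):
        with pytest.raises(ValueError, match="positive"):
            mean_contact_map(hc_ensemble, analysis_stride_ps=-1)


class TestVectorize:
    def test_23_units_give_253_dofs(self, helix_frame):
        m = contact_map(*helix_frame)
        assert m.shape == (23, 23)
        assert vectorize(m).shape == (253,)

    @given(n=st.integers(2, 30))
    def test_length_law(self, n):
        m = np.zeros((n, n))
        assert len(vectorize(m)) == n * (n - 1) // 2
        assert len(pair_labels(n)) == n * (n - 1) // 2

    def test_roundtrip(self, hc_ensemble):
        m = mean_contact_map(hc_ensemble)
        back = unvectorize(vectorize(m))
        off = ~np.eye(23, dtype=bool)
        assert np.array_equal(back[off], m[off])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            vectorize(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="n\\(n-1\\)/2"):
            unvectorize(np.zeros(5))

    def test_featurizer_transform(self, hc_ensemble):
        from sklearn.base import clone
        est = ContactFeaturizer(cutoff=4.2)
        X = clone(est).fit(hc_ensemble).transform(hc_ensemble)
        assert X.shape == (hc_ensemble.n_frames, 253)
        assert np.array_equal(X[0], vectorize(
            contact_map(hc_ensemble.coords[0], hc_ensemble.topology)))


class TestFragmentProfile:
    def test_forced_contact_reads_100(self, spec406):
        ens = sample_helix_coil(spec406, HelixCoilModel(n_frames=50, seed=6))
        lig = attach_pseudo_ligand(ens, bias=ContactBias(5, 1.0), seed=1)
        prof = fragment_contact_profile(lig)
        assert prof.loc[5, "B-ring"] == 100.0
        # attachment residue always contacts its own stem
        assert prof.loc[12, "stem"] == 100.0
        assert prof.loc[12, "Cys"] == 100.0

    def test_distal_residues_read_zero(self, spec406):
        ens = sample_helix_coil(
            spec406, HelixCoilModel(p_helix=1.0, n_frames=20, seed=6))
        lig = attach_pseudo_ligand(ens)  # unbiased, points away
        prof = fragment_contact_profile(lig)
        assert prof.loc[1, "B-ring"] == 0.0
        assert prof.loc[23, "A-ring"] == 0.0

    def test_partial_bias_ratio_recovered(self, spec406):
        ens = sample_helix_coil(
            spec406, HelixCoilModel(p_helix=0.8, n_frames=1000, seed=31))
        lig = attach_pseudo_ligand(ens, bias=ContactBias(5, 0.6), seed=2)
        prof = fragment_contact_profile(lig, analysis_stride_ps=None)
        # direct per-frame count oracle
        b = lig.topology.fragment_atoms("B-ring")
        r5 = lig.topology.atoms_of_internal_index(5)
        hits = sum(
            np.linalg.norm(lig.coords[f][b][:, None]
                           - lig.coords[f][r5][None], axis=-1).min() <= 4.2
            for f in range(lig.n_frames))
        assert prof.loc[5, "B-ring"] == pytest.approx(100.0 * hits / 1000)
        assert abs(prof.loc[5, "B-ring"] - 60.0) <= 4.0

    def test_profile_bounds_and_missing_labels(self, spec406, hc_ensemble):
        with pytest.raises(ValueError, match="fragment"):
            fragment_contact_profile(hc_ensemble)
        lig = attach_pseudo_ligand(hc_ensemble)
        prof = fragment_contact_profile(lig)
        assert prof.values.min() >= 0.0 and prof.values.max() <= 100.0


class TestRunLengthFormat:
    def test_roundtrip(self, tmp_path, hc_ensemble):
        vecs = contact_vectors(hc_ensemble[:30])
        p = tmp_path / "maps.rle"
        write_rle(vecs, p)
        assert np.array_equal(read_rle(p), vecs)
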