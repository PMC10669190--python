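"""Index bookkeeping, PDB round-trips, registry, block splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from contactdof.core import SegmentSpec
from contactdof.generate import HelixCoilModel, attach_pseudo_ligand, sample_helix_coil
from contactdof.trajio import (StudyRegistry, SystemRecord,
                               discard_equilibration, internal_index,
                               load_registry, read_ensemble,
                               sequence_position, split_blocks,
                               write_ensemble)


class TestInternalIndex:
    @pytest.mark.parametrize("pos,expected", [(399, 5), (403, 9), (406, 12)])
    def test_indexing_convention_anchors(self, spec406, pos, expected):
        # W399 -> #5, A403 -> #9, central Cys C406 -> #12
        assert internal_index(pos, spec406) == expected

    def test_out_of_segment_rejected(self, spec406):
        for pos in (395, 417):
            with pytest.raises(ValueError, match="outside segment"):
                internal_index(pos, spec406)

    @given(center=st.integers(50, 800), flank=st.integers(0, 12),
           offset=st.integers(-12, 12))
    def test_bijection_over_segment(self, center, flank, offset):
        if abs(offset) > flank:
            return
        spec = SegmentSpec(center, "A" * (2 * flank + 1), flank)
        pos = center + offset
        idx = internal_index(pos, spec)
        assert 2 <= idx <= 2 * flank + 2
        assert sequence_position(idx, spec) == pos

    def test_caps_have_no_sequence_position(self, spec406):
        for idx in (1, 23):
            with pytest.raises(ValueError, match="cap"):
                sequence_position(idx, spec406)


class TestEnsembleIO:
    def test_roundtrip_coordinates_and_topology(self, tmp_path, spec406):
        ens = sample_helix_coil(
            spec406, HelixCoilModel(p_helix=0.7, n_frames=10, seed=8))
        ens = attach_pseudo_ligand(ens)
        ens.label = "demo"
        pdb = tmp_path / "e.pdb"
        write_ensemble(ens, pdb)
        back = read_ensemble(pdb)
        assert back.n_frames == 10
        assert np.abs(back.coords - ens.coords).max() <= 1e-3
        assert [u.name for u in back.topology.units] == \
               [u.name for u in ens.topology.units]
        assert back.topology.segment == spec406
        frags = [a.fragment for a in back.topology.atoms if a.fragment]
        assert frags == [a.fragment for a in ens.topology.atoms if a.fragment]

    def test_single_model_reads_as_one_frame(self, tmp_path, spec406):
        ens = sample_helix_coil(spec406, HelixCoilModel(n_frames=1, seed=0))
        pdb = tmp_path / "one.pdb"
        write_ensemble(ens, pdb)
        assert read_ensemble(pdb).n_frames == 1

    def test_missing_atom_in_model_reported(self, tmp_path, spec406):
        ens = sample_helix_coil(spec406, HelixCoilModel(n_frames=4, seed=0))
        pdb = tmp_path / "bad.pdb"
        write_ensemble(ens, pdb)
        lines = pdb.read_text().splitlines(keepends=True)
        # drop one ATOM record from model 3
        n_model = 0
        for i, ln in enumerate(lines):
            if ln.startswith("MODEL"):
                n_model += 1
            elif n_model == 3 and ln.startswith("ATOM"):
                del lines[i]
                break
        pdb.write_text("".join(lines))
        with pytest.raises(ValueError, match="model 3"):
            read_ensemble(pdb)


class TestRegistry:
    def test_packaged_study_design_has_14_systems(self):
        reg = load_registry()
        assert len(reg) == 14
        assert len(set(reg.notations)) == 14

    def test_center_filters(self):
        reg = load_registry()
        # Center counts from the study roster: 7 + 4 + 3
        assert len(reg.filter(center=406)) == 7
        assert len(reg.filter(center=327)) == 4
        assert len(reg.filter(center=240)) == 3
        assert len(reg.filter(liganded=False)) == 6

    def test_record_fields(self):
        rec = load_registry()["XNN_4H"]
        assert (rec.center, rec.start, rec.ligand, rec.run_ns) == \
               (406, "H", "XNN", 100)
        assert load_registry()["NTD_2H"].ligand is None

    def test_empty_config(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("notation,center,start,ligand,run_ns,ion,n_water\n")
        assert len(load_registry(p)) == 0

    def test_duplicate_notation_rejected(self):
        rec = SystemRecord("X_4H", 406, "H", None, 50, None, 100)
        with pytest.raises(ValueError, match="duplicate"):
            StudyRegistry([rec, rec])

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError, match="center"):
            StudyRegistry([SystemRecord("A", 999, "H", None, 50, None, 1)])
        with pytest.raises(ValueError, match="start"):
            StudyRegistry([SystemRecord("A", 406, "Q", None, 50, None, 1)])


class TestBlocks:
    @pytest.mark.parametrize("n_frames,n_blocks,sizes",
                             [(100, 2, [50, 50]), (101, 2, [51, 50]),
                              (10, 3, [4, 3, 3])])
    def test_partition_sizes(self, spec406, n_frames, n_blocks, sizes):
        ens = sample_helix_coil(
            spec406, HelixCoilModel(n_frames=n_frames, seed=1))
        blocks = split_blocks(ens, n_blocks)
        assert [b.n_frames for b in blocks] == sizes
        restored = np.concatenate([b.coords for b in blocks])
        assert np.array_equal(restored, ens.coords)
        assert blocks[0].label.endswith("_1")

    def test_single_block_is_identity(self, hc_ensemble):
        assert split_blocks(hc_ensemble, 1) == [hc_ensemble]

    def test_too_few_frames_rejected(self, spec406):
        ens = sample_helix_coil(spec406, HelixCoilModel(n_frames=2, seed=1))
        with pytest.raises(ValueError, match="split"):
            split_blocks(ens, 3)

    def test_discard_equilibration(self, hc_ensemble):
        out = discard_equilibration(hc_ensemble, 50)
        assert out.n_frames == hc_ensemble.n_frames - 50
        assert np.array_equal(out.coords, hc_ensemble.coords[50:])
        assert discard_equilibration(hc_ensemble, 0) is hc_ensemble
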