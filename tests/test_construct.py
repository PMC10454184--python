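"""Construct assembly, PDB coarse-graining and topology derivation."""

import numpy as np
import pytest

from fretforge import (
    CGStructure,
    ConstructSpec,
    EmptySelectionError,
    Segment,
    assemble_fusion,
    derive_topology,
    potential_energy,
    read_reference_pdb,
    read_structure_pdb,
    read_topology,
    write_structure_pdb,
    write_topology,
)
from conftest import TOY_PDB_1RES, TOY_PDB_3RES, TOY_PDB_NO_CA, make_chain


class TestReadReferencePDB:
    def test_single_residue(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(TOY_PDB_1RES)
        s = read_reference_pdb(p)
        assert s.n_beads == 1
        assert np.allclose(s.coords[0], 0.0)

    def test_three_residues_ca_positions(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(TOY_PDB_3RES)
        s = read_reference_pdb(p)
        assert s.n_beads == 3
        d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
        assert np.allclose(d, 3.8)
        # heavy atoms of residue 2 retained (CA + CB)
        assert s.heavy[1].shape[0] == 2

    def test_residue_without_ca_skipped_with_warning(self, tmp_path):
        p = tmp_path / "gap.pdb"
        p.write_text(TOY_PDB_NO_CA)
        with pytest.warns(UserWarning, match="without a C-alpha"):
            s = read_reference_pdb(p)
        assert s.n_beads == 2

    def test_empty_selection(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(TOY_PDB_1RES)
        with pytest.raises(EmptySelectionError):
            read_reference_pdb(p, chain="Z")

    def test_bead_count_matches_ca_record_count(self, tmp_path, open_dumbbell):
        """Independent oracle: count CA ATOM records by plain text scan."""
        p = tmp_path / "dumbbell.pdb"
        write_structure_pdb(open_dumbbell, p)
        n_ca = sum(1 for line in p.read_text().splitlines()
                   if line.startswith("ATOM") and line[12:16].strip() == "CA")
        # the file holds several chains; read them all
        total = 0
        for chain in "ABCDEF":
            try:
                total += read_reference_pdb(p, chain=chain).n_beads
            except EmptySelectionError:
                pass
        assert total == n_ca == open_dumbbell.n_beads


class TestAssembleFusion:
    @staticmethod
    def _one_bead():
        return make_chain(np.zeros((1, 3)))

    def test_minimal_three_bead_chain(self):
        spec = ConstructSpec(yfp_seq="A", cfp_seq="A", linker1="", linker2="",
                             core_span=(1, 1), core_domain_boundary=1)
        fused = assemble_fusion(spec, self._one_bead(), self._one_bead(),
                                self._one_bead(), rng_seed=0)
        assert fused.n_beads == 3
        d = np.linalg.norm(np.diff(fused.coords, axis=0), axis=1)
        assert np.allclose(d, 3.8)

    def test_reference_construct_bookkeeping(self):
        """Linkers LE/AGGR and the 7-residue YFP completion give the stated
        segment layout: n = len(YFP) + 2 + core + 4 + len(CFP)."""
        rng = np.random.default_rng(0)
        n_fp_struct, n_core = 20, 30
        yfp_seq = "A" * n_fp_struct + "EGMNELY"   # completion modeled
        cfp_seq = "A" * n_fp_struct
        spec = ConstructSpec(
            yfp_seq=yfp_seq, cfp_seq=cfp_seq,
            core_span=(208, 208 + n_core - 1), core_domain_boundary=15,
            yfp_chromophore_offset=5, yfp_dipole_ref_offset=10,
            cfp_chromophore_offset=5, cfp_dipole_ref_offset=10)

        def blob(n):
            from conftest import random_compact_chain
            return random_compact_chain(rng, n)

        fused = assemble_fusion(spec, blob(n_core), blob(n_fp_struct),
                                blob(n_fp_struct), rng_seed=4)
        assert fused.n_beads == len(yfp_seq) + 2 + n_core + 4 + len(cfp_seq)
        seg = fused.segments
        bounds = [len(yfp_seq), 2, 15, n_core - 15, 4, len(cfp_seq)]
        expected = np.concatenate([np.full(b, c) for b, c in
                                   zip(bounds, [0, 1, 2, 3, 4, 5])])
        assert np.array_equal(seg, expected)
        fused.validate()
        # linker and completed residues carry the modeled flag
        assert fused.modeled[len(yfp_seq) - 7:len(yfp_seq) + 2].all()

    def test_assembly_deterministic(self):
        spec = ConstructSpec(yfp_seq="AAAA", cfp_seq="AAAA", core_span=(1, 6),
                             core_domain_boundary=3)
        rng = np.random.default_rng(5)
        from conftest import random_compact_chain
        core = random_compact_chain(rng, 6)
        fp1 = random_compact_chain(rng, 4)
        fp2 = random_compact_chain(rng, 4)
        a = assemble_fusion(spec, core, fp1, fp2, rng_seed=9)
        b = assemble_fusion(spec, core, fp1, fp2, rng_seed=9)
        assert np.array_equal(a.coords, b.coords)

    def test_circular_permutation_bookkeeping(self):
        spec = ConstructSpec(yfp_seq="ABCDEFGH", cfp_seq="AA",
                             yfp_chromophore_offset=2, cp_offset=3)
        assert spec.yfp_seq == "DEFGHABC"
        assert spec.yfp_seq[spec.yfp_chromophore_offset] == "C"


class TestDeriveTopology:
    def test_three_collinear_beads(self):
        s = make_chain([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        t = derive_topology(s)
        assert t.bond_idx.shape == (2, 2)
        assert np.allclose(t.bond_r0, 3.8)
        assert t.angle_idx.shape == (1, 3)
        assert np.isclose(t.angle_t0[0], np.pi)
        assert t.dihedral_idx.shape == (0, 4)
        assert t.n_contacts == 0

    def test_single_ca_contact(self):
        z = np.sqrt(5.0 ** 2 - 3.8 ** 2)
        coords = [[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 0],
                  [0, 3.8, z]]
        s = make_chain(coords)
        # beads 0 and 4 are 5.0 A apart with |i-j| = 4
        assert np.isclose(np.linalg.norm(s.coords[4] - s.coords[0]), 5.0)
        t = derive_topology(s, contact_cutoff=6.5)
        assert t.n_contacts == 1
        assert tuple(t.contact_idx[0]) == (0, 4)
        assert np.isclose(t.contact_r0[0], 5.0)

    def test_contact_count_matches_pair_scan(self, open_dumbbell):
        """Independent O(n^2) oracle with the same contact rules."""
        from scipy.spatial.distance import cdist

        s = open_dumbbell
        t = derive_topology(s)
        d = cdist(s.coords, s.coords)
        n = s.n_beads
        linker = np.isin(s.segments, [int(Segment.LINKER1),
                                      int(Segment.LINKER2)])
        count = sum(
            1
            for i in range(n)
            for j in range(i + 4, n)
            if not linker[i] and not linker[j] and d[i, j] < 6.5
        )
        assert t.n_contacts == count

    def test_no_contacts_anchored_in_linkers(self, open_dumbbell):
        t = derive_topology(open_dumbbell)
        linker = np.isin(open_dumbbell.segments,
                         [int(Segment.LINKER1), int(Segment.LINKER2)])
        assert not linker[t.contact_idx].any()

    def test_interdomain_scale_zero_removes_energy(self, closed_dumbbell):
        t1 = derive_topology(closed_dumbbell, interdomain_scale=1.0)
        t0 = derive_topology(closed_dumbbell, interdomain_scale=0.0)
        assert t1.n_interdomain > 0
        e1 = potential_energy(closed_dumbbell, t1)
        e0 = potential_energy(closed_dumbbell, t0)
        # at the native coordinates each interdomain contact contributes -eps
        expected = t1.contact_eps[t1.contact_inter].sum()
        assert np.isclose(e0 - e1, expected, rtol=1e-10)

    def test_contact_pairs_unique_and_ordered(self, closed_dumbbell):
        t = derive_topology(closed_dumbbell)
        i, j = t.contact_idx.T
        assert (j - i >= 4).all()
        keys = i * closed_dumbbell.n_beads + j
        assert len(np.unique(keys)) == len(keys)


class TestFileRoundTrips:
    def test_structure_pdb_round_trip(self, tmp_path, open_dumbbell):
        p = tmp_path / "m.pdb"
        write_structure_pdb(open_dumbbell, p)
        back = read_structure_pdb(p)
        assert np.abs(back.coords - open_dumbbell.coords).max() < 1e-3
        assert np.array_equal(back.segments, open_dumbbell.segments)

    def test_multi_model_round_trip(self, tmp_path, open_dumbbell):
        frames = np.stack([open_dumbbell.coords,
                           open_dumbbell.coords + [1.0, 0.0, 0.0]])
        p = tmp_path / "traj.pdb"
        write_structure_pdb(open_dumbbell, p, frames=frames)
        text = p.read_text()
        assert text.count("MODEL") == 2

    def test_topology_table_round_trip(self, tmp_path, open_dumbbell):
        t = derive_topology(open_dumbbell)
        p = tmp_path / "m.top"
        write_topology(t, p)
        back = read_topology(p)
        assert np.array_equal(back.bond_idx, t.bond_idx)
        assert np.allclose(back.bond_r0, t.bond_r0)
        assert np.allclose(back.angle_t0, t.angle_t0, atol=1e-7)
        assert np.allclose(back.dihedral_p0, t.dihedral_p0, atol=1e-7)
        assert np.array_equal(back.contact_idx, t.contact_idx)
        assert np.allclose(back.contact_eps, t.contact_eps)
        assert np.array_equal(back.contact_inter, t.contact_inter)
        assert back.sigma_ev == t.sigma_ev and back.eps_ev == t.eps_ev

    def test_construct_spec_yaml_round_trip(self, tmp_path):
        spec = ConstructSpec(yfp_seq="AAEGMNELY", cfp_seq="GGG",
                             yfp_chromophore_offset=1)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        back = ConstructSpec.from_yaml(p)
        assert back == spec
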