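"""Structure editing: mutate, flip, methylate, extend, connect."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dnaforge as df
from dnaforge.editor import optimal_bridge_length
from dnaforge.exceptions import EditError, NotMethylatableError, UnknownBaseError
from dnaforge.geometry import Frame
from dnaforge.templates import DEFAULT_TEMPLATES


class TestMutate:
    def test_complementary_updates_partner(self, small_duplex):
        m = df.mutate(small_duplex, {0: "G"})
        assert m.sequence[0] == "G"
        assert m.anti_sequence[-1] == "C"

    def test_non_complementary_leaves_partner(self, small_duplex):
        # A at position 0 paired with the old partner of A (T stays T)
        m = df.mutate(small_duplex, {1: "A"}, complementary=False)
        assert m.sequence[1] == "A"
        assert m.anti_sequence == small_duplex.anti_sequence

    def test_idempotent_on_identical_targets(self, small_duplex):
        m = df.mutate(small_duplex, {i: c for i, c in enumerate(small_duplex.sequence)})
        assert m.sequence == small_duplex.sequence
        assert np.array_equal(m.frames, small_duplex.frames)

    def test_frames_untouched(self, small_duplex):
        m = df.mutate(small_duplex, {0: "G", 5: "T"})
        assert np.array_equal(m.frames, small_duplex.frames)

    def test_bad_inputs(self, small_duplex):
        with pytest.raises(UnknownBaseError):
            df.mutate(small_duplex, {0: "X"})
        with pytest.raises(EditError):
            df.mutate(small_duplex, {99: "A"})


class TestFlip:
    def test_involution_at_180(self, small_duplex):
        once = df.flip(small_duplex, [2])
        twice = df.flip(once, [2])
        a0 = df.to_atomic(small_duplex)
        a2 = df.to_atomic(twice)
        assert np.max(np.abs(a0.coordinates - a2.coordinates)) < 1e-9
        assert once.hoogsteen == {2} and twice.hoogsteen == set()

    def test_glycosidic_axis_atoms_are_fixed_points(self, small_duplex):
        pos = 0  # an A: purine, axis C1'-N9
        a0 = df.to_atomic(small_duplex)
        a1 = df.to_atomic(df.flip(small_duplex, [pos]))
        keys = [(c, int(r), n) for c, r, n in
                zip(a0.chain_ids, a0.residue_indices, a0.atom_names)]
        for axis_atom in ("C1'", "N9"):
            k = keys.index(("A", pos, axis_atom))
            assert np.allclose(a0.coordinates[k], a1.coordinates[k], atol=1e-12)

    def test_sugar_and_phosphate_do_not_move(self, small_duplex):
        a0 = df.to_atomic(small_duplex)
        a1 = df.to_atomic(df.flip(small_duplex, [4]))
        tpl = DEFAULT_TEMPLATES.get(small_duplex.sequence[4])
        backbone = [n for n, base in zip(tpl.atom_names, tpl.base_atom_mask())
                    if not base]
        keys = [(c, int(r), n) for c, r, n in
                zip(a0.chain_ids, a0.residue_indices, a0.atom_names)]
        for name in backbone:
            k = keys.index(("A", 4, name))
            assert np.allclose(a0.coordinates[k], a1.coordinates[k], atol=1e-12)

    def test_rotation_matches_rodrigues_oracle(self, small_duplex):
        angle = 73.0  # arbitrary-angle geometric flip (applied to the model)
        pos = 1
        a0 = df.to_atomic(small_duplex)
        a1 = df.flip(small_duplex, [pos], angle=angle).atomic()
        tpl = DEFAULT_TEMPLATES.get(small_duplex.sequence[pos])
        keys = [(c, int(r), n) for c, r, n in
                zip(a0.chain_ids, a0.residue_indices, a0.atom_names)]
        sel = [keys.index(("A", pos, n)) for n in tpl.atom_names]
        c1 = a0.coordinates[keys.index(("A", pos, "C1'"))]
        ng = a0.coordinates[keys.index(("A", pos, tpl.glycosidic_atoms[1]))]
        axis = (ng - c1) / np.linalg.norm(ng - c1)
        rot = Rotation.from_rotvec(np.radians(angle) * axis)  # independent oracle
        expected = a0.coordinates.copy()
        base_sel = [k for k, keep in zip(sel, tpl.base_atom_mask()) if keep]
        expected[base_sel] = rot.apply(expected[base_sel] - c1) + c1
        assert np.allclose(a1.coordinates, expected, atol=1e-9)

    def test_non_finite_angle_rejected(self, small_duplex):
        with pytest.raises(EditError):
            df.flip(small_duplex, [0], angle=float("nan"))


class TestMethylate:
    def test_cpg_auto_scan(self):
        s = df.make(sequence="ACGCGT")
        m = df.methylate(s, cpg_auto=True)
        assert m.methylated == {1, 3}

    def test_no_cpg_no_change(self):
        s = df.make(sequence="ATTATA")
        m = df.methylate(s, cpg_auto=True)
        assert m.methylated == set()
        assert np.array_equal(m.frames, s.frames)

    def test_atom_count_oracle(self):
        s = df.make(sequence="ACGCGTGC")
        m = df.methylate(s, cpg_auto=True)
        extra = df.to_atomic(m).n_atoms - df.to_atomic(s).n_atoms
        assert extra == len(m.methylated)  # one heavy atom per methyl

    def test_both_strands_cpg(self):
        s = df.make(sequence="AACGTT")
        m = df.methylate(s, cpg_auto=True, both_strands=True)
        assert m.methylated == {2}
        assert m.methylated_anti == {6 - 2 - 2}
        extra = df.to_atomic(m).n_atoms - df.to_atomic(s).n_atoms
        assert extra == 2

    def test_guanine_gets_n7_methyl(self):
        s = df.make(sequence="AGGA")
        m = df.methylate(s, positions=[1])
        model = df.to_atomic(m)
        assert "CM7" in model.atom_names
        names = [rn for _, rn, _ in model.chain_residues("A")]
        assert names[1] == "7MG"

    def test_at_bases_rejected(self):
        s = df.make(sequence="ATAT")
        with pytest.raises(NotMethylatableError):
            df.methylate(s, positions=[0])

    def test_remethylation_warns_noop(self):
        s = df.methylate(df.make(sequence="ACGT"), positions=[1])
        with pytest.warns(UserWarning):
            m = df.methylate(s, positions=[1])
        assert m.methylated == {1}

    def test_positions_xor_cpg_auto(self, small_duplex):
        with pytest.raises(EditError):
            df.methylate(small_duplex, positions=[1], cpg_auto=True)
        with pytest.raises(EditError):
            df.methylate(small_duplex)


class TestExtend:
    def test_extend_36_bp_preserves_original(self, linear80):
        out = df.extend(linear80, n_bp=36)
        assert out.n_bp == 116
        assert np.array_equal(out.frames[0, :80], linear80.frames[0])
        assert out.sequence[:80] == linear80.sequence

    def test_margin_defines_free_set(self, linear80):
        out = df.extend(linear80, n_bp=36, margin=3)
        assert out.free_indices == set(range(77, 116))

    def test_straight_extension_geometry(self, linear80):
        out = df.extend(linear80, n_bp=10)
        params = df.compute_rigid_parameters(out)
        rises = params["rise"][0, 79:-1]
        twists = params["twist"][0, 79:-1]
        assert np.allclose(rises, 0.34, atol=1e-9)
        assert np.allclose(twists, 360 / 10.5, atol=1e-9)

    def test_backward_extension(self, linear80):
        out = df.extend(linear80, sequence="ACGT", forward=False)
        assert out.n_bp == 84
        assert out.sequence[:4] == "ACGT"
        assert np.array_equal(out.frames[0, 4:], linear80.frames[0])
        assert out.free_indices == {0, 1, 2, 3, 4}

    def test_invalid_requests(self, linear80):
        circ = df.make(n_bp=105, circular=True)
        with pytest.raises(EditError):
            df.extend(circ, n_bp=10)
        with pytest.raises(EditError):
            df.extend(linear80, n_bp=10, sequence="ACGT")
        with pytest.raises(EditError):
            df.extend(linear80)


class TestConnect:
    def _offset_copy(self, a, gap, twist_steps):
        """A second duplex placed beyond a's 3' end: translated ``gap`` nm
        along the helix axis, rotated to be twist-compatible with a bridge
        of ``twist_steps`` ideal steps."""
        b = a.copy()
        chi = np.radians((a.n_bp - 1 + twist_steps) * 360 / 10.5)
        rot = Rotation.from_euler("z", chi).as_matrix()
        shift = a.frames[0, -1, 0] + [0, 0, gap]
        b.frames = a.frames.copy()
        b.frames[0, :, 0] = (a.frames[0, :, 0] - a.frames[0, 0, 0]) @ rot.T + shift
        b.frames[0, :, 1:] = a.frames[0, :, 1:] @ rot.T
        return b

    def test_bridge_length_brute_force_oracle(self, linear80):
        b = self._offset_copy(linear80, gap=3.4, twist_steps=10)
        a_end = Frame.from_array(linear80.frames[0, -1])
        b_start = Frame.from_array(b.frames[0, 0])
        n = optimal_bridge_length(a_end, b_start)
        # independent brute force over the candidate range
        rel = Rotation.from_matrix(
            a_end.triad @ b_start.triad.T).as_rotvec(degrees=True)[2]
        def penalty(m):
            d = (rel - m * 360 / 10.5 + 180.0) % 360.0 - 180.0
            return d * d
        candidates = range(2, 21)
        best = min(candidates, key=penalty)
        assert n == best == 10

    def test_total_length_conserved(self, linear80):
        b = self._offset_copy(linear80, gap=3.4, twist_steps=10)
        out = df.connect(linear80, b)
        assert out.n_bp == 80 + 10 + 80

    def test_terminal_frames_unchanged(self, linear80):
        b = self._offset_copy(linear80, gap=3.4, twist_steps=10)
        out = df.connect(linear80, b, margin=1)
        assert np.array_equal(out.frames[0, :80], linear80.frames[0])
        assert np.array_equal(out.frames[0, 90:], b.frames[0])
        assert out.free_indices == set(range(79, 91))

    def test_circular_inputs_rejected(self, linear80):
        circ = df.make(n_bp=105, circular=True)
        with pytest.raises(EditError):
            df.connect(linear80, circ)

    def test_overlapping_termini_need_explicit_n(self, linear80):
        b = self._offset_copy(linear80, gap=0.1, twist_steps=1)
        with pytest.raises(EditError):
            df.connect(linear80, b)
        out = df.connect(linear80, b, n_bp=3)
        assert out.n_bp == 163
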