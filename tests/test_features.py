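"""Feature encodings: compositions, PSSM parsing/normalization/composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aromapred.features import (
    DIPEPTIDES,
    RESIDUE_INDEX,
    FeatureVector,
    PSSMProfile,
    Scheme,
    aac,
    dpc,
    encode_dataset,
    hybrid,
    normalize_pssm,
    parse_pssm,
    pssm_composition,
    write_pssm,
)
from aromapred.io_seq import STANDARD_RESIDUES, ProteinRecord
from aromapred.synthetic import PSIBLAST_COLUMN_ORDER

from _oracles import count_dipeptides, count_residues

seq_strategy = st.text(alphabet=STANDARD_RESIDUES, min_size=2, max_size=120)


def _rec(seq: str) -> ProteinRecord:
    return ProteinRecord(id="t", sequence=seq)


class TestAAC:
    def test_homopolymer(self):
        v = aac(_rec("AAAA"))
        assert v.values[RESIDUE_INDEX["A"]] == 1.0
        assert v.values.sum() == pytest.approx(1.0)
        assert np.count_nonzero(v.values) == 1

    def test_two_residue_symmetry(self):
        v = aac(_rec("ACAC"))
        assert v.values[RESIDUE_INDEX["A"]] == pytest.approx(0.5)
        assert v.values[RESIDUE_INDEX["C"]] == pytest.approx(0.5)

    def test_matches_counting_oracle_on_random_sequence(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=200))
        v = aac(_rec(seq))
        counts = count_residues(seq)
        for res, i in RESIDUE_INDEX.items():
            assert v.values[i] == pytest.approx(counts.get(res, 0) / 200)

    @settings(max_examples=50, deadline=None)
    @given(seq_strategy)
    def test_sums_to_one_and_permutation_invariant(self, seq):
        v = aac(_rec(seq))
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)
        shuffled = "".join(sorted(seq))
        np.testing.assert_allclose(aac(_rec(shuffled)).values, v.values)


class TestDPC:
    def test_alternating_sequence(self):
        v = dpc(_rec("ACAC"))
        assert v.values[DIPEPTIDES.index("AC")] == pytest.approx(2 / 3)
        assert v.values[DIPEPTIDES.index("CA")] == pytest.approx(1 / 3)
        assert np.count_nonzero(v.values) == 2

    @pytest.mark.parametrize("n", [2, 5, 30])
    def test_homopolymer_single_dipeptide(self, n):
        v = dpc(_rec("A" * n))
        assert v.values[DIPEPTIDES.index("AA")] == 1.0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            dpc(_rec("M"))

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=100))
        v = dpc(_rec(seq))
        counts = count_dipeptides(seq)
        for k, dip in enumerate(DIPEPTIDES):
            assert v.values[k] == pytest.approx(counts.get(dip, 0) / 99)

    @settings(max_examples=50, deadline=None)
    @given(seq_strategy)
    def test_sums_to_one(self, seq):
        assert dpc(_rec(seq)).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_not_permutation_invariant(self):
        # AABB and ABAB share residue counts but provably different dipeptides
        a, b = dpc(_rec("AACC")), dpc(_rec("ACAC"))
        assert not np.allclose(a.values, b.values)
        np.testing.assert_allclose(aac(_rec("AACC")).values, aac(_rec("ACAC")).values)


class TestHybrid:
    def test_concatenation_definition(self, synth_small):
        ds, _ = synth_small
        rec = ds[0]
        h = hybrid(rec)
        assert len(h) == 420
        np.testing.assert_allclose(h.values[:20], aac(rec).values)
        np.testing.assert_allclose(h.values[20:], dpc(rec).values)

    def test_alternating_example(self):
        h = hybrid(_rec("ACAC"))
        assert h.values[RESIDUE_INDEX["A"]] == pytest.approx(0.5)
        assert h.values[20 + DIPEPTIDES.index("AC")] == pytest.approx(2 / 3)

    def test_every_vector_is_420(self, synth_small):
        ds, _ = synth_small
        assert all(len(hybrid(r)) == 420 for r in ds)


def _profile(seq: str, matrix) -> PSSMProfile:
    return PSSMProfile(seq, np.asarray(matrix, float), PSIBLAST_COLUMN_ORDER)


class TestParsePSSM:
    def _write(self, tmp_path, lines):
        p = tmp_path / "x.pssm"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_five_position_fixture(self, tmp_path):
        rng = np.random.default_rng(2)
        matrix = rng.integers(-5, 10, size=(5, 20)).astype(float)
        prof = _profile("MKLVW", matrix)
        path = write_pssm(prof, tmp_path / "p.pssm")
        back = parse_pssm(path)
        assert back.sequence == "MKLVW"
        assert back.matrix.shape == (5, 20)
        np.testing.assert_array_equal(back.matrix, matrix)
        assert back.residue_order == PSIBLAST_COLUMN_ORDER

    def test_truncated_row_names_line(self, tmp_path):
        header = "            " + "   ".join(PSIBLAST_COLUMN_ORDER)
        row = "    1 M " + " ".join(["1"] * 19)  # one score short
        p = self._write(tmp_path, ["", header, row])
        with pytest.raises(ValueError, match=":3"):
            parse_pssm(p)

    def test_non_integer_cell_rejected(self, tmp_path):
        header = "            " + "   ".join(PSIBLAST_COLUMN_ORDER)
        row = "    1 M " + " ".join(["1"] * 19 + ["x"])
        p = self._write(tmp_path, ["", header, row])
        with pytest.raises(ValueError, match="non-integer"):
            parse_pssm(p)

    def test_missing_header_rejected(self, tmp_path):
        p = self._write(tmp_path, ["nothing here"])
        with pytest.raises(ValueError, match="header|rows"):
            parse_pssm(p)

    def test_footer_statistics_ignored(self, tmp_path):
        header = "            " + "   ".join(PSIBLAST_COLUMN_ORDER)
        rows = [f"{i} {r} " + " ".join(["2"] * 20) for i, r in enumerate("MK", start=1)]
        p = self._write(
            tmp_path,
            ["", header, *rows, "", "                      K         Lambda", "0.04 0.2"],
        )
        assert parse_pssm(p).matrix.shape == (2, 20)


class TestNormalizePSSM:
    def test_hand_computed_example(self):
        m = np.full((1, 20), 0.0)
        m[0, :3] = [-3, 0, 5]
        out = normalize_pssm(_profile("M", m))
        np.testing.assert_allclose(out.matrix[0, :3], [0.0, 0.375, 1.0])

    def test_constant_matrix_maps_to_zero(self):
        out = normalize_pssm(_profile("MK", np.full((2, 20), 7.0)))
        assert np.all(out.matrix == 0.0)

    def test_range_is_unit_for_nonconstant_input(self):
        rng = np.random.default_rng(4)
        m = rng.integers(-8, 12, size=(10, 20)).astype(float)
        out = normalize_pssm(_profile("M" * 10, m))
        assert out.matrix.min() == 0.0
        assert out.matrix.max() == 1.0


class TestPSSMComposition:
    def test_homopolymer_all_ones(self):
        prof = _profile("AAAA", np.ones((4, 20)))
        v = pssm_composition(prof)
        grid = v.values.reshape(20, 20)
        assert np.all(grid[RESIDUE_INDEX["A"]] == 1.0)
        mask = np.ones(20, bool)
        mask[RESIDUE_INDEX["A"]] = False
        assert np.all(grid[mask] == 0.0)

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            pssm_composition(_profile("MK", np.full((2, 20), 3.0)))

    def test_component_bounded_by_residue_fraction(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=40))
        prof = normalize_pssm(_profile(seq, rng.integers(-5, 9, size=(40, 20)).astype(float)))
        grid = pssm_composition(prof).values.reshape(20, 20)
        freqs = {res: seq.count(res) / len(seq) for res in STANDARD_RESIDUES}
        for res, i in RESIDUE_INDEX.items():
            assert np.all(grid[i] <= freqs[res] + 1e-12)
            assert np.all(grid[i] >= 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=30))
        prof = normalize_pssm(_profile(seq, rng.integers(-6, 10, size=(30, 20)).astype(float)))
        got = pssm_composition(prof).values.reshape(20, 20)
        # independent accumulation straight from the definition
        expected = np.zeros((20, 20))
        for p, res in enumerate(seq):
            for c, col_res in enumerate(prof.residue_order):
                expected[RESIDUE_INDEX[res], RESIDUE_INDEX[col_res]] += prof.matrix[p, c]
        expected /= len(seq)
        np.testing.assert_allclose(got, expected)

    def test_constant_profile_reduces_to_scaled_aac(self):
        c = 0.6
        seq = "MKLVMKA"
        prof = _profile(seq, np.full((len(seq), 20), c))
        grid = pssm_composition(prof).values.reshape(20, 20)
        expected_aac = aac(_rec(seq)).values
        for j in range(20):
            np.testing.assert_allclose(grid[:, j], c * expected_aac, atol=1e-12)


class TestEncodeDataset:
    @pytest.mark.parametrize("scheme,dim", [
        ("aac", 20), ("dpc", 400), ("hybrid", 420),
    ])
    def test_dimensions_and_order(self, synth_small, scheme, dim):
        ds, _ = synth_small
        vecs = encode_dataset(ds, scheme)
        assert len(vecs) == len(ds)
        assert all(len(v) == dim for v in vecs)
        assert [v.source_id for v in vecs] == ds.ids

    def test_pssm_scheme(self, synth_small, tmp_path):
        from aromapred.synthetic import generate_pssm_fixtures
        ds, _ = synth_small
        generate_pssm_fixtures(ds, tmp_path, seed=7)
        vecs = encode_dataset(ds, "pssm", tmp_path)
        assert all(len(v) == 400 for v in vecs)
        assert all(0 <= v.values.min() and v.values.max() <= 1 for v in vecs)

    def test_missing_pssm_file_names_ids(self, synth_small, tmp_path):
        from aromapred.synthetic import generate_pssm_fixtures
        ds, _ = synth_small
        generate_pssm_fixtures(ds, tmp_path, seed=7)
        (tmp_path / f"{ds[0].id}.pssm").unlink()
        with pytest.raises(FileNotFoundError, match=ds[0].id):
            encode_dataset(ds, "pssm", tmp_path)

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(Scheme.AAC, np.zeros(19), "x")
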