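"""Conservation profiles: parsing, per-column counting, gap policies."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memprobe.alignment import (
    Alignment,
    AlignmentFormatError,
    ConservationConfig,
    conservation_heatmap_matrix,
    conservation_profile,
    read_alignment,
    read_profile_tsv,
    write_alignment_fasta,
    write_profile_tsv,
)

from _oracles import brute_conservation


def _aln(rows, reference_id="s0", ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment(ids=ids, rows=rows, reference_id=reference_id)


class TestReadAlignment:
    def test_fasta_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s0\nMAVILCYFWG\n>s1\nMAVILCYFWG\n>s2\nMAVILCYFW-\n")
        aln = read_alignment(p, "s0")
        assert aln.n_rows == 3 and aln.length == 10
        assert aln.reference_row == "MAVILCYFWG"

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">s0\nMAVILCYFWG\n>s1\nMAVILCYFW\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p, "s0")

    def test_missing_reference_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s0\nMAVI\n>s1\nMAVL\n")
        with pytest.raises(KeyError):
            read_alignment(p, "nope")

    def test_clustal_and_fasta_agree(self, tmp_path):
        from Bio import AlignIO

        fa = tmp_path / "a.fasta"
        fa.write_text(">s0\nMAVILCYFWG\n>s1\nMAVKLCYFWG\n>s2\nMAVILCY-WG\n")
        msa = AlignIO.read(str(fa), "fasta")
        cl = tmp_path / "a.aln"
        AlignIO.write(msa, str(cl), "clustal")
        a1 = read_alignment(fa, "s0")
        a2 = read_alignment(cl, "s0")
        assert a1.rows == a2.rows and a1.ids == a2.ids

    def test_nonstandard_letters_warn(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">s0\nMAVX\n>s1\nMAVB\n")
        with pytest.warns(UserWarning, match="nonstandard"):
            read_alignment(p, "s0")


class TestConservationProfile:
    def test_unanimous_column(self):
        prof = conservation_profile(_aln(["L", "L", "L", "L"]))
        assert prof.identity_pct[0] == 100.0 and prof.class_pct[0] == 100.0
        assert prof.modal_residues[0] == "L"

    def test_mixed_column_all_rows(self):
        prof = conservation_profile(_aln(["L", "V", "K", "E"]))
        assert prof.identity_pct[0] == 25.0
        assert prof.class_pct[0] == 50.0  # L, V in class

    @pytest.mark.parametrize(
        "policy,expected_class", [("nongap_rows", 200.0 / 3.0), ("all_rows", 50.0)]
    )
    def test_gap_policy_denominators(self, policy, expected_class):
        prof = conservation_profile(
            _aln(["L", "V", "-", "E"]), ConservationConfig(gap_policy=policy)
        )
        assert prof.class_pct[0] == pytest.approx(expected_class, abs=1e-9)

    def test_reference_gap_columns_skipped_not_renumbered(self):
        prof = conservation_profile(_aln(["LA-V", "LAKV", "LAKV"]))
        assert prof.positions.tolist() == [1, 2, 3]
        assert "".join(prof.reference_residues) == "LAV"

    def test_all_gap_reference_rejected(self):
        with pytest.raises(ValueError, match="all gaps"):
            conservation_profile(_aln(["--", "LV", "LV"]))

    def test_single_row_identity_always_100(self):
        prof = conservation_profile(_aln(["LKVG"]))
        assert (prof.identity_pct == 100.0).all()
        assert set(prof.class_pct.tolist()) <= {0.0, 100.0}

    def test_row_permutation_invariance(self, rng):
        rows = ["LAVKE", "LAVKD", "MAVIL", "GAV-L"]
        base = conservation_profile(_aln(rows))
        perm = list(rng.permutation(len(rows)))
        shuffled = conservation_profile(
            _aln([rows[i] for i in perm], reference_id="s0",
                 ids=[f"s{i}" for i in perm])
        )
        np.testing.assert_allclose(base.identity_pct, shuffled.identity_pct)
        np.testing.assert_allclose(base.class_pct, shuffled.class_pct)

    def test_row_duplication_invariance_all_rows(self):
        rows = ["LAVKE", "MAVIL", "GAV-L"]
        base = conservation_profile(_aln(rows))
        doubled = conservation_profile(_aln(rows + rows))
        np.testing.assert_allclose(base.identity_pct, doubled.identity_pct)
        np.testing.assert_allclose(base.class_pct, doubled.class_pct)

    @pytest.mark.parametrize("policy", ["all_rows", "nongap_rows"])
    def test_agrees_with_brute_force_on_random_alignments(self, policy, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(20):
            n_rows = int(rng.integers(2, 11))
            length = int(rng.integers(1, 51))
            mat = rng.choice(letters, size=(n_rows, length))
            mat[0] = rng.choice(letters[:-1], size=length)  # gap-free reference
            rows = ["".join(r) for r in mat]
            prof = conservation_profile(
                _aln(rows), ConservationConfig(gap_policy=policy)
            )
            expected = brute_conservation(rows, 0, set("MAVILCYFW"), policy)
            assert len(prof) == len(expected)
            for k, exp in enumerate(expected):
                assert prof.modal_residues[k] == exp["modal"]
                assert prof.identity_pct[k] == pytest.approx(exp["identity_pct"])
                assert prof.class_pct[k] == pytest.approx(exp["class_pct"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_class_ge_identity_when_modal_in_class(self, seed):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        mat = rng.choice(letters, size=(int(rng.integers(1, 8)), 6))
        prof = conservation_profile(_aln(["".join(r) for r in mat]))
        in_class = np.isin(prof.modal_residues, list("MAVILCYFW"))
        assert (prof.class_pct[in_class] >= prof.identity_pct[in_class] - 1e-12).all()


class TestHeatmapAndSerialization:
    def test_pairs_in_order(self):
        prof = conservation_profile(_aln(["LAVKE", "LAVKE"]))
        m = conservation_heatmap_matrix(prof)
        assert m.shape == (5, 2)
        np.testing.assert_allclose(m[:, 0], [1, 2, 3, 4, 5])
        np.testing.assert_allclose(m[:, 1], prof.class_pct)

    def test_all_zero_class(self):
        prof = conservation_profile(_aln(["KKK", "KKK"]))
        m = conservation_heatmap_matrix(prof)
        assert (m[:, 1] == 0.0).all()

    def test_windowed_layout_pads_with_nan(self):
        prof = conservation_profile(_aln(["LAVKE", "LAVKE"]))
        m = conservation_heatmap_matrix(prof, window=3)
        assert m.shape == (2, 3)
        assert np.isnan(m[1, 2])

    def test_tsv_round_trip_full_precision(self, tmp_path):
        rows = ["LAVKECD", "MAVILCY", "GAV-LKW"]
        prof = conservation_profile(_aln(rows))
        p = tmp_path / "prof.tsv"
        write_profile_tsv(prof, p)
        back = read_profile_tsv(p)
        np.testing.assert_array_equal(prof.identity_pct, back.identity_pct)
        np.testing.assert_array_equal(prof.class_pct, back.class_pct)
        assert prof.modal_residues.tolist() == back.modal_residues.tolist()

    def test_fasta_write_read_round_trip(self, tmp_path):
        aln = _aln(["LAVKE", "MAVIL"])
        p = tmp_path / "out.fasta"
        write_alignment_fasta(aln, p)
        back = read_alignment(p, "s0")
        assert back.rows == aln.rows
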