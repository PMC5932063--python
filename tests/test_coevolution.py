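"""Conservation and coevolution scoring."""

import math

import numpy as np
import pytest

from allokit import coevolution as co
from allokit import structure as stx
from allokit._tables import AMINO_ACIDS


def aln(*seqs):
    return co.Alignment(list(seqs), [f"s{i}" for i in range(len(seqs))])


class TestColumnFrequencies:
    def test_pure_column(self):
        freqs, gaps = co.column_frequencies(aln("A", "A", "A", "A"), 0)
        assert freqs == {"A": 1.0} and gaps == 0.0

    def test_even_split(self):
        freqs, _ = co.column_frequencies(aln("A", "A", "G", "G"), 0)
        assert freqs == {"A": 0.5, "G": 0.5}

    def test_gaps_excluded_from_frequencies(self):
        freqs, gaps = co.column_frequencies(aln("A", "-", "A", "-"), 0)
        assert freqs == {"A": 1.0} and gaps == pytest.approx(0.5)

    def test_all_gap_column_raises(self):
        with pytest.raises(co.AllGapColumnError):
            co.column_frequencies(aln("-", "-"), 0)


class TestKLConservation:
    def test_column_matching_background_scores_zero(self):
        # two symbols at frequencies equal to a matching background
        bg = {aa: 0.05 for aa in AMINO_ACIDS}
        bg["A"] = bg["G"] = 0.5 - 0.45  # placeholder, replaced below
        bg = {aa: (0.5 if aa in "AG" else 0.0) for aa in AMINO_ACIDS}
        bg = {aa: v if v else 1e-300 for aa, v in bg.items()}
        prof = co.kl_conservation(aln("AG", "GA", "AG", "GA"), bg)
        assert prof.kl_score[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_column_value(self):
        bg = {aa: (0.08 if aa == "A" else 0.92 / 19) for aa in AMINO_ACIDS}
        prof = co.kl_conservation(aln("A", "A", "A"), bg)
        assert prof.kl_score[0] == pytest.approx(math.log(1 / 0.08),
                                                 rel=1e-12)

    def test_uniform_column_against_uniform_background_is_zero(self):
        bg = {aa: 1 / 20 for aa in AMINO_ACIDS}
        seqs = [a for a in AMINO_ACIDS]
        prof = co.kl_conservation(co.Alignment(seqs, list(AMINO_ACIDS)), bg)
        assert prof.kl_score[0] == pytest.approx(0.0, abs=1e-12)

    def test_scores_nonnegative_on_random_alignments(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=6))
                    for _ in range(10)]
            prof = co.kl_conservation(co.Alignment(seqs, list("0123456789")))
            assert (prof.kl_score >= -1e-12).all()

    def test_gappy_column_flagged_unreliable(self):
        prof = co.kl_conservation(aln("A-", "--", "-C", "--"))
        assert prof.unreliable[0] and prof.unreliable[1]


class TestMutualInformation:
    def test_conserved_columns_have_zero_mi(self):
        mi = co.mutual_information_matrix(aln("AC", "AC", "AC"), "raw",
                                          min_joint_observations=1)
        assert mi.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_covariation_is_ln2(self):
        seqs = ["AC", "GD"] * 5
        mi = co.mutual_information_matrix(co.Alignment(seqs, [str(i) for i
                                                              in range(10)]),
                                          "raw", min_joint_observations=1)
        assert mi.values[0, 1] == pytest.approx(math.log(2), rel=1e-12)

    def test_bounded_by_column_entropies(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACDE"), size=4))
                for _ in range(25)]
        a = co.Alignment(seqs, [str(i) for i in range(25)])
        mi = co.mutual_information_matrix(a, "raw", min_joint_observations=1)
        enc = a.encoded()
        for i in range(4):
            counts = np.bincount(enc[:, i], minlength=21)[:20]
            p = counts[counts > 0] / counts.sum()
            h_i = -(p * np.log(p)).sum()
            for j in range(4):
                if i == j:
                    continue
                assert mi.values[i, j] >= -1e-12
                assert mi.values[i, j] <= h_i + 1e-9

    def test_sparse_pairs_masked(self):
        seqs = ["AC", "A-", "A-", "A-", "A-"]
        mi = co.mutual_information_matrix(
            co.Alignment(seqs, list("01234")), "raw",
            min_joint_observations=3)
        assert np.isnan(mi.values[0, 1])

    def test_zscore_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=5))
                for _ in range(30)]
        a = co.Alignment(seqs, [str(i) for i in range(30)])
        m1 = co.mutual_information_matrix(a, "zscore", n_shuffles=10, seed=7)
        m2 = co.mutual_information_matrix(a, "zscore", n_shuffles=10, seed=7)
        np.testing.assert_array_equal(m1.values, m2.values)


class TestCumulativeMI:
    def test_all_below_threshold_gives_zero(self):
        mi = co.mutual_information_matrix(aln("AC", "AC", "AC"), "raw",
                                          min_joint_observations=1)
        assert (co.cumulative_mi(mi, 6.5) == 0).all()

    def test_sums_only_scores_above_threshold(self):
        vals = np.full((4, 4), np.nan)
        vals[0, 1] = vals[1, 0] = 7.0
        vals[0, 2] = vals[2, 0] = 8.0
        vals[0, 3] = vals[3, 0] = 3.0
        m = co.MIMatrix(values=vals, raw=vals, correction="zscore",
                        min_joint_observations=1)
        cmi = co.cumulative_mi(m, 6.5)
        assert cmi[0] == pytest.approx(15.0)
        assert cmi[3] == pytest.approx(0.0)

    def test_strictly_above_threshold(self):
        vals = np.full((2, 2), np.nan)
        vals[0, 1] = vals[1, 0] = 6.5
        m = co.MIMatrix(values=vals, raw=vals, correction="zscore",
                        min_joint_observations=1)
        assert (co.cumulative_mi(m, 6.5) == 0).all()


class TestProximityMI:
    def _contacts(self, pairs, n):
        c = np.zeros((n, n), dtype=bool)
        for i, j in pairs:
            c[i, j] = c[j, i] = True
        return stx.ContactMap(n_residues=n, contacts=c, cutoff=5.0,
                              metric="heavy-atom-min")

    def _identity_map(self, n):
        return co.ColumnStructureMap(
            column_to_residue={i: i for i in range(n)},
            residue_to_column={i: i for i in range(n)}, identity=1.0)

    def test_isolated_residue_keeps_own_cmi(self):
        pmi = co.proximity_mi(np.array([2.0, 4.0]), self._contacts([], 2),
                              self._identity_map(2))
        np.testing.assert_allclose(pmi, [2.0, 4.0])

    def test_contact_pair_shares_mean(self):
        pmi = co.proximity_mi(np.array([2.0, 4.0]),
                              self._contacts([(0, 1)], 2),
                              self._identity_map(2))
        np.testing.assert_allclose(pmi, [3.0, 3.0])

    def test_unmapped_residue_masked(self):
        cm = co.ColumnStructureMap(column_to_residue={0: 0},
                                   residue_to_column={0: 0}, identity=1.0)
        pmi = co.proximity_mi(np.array([2.0]), self._contacts([(0, 1)], 2),
                              cm)
        assert pmi[0] == pytest.approx(2.0)
        assert np.isnan(pmi[1])


class TestColumnStructureMap:
    def _model(self, seq):
        from allokit._tables import AMINO1_TO_3
        lines = []
        for i, ch in enumerate(seq, start=1):
            lines.append(
                f"ATOM  {i:>5d}  CA  {AMINO1_TO_3[ch]} A{i:>4d}    "
                f"{4.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00"
                f"           C")
        return stx.load_structure("\n".join(lines) + "\nEND\n")

    def test_identity_mapping(self):
        seq = "ACDEFGHIKL"
        a = co.Alignment([seq, seq], ["query", "other"])
        m = co.map_columns_to_residues(a, self._model(seq), "query")
        assert m.column_to_residue == {i: i for i in range(10)}
        assert m.identity == 1.0

    def test_missing_terminal_residues_masked(self):
        seq = "ACDEFGHIKL"
        a = co.Alignment([seq, seq], ["query", "other"])
        m = co.map_columns_to_residues(a, self._model(seq[:-2]), "query")
        cols = m.mapped_columns()
        assert 8 not in cols and 9 not in cols
        assert cols == list(range(8))

    def test_internal_insertion_masked_flanks_mapped(self):
        struct_seq = "ACDEFGHIKL"
        query = "ACDEFWGHIKL"  # one-residue insertion after F
        a = co.Alignment([query, query], ["query", "other"])
        m = co.map_columns_to_residues(a, self._model(struct_seq), "query",
                                       min_identity=0.8)
        assert 5 not in m.column_to_residue          # the inserted W
        assert m.column_to_residue[4] == 4           # F before
        assert m.column_to_residue[6] == 5           # G after
        # injectivity
        vals = list(m.column_to_residue.values())
        assert len(vals) == len(set(vals))

    def test_low_identity_rejected(self):
        a = co.Alignment(["ACDEFGHIKL", "ACDEFGHIKL"], ["query", "o"])
        with pytest.raises(co.MappingQualityError):
            co.map_columns_to_residues(a, self._model("YYYYYGHIKL"), "query")


def test_fasta_reader_roundtrip(tmp_path):
    text = ">a\nAC-D\n>b\nAG-D\n"
    a = co.Alignment.from_fasta(text)
    assert a.ids == ["a", "b"] and a.length == 4
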