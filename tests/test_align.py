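import math

import numpy as np
import pytest

from nnmine.align import (
    PairwiseAlignment,
    ScoringScheme,
    align_global,
    align_local,
    evalue,
    log_evalue,
    percent_identity,
)
from nnmine.records import AMINO_ACIDS, ProteinRecord

from _oracles import bruteforce_global_score, bruteforce_local_score


def _degap(s: str) -> str:
    return s.replace("-", "")


class TestGlobalAlignment:
    def test_identity_alignment(self, scheme):
        aln = align_global(ProteinRecord("a", "AAAA"), ProteinRecord("b", "AAAA"), scheme)
        assert aln.identity_pct == 100.0
        assert "-" not in aln.aligned_query + aln.aligned_subject

    def test_single_column_substitution(self, scheme):
        aln = align_global(ProteinRecord("a", "A"), ProteinRecord("b", "G"), scheme)
        assert aln.score == scheme.pair_score("A", "G") == 0
        assert aln.identity_pct == 0.0

    def test_degapped_rows_reproduce_inputs(self, scheme):
        a, b = ProteinRecord("a", "MKVLHG"), ProteinRecord("b", "MVLHWG")
        aln = align_global(a, b, scheme)
        assert _degap(aln.aligned_query) == a.sequence
        assert _degap(aln.aligned_subject) == b.sequence

    def test_rescoring_traceback_matches_reported_score(self, scheme):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 15)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 15)))
            aln = align_global(ProteinRecord("a", a), ProteinRecord("b", b), scheme)
            total, state = 0, None
            for x, y in zip(aln.aligned_query, aln.aligned_subject):
                if x == "-":
                    total -= scheme.gap_extend + (scheme.gap_open if state != "y" else 0)
                    state = "y"
                elif y == "-":
                    total -= scheme.gap_extend + (scheme.gap_open if state != "x" else 0)
                    state = "x"
                else:
                    total += scheme.pair_score(x, y)
                    state = "m"
            assert total == aln.score


class TestLocalAlignment:
    def test_exact_substring_found(self, scheme):
        aln = align_local(ProteinRecord("q", "MKVMKV"), ProteinRecord("t", "KV"), scheme)
        assert aln.aligned_query == "KV"
        assert aln.aligned_subject == "KV"
        assert aln.identity_pct == 100.0

    def test_all_negative_scores_give_empty_alignment(self, scheme):
        # BLOSUM62(P, G) = -2: no positive-scoring pair exists
        aln = align_local(ProteinRecord("q", "PPP"), ProteinRecord("t", "GGG"), scheme)
        assert aln.score == 0
        assert aln.aligned_query == "" and aln.aligned_subject == ""

    def test_local_rows_are_substrings(self, scheme):
        a, b = ProteinRecord("a", "WWMKVLHGWW"), ProteinRecord("b", "AAMKVLHGAA")
        aln = align_local(a, b, scheme)
        assert _degap(aln.aligned_query) in a.sequence
        assert _degap(aln.aligned_subject) in b.sequence


class TestOracleEquivalence:
    """Exact agreement with exhaustive enumeration over all gapped
    alignments (a smaller draw than the full battery run elsewhere)."""

    def test_global_and_local_match_bruteforce(self, scheme):
        rng = np.random.default_rng(20240124)
        aas = list("ACDE")
        for _ in range(60):
            a = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 7)))
            expect_g = bruteforce_global_score(
                a, b, scheme.pair_score, scheme.gap_open, scheme.gap_extend
            )
            expect_l = bruteforce_local_score(
                a, b, scheme.pair_score, scheme.gap_open, scheme.gap_extend
            )
            got_g = align_global(ProteinRecord("a", a), ProteinRecord("b", b), scheme)
            got_l = align_local(ProteinRecord("a", a), ProteinRecord("b", b), scheme)
            assert got_g.score == expect_g, (a, b)
            assert got_l.score == expect_l, (a, b)

    def test_agreement_with_biopython_aligner(self, scheme):
        """Independent cross-check against Bio.Align.PairwiseAligner on
        longer sequences than enumeration can reach."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        rng = np.random.default_rng(77)
        for mode in ("global", "local"):
            aligner.mode = mode
            for _ in range(10):
                a = "".join(rng.choice(list(AMINO_ACIDS), size=40))
                b = "".join(rng.choice(list(AMINO_ACIDS), size=35))
                ours = (align_global if mode == "global" else align_local)(
                    ProteinRecord("a", a), ProteinRecord("b", b), scheme
                )
                assert ours.score == int(aligner.score(a, b))

    def test_score_symmetry(self, scheme):
        rng = np.random.default_rng(3)
        for _ in range(15):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=12))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=9))
            ra, rb = ProteinRecord("a", a), ProteinRecord("b", b)
            assert align_global(ra, rb, scheme).score == align_global(rb, ra, scheme).score
            assert align_local(ra, rb, scheme).score == align_local(rb, ra, scheme).score


class TestEvalue:
    def test_zero_score_closed_form(self, scheme):
        assert math.isclose(
            evalue(0, 100, 200, scheme), scheme.karlin_K * 100 * 200, rel_tol=1e-12
        )

    def test_linear_in_lengths(self, scheme):
        base = evalue(50, 100, 100, scheme)
        assert math.isclose(evalue(50, 200, 100, scheme), 2 * base, rel_tol=1e-12)
        assert math.isclose(evalue(50, 100, 300, scheme), 3 * base, rel_tol=1e-12)

    def test_closed_form_at_reference_point(self, scheme):
        # K*m*n*exp(-lambda*S) at (S=300, m=n=500, lambda=0.267, K=0.041),
        # evaluated independently
        expected = 0.041 * 500 * 500 * math.exp(-0.267 * 300)
        assert math.isclose(evalue(300, 500, 500, scheme), expected, rel_tol=1e-12)
        assert math.isclose(evalue(300, 500, 500, scheme), 1.673924496459573e-31,
                            rel_tol=1e-11)

    def test_strictly_decreasing_in_score(self, scheme):
        values = [evalue(s, 300, 300, scheme) for s in range(0, 400, 25)]
        assert all(x > y > 0 for x, y in zip(values, values[1:]))

    def test_log_form_consistent_and_underflow_safe(self, scheme):
        assert math.isclose(
            math.exp(log_evalue(100, 50, 60, scheme)), evalue(100, 50, 60, scheme)
        )
        assert log_evalue(10000, 300, 300, scheme) < -2000  # no underflow
        assert evalue(10000, 300, 300, scheme) > 0  # strictly positive, floored

    def test_invalid_inputs_rejected(self, scheme):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, scheme)
        with pytest.raises(ValueError):
            evalue(-5, 100, 100, scheme)


class TestPercentIdentity:
    def _aln(self, qa, qb, mode):
        return PairwiseAlignment(
            query_id="q", subject_id="s", aligned_query=qa, aligned_subject=qb,
            score=0, mode=mode, identity_pct=0.0, evalue=1.0,
        )

    def test_identical_global_is_100(self):
        assert percent_identity(self._aln("ACDE", "ACDE", "global")) == 100.0

    def test_mismatch_fraction(self):
        assert percent_identity(self._aln("ACDE", "ACDG", "global")) == 75.0

    def test_gap_column_conventions_differ(self):
        # 5 columns, 1 gap column, 3 matches: global counts the gap column
        # in the denominator (3/5), local does not (3/4)
        qa, qb = "ACD-E", "ACDKG"
        assert percent_identity(self._aln(qa, qb, "global")) == 60.0
        assert percent_identity(self._aln(qa, qb, "local")) == 75.0

    def test_empty_alignment_is_an_error(self):
        with pytest.raises(ValueError):
            percent_identity(self._aln("", "", "global"))


class TestScoringScheme:
    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[1, 2], [3, 1]])
        with pytest.raises(ValueError, match="symmetric"):
            ScoringScheme(name="bad", alphabet="AB", matrix=mat)

    def test_illegal_character_raises_input_error(self, scheme):
        with pytest.raises(ValueError, match="not in the"):
            scheme.encode("AC!E")

    def test_ncbi_matrix_file_loading(self, scheme, tmp_path):
        p = tmp_path / "mini.mat"
        p.write_text("   A  C\nA  4  0\nC  0  9\n")
        mini = ScoringScheme.from_file(p)
        assert mini.pair_score("C", "C") == 9
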