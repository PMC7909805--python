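import numpy as np
import pytest

from mahds.align import (DIAG, PSKIP, SSKIP, DpConfig, align_to_pwm,
                         brute_force_align, reconstruct_msa, rescore_path)
from mahds.pwm import DinucPWM, channel_index
from mahds.sequences import EncodedSequence, concatenate
from mahds.simulate import toy_grammar_set
from mahds.pipeline import fuse, stack_pwm


def context_free_pwm(rng, m):
    """Matrix whose four previous-base channels agree for every
    (position, current-base), removing all path dependence."""
    base = rng.normal(0, 3, (m, 4))
    W = np.zeros((m, 16))
    for cur0 in range(4):
        W[:, 4 * cur0:4 * cur0 + 4] = base[:, [cur0]]
    return DinucPWM(W)


class TestDpBasics:
    def test_zero_matrix_zero_score_no_gaps(self, rng):
        pwm = DinucPWM(np.zeros((8, 16)))
        S = EncodedSequence(rng.integers(1, 5, 24).astype(np.int8))
        res = align_to_pwm(S, pwm, 3)
        assert res.score == 0.0
        assert res.n_gap_moves == 0

    def test_gap_free_closed_form(self, rng):
        # context-free matrix, single repeat, equal lengths: the score
        # is the boundary term plus the chain of dinucleotide terms
        m = 12
        pwm = context_free_pwm(rng, m)
        codes = rng.integers(1, 5, m).astype(np.int8)
        res = align_to_pwm(EncodedSequence(codes), pwm, 1)
        expected = pwm.W1[0, codes[0] - 1]
        for i in range(1, m):
            expected += pwm.W[i, channel_index(codes[i - 1], codes[i]) - 1]
        assert res.score >= expected - 1e-9
        if res.n_gap_moves == 0:
            assert res.score == pytest.approx(expected)

    def test_invalid_inputs(self, rng):
        pwm = DinucPWM(np.zeros((4, 16)))
        with pytest.raises(ValueError):
            align_to_pwm(EncodedSequence(np.array([1, 0, 2],
                                                  dtype=np.int8)), pwm, 1)
        with pytest.raises(ValueError):
            align_to_pwm(EncodedSequence(np.array([1, 2], dtype=np.int8)),
                         pwm, 0)

    def test_structured_beats_shuffles(self, rng):
        # the toy-grammar concatenation outscores 95% of its shuffles
        # under its own model matrix
        toy = toy_grammar_set()
        cs = concatenate(toy)
        codes, lengths, m, N = fuse(toy)
        pwm = stack_pwm(codes, lengths, m, 110.0 * m, -1.8)
        obs = align_to_pwm(cs.S, pwm, N).score
        null = []
        for _ in range(100):
            null.append(align_to_pwm(
                EncodedSequence(rng.permutation(cs.S.codes)), pwm, N).score)
        assert obs > np.quantile(null, 0.95)


class TestRescore:
    def test_self_consistency_random_instances(self, rng):
        for _ in range(30):
            m = int(rng.integers(2, 6))
            N = int(rng.integers(1, 4))
            ls = int(rng.integers(2, 12))
            pwm = DinucPWM(rng.normal(0, 3, (m, 16)))
            S = EncodedSequence(rng.integers(1, 5, ls).astype(np.int8))
            res = align_to_pwm(S, pwm, N)
            assert rescore_path(res.path, S, pwm) == pytest.approx(
                res.score, abs=1e-9)

    def test_all_diagonal_zero_matrix(self):
        pwm = DinucPWM(np.zeros((3, 16)))
        S = EncodedSequence.from_string("atc")
        path = np.array([DIAG, DIAG, DIAG], dtype=np.int8)
        assert rescore_path(path, S, pwm) == 0.0

    def test_hand_built_two_cell_path(self):
        # 1-position matrix vs 2-base sequence: diagonal then S-skip
        W = np.zeros((1, 16))
        W[0, :] = 1.0          # every channel 1.0 -> W1 also 1.0
        pwm = DinucPWM(W)
        S = EncodedSequence.from_string("at")
        path = np.array([DIAG, SSKIP], dtype=np.int8)
        # boundary term 1.0, then an interior S-skip costs del
        assert rescore_path(path, S, pwm) == pytest.approx(1.0 - 25.0)

    def test_malformed_path_rejected(self):
        pwm = DinucPWM(np.zeros((2, 16)))
        S = EncodedSequence.from_string("at")
        with pytest.raises(ValueError):
            rescore_path(np.array([DIAG], dtype=np.int8), S, pwm)


class TestBruteForceOracle:
    def test_context_free_equivalence(self, rng):
        hits = 0
        while hits < 100:
            m = int(rng.integers(2, 4))
            N = int(rng.integers(1, 3))
            ls = int(rng.integers(2, 8))
            if (m * N + 1) * (ls + 1) > 120:
                continue
            pwm = context_free_pwm(rng, m)
            S = EncodedSequence(rng.integers(1, 5, ls).astype(np.int8))
            res = align_to_pwm(S, pwm, N)
            bf = brute_force_align(S, pwm, N)
            assert res.score == pytest.approx(bf, abs=1e-9)
            hits += 1

    def test_dp_bounded_by_brute_force_in_general(self, rng):
        for _ in range(40):
            m = int(rng.integers(2, 4))
            N = int(rng.integers(1, 3))
            ls = int(rng.integers(2, 8))
            if (m * N + 1) * (ls + 1) > 120:
                continue
            pwm = DinucPWM(rng.normal(0, 3, (m, 16)))
            S = EncodedSequence(rng.integers(1, 5, ls).astype(np.int8))
            res = align_to_pwm(S, pwm, N)
            assert res.score <= brute_force_align(S, pwm, N) + 1e-9

    def test_zero_matrix(self):
        pwm = DinucPWM(np.zeros((2, 16)))
        S = EncodedSequence.from_string("atcg")
        assert brute_force_align(S, pwm, 2) == 0.0

    def test_too_large_rejected(self, rng):
        pwm = DinucPWM(np.zeros((30, 16)))
        S = EncodedSequence(rng.integers(1, 5, 30).astype(np.int8))
        with pytest.raises(ValueError, match="too large"):
            brute_force_align(S, pwm, 1)


class TestGapMonotonicity:
    def test_higher_del_never_more_gaps(self, rng):
        for _ in range(15):
            m = int(rng.integers(3, 6))
            N = int(rng.integers(1, 3))
            ls = m * N + int(rng.integers(-2, 3))
            if ls < 2:
                continue
            pwm = DinucPWM(rng.normal(0, 6, (m, 16)))
            S = EncodedSequence(rng.integers(1, 5, ls).astype(np.int8))
            gaps = [align_to_pwm(S, pwm, N,
                                 DpConfig(del_penalty=d)).n_gap_moves
                    for d in (2.0, 8.0, 25.0)]
            assert gaps[0] >= gaps[1] >= gaps[2]


class TestReconstruction:
    def test_gap_free_alignment(self, rng):
        # equal-length inputs, zero matrix: m columns, no gap characters
        seqs = [EncodedSequence(rng.integers(1, 5, 9).astype(np.int8),
                                f"s{i}") for i in range(4)]
        codes, lengths, m, N = fuse(seqs)
        res = align_to_pwm(EncodedSequence(codes), DinucPWM(
            np.zeros((m, 16))), N)
        rows = reconstruct_msa(res, seqs)
        assert all(len(r) == m for r in rows)
        assert all(not r.is_gapped for r in rows)
        assert [str(r) for r in rows] == [str(s) for s in seqs]

    def test_toy_set_aligns_gap_free_to_own_model(self):
        toy = toy_grammar_set()
        codes, lengths, m, N = fuse(toy)
        pwm = stack_pwm(codes, lengths, m, 110.0 * m, -1.8)
        res = align_to_pwm(EncodedSequence(codes), pwm, N)
        rows = reconstruct_msa(res, toy)
        assert res.n_gap_moves == 0
        assert all(len(r) == 4 for r in rows)

    def test_single_insertion_makes_one_extra_column(self, rng):
        # one sequence carries one extra base; with a model built from
        # the clean stack the path must route it through a sequence-skip
        base = rng.integers(1, 5, 30).astype(np.int8)
        seqs = [EncodedSequence(base.copy(), f"s{i}") for i in range(6)]
        ins = np.insert(base, 13, 2).astype(np.int8)
        seqs[2] = EncodedSequence(ins, "s2")
        clean = [EncodedSequence(base.copy(), f"c{i}") for i in range(6)]
        ccodes, clengths, m, _ = fuse(clean)
        pwm = stack_pwm(ccodes, clengths, m, 110.0 * m, -1.8)
        codes, lengths, _, N = fuse(seqs, m)
        res = align_to_pwm(EncodedSequence(codes), pwm, N)
        rows = reconstruct_msa(res, seqs)
        assert len(rows[0]) == m + 1
        gap_rows = [r for i, r in enumerate(rows) if i != 2]
        assert all(sum(c == 0 for c in r.codes) == 1 for r in gap_rows)
        assert sum(c == 0 for c in rows[2].codes) == 0
        # round-trip is exact for every row
        assert [str(r.ungapped()) for r in rows] == [str(s) for s in seqs]

    def test_roundtrip_on_arbitrary_alignments(self, rng):
        # even for random matrices and ragged inputs, ungapping every
        # reconstructed row returns the corresponding input
        for _ in range(10):
            seqs = [EncodedSequence(
                rng.integers(1, 5, int(rng.integers(8, 14))).astype(np.int8),
                f"s{i}") for i in range(3)]
            codes, lengths, m, N = fuse(seqs)
            pwm = DinucPWM(rng.normal(0, 4, (m, 16)))
            res = align_to_pwm(EncodedSequence(codes), pwm, N)
            rows = reconstruct_msa(res, seqs)
            assert len({len(r) for r in rows}) == 1
            assert [str(r.ungapped()) for r in rows] == \
                [str(s) for s in seqs]
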