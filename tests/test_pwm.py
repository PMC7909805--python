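import numpy as np
import pytest

from mahds.pwm import (DinucPWM, FreqMatrix, build_frequency_matrix,
                       channel_index, channel_labels, collapse_pwm,
                       compute_Kd, compute_R2, dinucleotide_probs,
                       frequency_to_pwm, generate_random_pwm_set,
                       load_pwm_tsv, save_pwm_tsv, transform_pwm)
from mahds.sequences import EncodedSequence, concatenate
from mahds.simulate import example_random_matrix, example_transformed_matrix


class TestFrequencyMatrix:
    def test_toy_counts(self, toy_set):
        cs = concatenate(toy_set)
        M = build_frequency_matrix(cs.S1, cs.S).M
        # "at" at profile position 2 occurs in atcg, atat, atta
        assert M[1, channel_index(1, 2) - 1] == 3
        # ta, gc, cg at position 2 likewise three times each
        assert M[1, channel_index(2, 1) - 1] == 3
        assert M[1, channel_index(4, 3) - 1] == 3
        assert M[1, channel_index(3, 4) - 1] == 3

    def test_total_is_L_minus_1(self, toy_set):
        cs = concatenate(toy_set)
        assert build_frequency_matrix(cs.S1, cs.S).total == cs.L - 1

    def test_single_pair(self):
        M = build_frequency_matrix(np.array([1, 2]),
                                   EncodedSequence.from_string("aa")).M
        assert M[1, 0] == 1 and M.sum() == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_frequency_matrix(np.array([1, 2, 3]),
                                   EncodedSequence.from_string("aa"))


class TestFrequencyToPwm:
    def test_uniform_counts_give_zero(self):
        W = frequency_to_pwm(FreqMatrix(np.full((3, 16), 5))).W
        assert np.allclose(W, 0.0)

    def test_single_cell_closed_form(self):
        # all mass in one cell: marginals make p=1 there and p=0
        # elsewhere, both degenerate, so the whole matrix is zero
        M = np.zeros((2, 16), dtype=int)
        M[0, 3] = 7
        assert np.allclose(frequency_to_pwm(FreqMatrix(M)).W, 0.0)

    def test_two_cell_closed_form(self):
        # two occupied cells in different rows and channels
        M = np.zeros((2, 16), dtype=int)
        M[0, 0] = 3
        M[1, 5] = 1
        L = 4
        p00 = (3 / L) * (3 / L)
        expect00 = (3 - L * p00) / np.sqrt(L * p00 * (1 - p00))
        W = frequency_to_pwm(FreqMatrix(M)).W
        assert W[0, 0] == pytest.approx(expect00)

    def test_toy_signs(self, toy_set):
        cs = concatenate(toy_set)
        W = frequency_to_pwm(build_frequency_matrix(cs.S1, cs.S)).W
        assert W[1, channel_index(1, 2) - 1] > 0     # "at" enriched
        assert W[1, channel_index(1, 1) - 1] < 0     # "aa" depleted

    def test_shuffled_matrix_mean_near_zero(self, rng):
        codes = rng.integers(1, 5, 4000).astype(np.int8)
        track = np.arange(4000) % 40 + 1
        W = frequency_to_pwm(
            build_frequency_matrix(track, EncodedSequence(codes))).W
        assert abs(W.mean()) < 0.2


class TestStatistics:
    def test_zero_matrix(self):
        Z = np.zeros((4, 16))
        assert compute_R2(Z) == 0.0
        assert compute_Kd(Z, np.full(4, 0.25), np.full(16, 1 / 16)) == 0.0

    def test_collapse_constant(self):
        W = np.full((3, 16), 2.5)
        assert np.allclose(collapse_pwm(W), 2.5)

    def test_collapse_single_channel(self):
        W = np.zeros((2, 16))
        # channels with current base 'a' are 1..4 (0-based 0..3)
        W[0, 1] = 4.0
        W1 = collapse_pwm(W)
        assert W1[0, 0] == pytest.approx(1.0)
        assert np.allclose(W1[0, 1:], 0.0) and np.allclose(W1[1], 0.0)

    def test_collapse_bundled_matrix(self):
        # position 1, current base a: mean of bundled aa, ta, ca, ga
        W1 = collapse_pwm(example_transformed_matrix().W)
        assert W1[0, 0] == pytest.approx(0.25 * (-5.4 - 3.2 - 4.1 - 4.4))


class TestTransform:
    def test_hits_targets(self):
        WT = transform_pwm(example_random_matrix(), 2000.0, -1.5)
        assert compute_R2(WT.W) == pytest.approx(2000.0, rel=1e-6)
        assert compute_Kd(WT.W, WT.p1, WT.p2) == pytest.approx(-1.5,
                                                               abs=1e-6)

    def test_matches_bundled_transform(self):
        WT = transform_pwm(example_random_matrix(), 2000.0, -1.5)
        bundled = example_transformed_matrix()
        assert np.max(np.abs(WT.W - bundled.W)) < 0.3

    def test_fixed_point(self):
        WT = transform_pwm(example_random_matrix(), 2000.0, -1.5)
        again = transform_pwm(WT, 2000.0, -1.5)
        assert np.allclose(again.W, WT.W, atol=1e-9)

    def test_nonuniform_weights(self, rng):
        p2 = dinucleotide_probs(rng.integers(1, 5, 997).astype(np.int8))
        pwm = DinucPWM(rng.normal(0, 2, (6, 16)), p2=p2)
        WT = transform_pwm(pwm, 110.0 * 6, -1.8)
        assert compute_R2(WT.W) == pytest.approx(660.0, rel=1e-9)
        assert compute_Kd(WT.W, WT.p1, WT.p2) == pytest.approx(-1.8,
                                                               abs=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            transform_pwm(DinucPWM(np.full((2, 16), 1.0)), 100.0, -1.8)

    def test_infeasible_target(self):
        # R0 below the value forced by K0 alone is unreachable
        pwm = DinucPWM(np.arange(32, dtype=float).reshape(2, 16))
        with pytest.raises(ValueError):
            transform_pwm(pwm, 1e-6, -1.8)


class TestRandomSet:
    def test_properties(self, rng):
        codes = rng.integers(1, 5, 600).astype(np.int8)
        S = EncodedSequence(codes)
        Q = generate_random_pwm_set(S, 30, n_candidates=60, max_set=20,
                                    R0=110.0 * 30, K0=-1.8, seed=3)
        assert 2 <= Q.n1 <= 20
        flat = np.stack([q.W.reshape(-1) for q in Q.matrices])
        for i in range(Q.n1):
            for j in range(i + 1, Q.n1):
                assert np.linalg.norm(flat[i] - flat[j]) >= Q.D0 - 1e-9
        for q in Q.matrices:
            assert compute_R2(q.W) == pytest.approx(3300.0, rel=1e-9)
            assert compute_Kd(q.W, q.p1, q.p2) == pytest.approx(-1.8,
                                                                abs=1e-9)

    def test_needs_two_candidates(self, rng):
        S = EncodedSequence(rng.integers(1, 5, 100).astype(np.int8))
        with pytest.raises(ValueError):
            generate_random_pwm_set(S, 10, n_candidates=1, max_set=5,
                                    R0=1100.0, K0=-1.8)

    def test_distance_metric_spot_checks(self, rng):
        a, b, c = (rng.normal(size=(3, 16)) for _ in range(3))
        d = lambda x, y: np.linalg.norm(x - y)
        assert d(a, b) == pytest.approx(d(b, a))
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


class TestSerialization:
    def test_tsv_roundtrip(self, tmp_path, rng):
        pwm = DinucPWM(rng.normal(0, 3, (7, 16)))
        path = tmp_path / "w.tsv"
        save_pwm_tsv(pwm, path)
        back = load_pwm_tsv(path)
        assert np.allclose(back.W, pwm.W, atol=1e-9)

    def test_header_checked(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("no header\n")
        with pytest.raises(ValueError, match="header"):
            load_pwm_tsv(path)

    def test_channel_label_order(self):
        labels = channel_labels()
        assert labels[0] == "aa" and labels[1] == "ta"
        assert labels[channel_index(1, 2) - 1] == "at"
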