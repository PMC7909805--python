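"""Dinucleotide position-weight matrices.

A profile of length m is scored with an (m x 16) matrix whose 16
channels encode the (previous base, current base) dinucleotide; channel
index = prev + 4*(cur - 1) with a=1, t=2, c=3, g=4.  Matrices are built
as binomial z-scores of observed dinucleotide counts against the product
of the count-table marginals, then affinely rescaled to prescribed
targets R^2 (sum of squared elements) and K_d (probability-weighted mean
element) so that score distributions are comparable across matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import EncodedSequence

__all__ = [
    "FreqMatrix",
    "DinucPWM",
    "PwmSet",
    "channel_index",
    "channel_labels",
    "build_frequency_matrix",
    "frequency_to_pwm",
    "compute_R2",
    "compute_Kd",
    "transform_pwm",
    "collapse_pwm",
    "dinucleotide_probs",
    "generate_random_pwm_set",
    "save_pwm_tsv",
    "load_pwm_tsv",
]

_BASES = "atcg"


def channel_index(prev: int, cur: int) -> int:
    """1-based channel of the (prev, cur) dinucleotide: prev + 4*(cur-1)."""
    return prev + 4 * (cur - 1)


def channel_labels() -> list[str]:
    """Channel labels in storage order (aa, ta, ca, ga, at, tt, ...)."""
    return [_BASES[p] + _BASES[c] for c in range(4) for p in range(4)]


@dataclass
class FreqMatrix:
    """Observed dinucleotide counts, (m x 16) non-negative integers."""

    M: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        if self.M.ndim != 2 or self.M.shape[1] != 16:
            raise ValueError("frequency matrix must be (m x 16)")

    @property
    def m(self) -> int:
        return self.M.shape[0]

    @property
    def total(self) -> int:
        return int(self.M.sum())


@dataclass
class DinucPWM:
    """An (m x 16) real score matrix with its collapsed 4-channel form.

    p1 is the profile-row probability (uniform 1/m); p2 holds the 16
    dinucleotide probabilities p(prev)*p(cur) used by the K_d statistic,
    uniform 1/16 unless measured from a sequence.
    """

    W: np.ndarray
    p1: np.ndarray | None = None
    p2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[1] != 16:
            raise ValueError("PWM must be (m x 16)")
        m = self.W.shape[0]
        if self.p1 is None:
            self.p1 = np.full(m, 1.0 / m)
        if self.p2 is None:
            self.p2 = np.full(16, 1.0 / 16.0)
        self.p1 = np.asarray(self.p1, dtype=np.float64)
        self.p2 = np.asarray(self.p2, dtype=np.float64)

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def W1(self) -> np.ndarray:
        """Collapsed (m x 4) matrix, the boundary matrix E."""
        return collapse_pwm(self.W)

    @property
    def R2(self) -> float:
        return compute_R2(self.W)

    @property
    def Kd(self) -> float:
        return compute_Kd(self.W, self.p1, self.p2)


@dataclass
class PwmSet:
    """A population Q of candidate matrices kept pairwise at least D0
    apart in Euclidean distance."""

    matrices: list[DinucPWM]
    D0: float = 0.0

    @property
    def n1(self) -> int:
        return len(self.matrices)


def build_frequency_matrix(track: np.ndarray, seq) -> FreqMatrix:
    """Count dinucleotides (s(i-1), s(i)) into row track(i), i = 2..L.

    `track` holds 1-based profile positions; pairs spanning tile joins
    are included exactly as the scan range states.
    """
    codes = seq.codes if isinstance(seq, EncodedSequence) else np.asarray(seq)
    track = np.asarray(track, dtype=np.int64)
    if track.shape != codes.shape:
        raise ValueError("track and sequence lengths differ")
    if np.any(codes < 1) or np.any(codes > 4):
        raise ValueError("sequence must be ungapped codes 1..4")
    m = int(track.max())
    prev = codes[:-1].astype(np.int64)
    cur = codes[1:].astype(np.int64)
    rows = track[1:] - 1
    chans = (prev - 1) + 4 * (cur - 1)
    flat = np.bincount(rows * 16 + chans, minlength=m * 16)
    return FreqMatrix(flat.reshape(m, 16))


def frequency_to_pwm(freq: FreqMatrix, p2: np.ndarray | None = None
                     ) -> DinucPWM:
    """Binomial z-score transform of a count matrix.

    Expected cell probability is the product of the row marginal (over
    all 16 channels) and the channel marginal (over all m rows) of the
    count table; cells whose expected probability is degenerate (0 or 1)
    get score 0.
    """
    M = freq.M
    total = M.sum()
    if total == 0:
        raise ValueError("frequency matrix has no counts")
    x = M.sum(axis=1, dtype=np.float64)
    y = M.sum(axis=0, dtype=np.float64)
    p = np.outer(x, y) / float(total) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (M - total * p) / np.sqrt(total * p * (1.0 - p))
    W[(p <= 0.0) | (p >= 1.0)] = 0.0
    return DinucPWM(W, p2=p2)


def compute_R2(W: np.ndarray) -> float:
    """Sum of squared matrix elements."""
    return float(np.sum(np.asarray(W) ** 2))


def compute_Kd(W: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Probability-weighted mean element, sum_ik w(i,k) p1(i) p2(k)."""
    return float(np.asarray(p1) @ np.asarray(W) @ np.asarray(p2))


def dinucleotide_probs(seq) -> np.ndarray:
    """16-vector of p(prev)*p(cur) from the base composition of `seq`
    (gap codes ignored), in channel storage order."""
    codes = seq.codes if isinstance(seq, EncodedSequence) else np.asarray(seq)
    codes = codes[codes > 0]
    counts = np.bincount(codes, minlength=5)[1:5].astype(np.float64)
    p = counts / counts.sum()
    # p2[ch-1] with ch = prev + 4*(cur-1)
    return np.outer(p, p).T.reshape(-1)


def transform_pwm(pwm: DinucPWM, R0: float, K0: float) -> DinucPWM:
    """Affine rescale WT = a*W + b (a > 0) to hit R^2 = R0, K_d = K0.

    Two free parameters match the two constraints: K_d is affine in
    (a, b) because the p1 x p2 weights sum to one, and R^2 becomes a
    quadratic in `a` after substituting b.  Raises if no positive real
    root exists (R0 too small for the constraint pair).
    """
    W, p1, p2 = pwm.W, pwm.p1, pwm.p2
    C = W.size
    r2 = compute_R2(W)
    kd = compute_Kd(W, p1, p2)
    sw = float(W.sum())
    A = r2 - 2.0 * kd * sw + kd * kd * C      # = sum (w - kd)^2
    if A <= 1e-300:
        raise ValueError("matrix is constant; targets unreachable")
    B = 2.0 * K0 * (sw - kd * C)
    D = K0 * K0 * C - R0
    disc = B * B - 4.0 * A * D
    if disc < 0:
        raise ValueError(f"no real transform for targets R0={R0}, K0={K0}")
    roots = ((-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A))
    pos = [a for a in roots if a > 0]
    if not pos:
        raise ValueError(f"no positive-scale transform for R0={R0}, K0={K0}")
    a = max(pos)
    b = K0 - a * kd
    return DinucPWM(a * W + b, p1=p1.copy(), p2=p2.copy())


def collapse_pwm(W: np.ndarray) -> np.ndarray:
    """Average over the previous-base channels: (m x 16) -> (m x 4).

    W1(i, b) = 0.25 * sum_prev W(i, prev + 4*(b-1)); this is the
    context-free boundary matrix E used where no valid previous base is
    available on the alignment path.
    """
    W = np.asarray(W)
    return 0.25 * W.reshape(W.shape[0], 4, 4).sum(axis=2)


def _greedy_filter(flat: np.ndarray, dist: np.ndarray, D0: float
                   ) -> list[int]:
    kept: list[int] = []
    for i in range(flat.shape[0]):
        if all(dist[i, j] >= D0 for j in kept):
            kept.append(i)
    return kept


def generate_random_pwm_set(S, m: int, n_candidates: int, max_set: int,
                            R0: float, K0: float, seed=None) -> PwmSet:
    """Build the random-matrix population Q.

    Each candidate is the transformed PWM of one composition-preserving
    shuffle of S scored against the periodic profile track; candidates
    are then thinned so retained matrices are pairwise at least D0 apart
    in Euclidean distance, with D0 found by bisection so that at most
    `max_set` matrices remain.
    """
    if n_candidates < 2:
        raise ValueError("need at least 2 candidate matrices")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    codes = S.codes if isinstance(S, EncodedSequence) else np.asarray(S)
    L = codes.shape[0]
    track = np.arange(L, dtype=np.int64) % m + 1
    p2 = dinucleotide_probs(codes)
    cands = []
    for _ in range(n_candidates):
        shuf = rng.permutation(codes)
        W = frequency_to_pwm(build_frequency_matrix(track, shuf), p2=p2)
        cands.append(transform_pwm(W, R0, K0))
    flat = np.stack([c.W.reshape(-1) for c in cands])
    sq = np.sum(flat ** 2, axis=1)
    dist = np.sqrt(np.maximum(sq[:, None] + sq[None, :]
                              - 2.0 * flat @ flat.T, 0.0))
    if n_candidates <= max_set:
        kept = list(range(n_candidates))
        D0 = float(dist[np.triu_indices(n_candidates, 1)].min()) \
            if n_candidates > 1 else 0.0
    else:
        lo, hi = 0.0, float(dist.max())
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if len(_greedy_filter(flat, dist, mid)) <= max_set:
                hi = mid
            else:
                lo = mid
        D0 = hi
        kept = _greedy_filter(flat, dist, D0)
    return PwmSet([cands[i] for i in kept], D0=D0)


def save_pwm_tsv(pwm: DinucPWM, path) -> None:
    """Serialize as TSV with a 2-line header (shape, channel order)."""
    with open(path, "w") as fh:
        fh.write(f"# m={pwm.m}\tchannels=16\n")
        fh.write("# " + "\t".join(channel_labels()) + "\n")
        for row in pwm.W:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def load_pwm_tsv(path) -> DinucPWM:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# m="):
            raise ValueError("missing PWM header line")
        m = int(header.split("m=")[1].split("\t")[0])
        chans = fh.readline().lstrip("# ").split()
        if chans != channel_labels():
            raise ValueError("unexpected channel order in PWM file")
        W = np.loadtxt(fh)
    W = np.atleast_2d(W)
    if W.shape != (m, 16):
        raise ValueError(f"PWM body shape {W.shape} does not match header")
    return DinucPWM(W)
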