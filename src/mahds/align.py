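"""Global alignment of a concatenated sequence against a tiled
dinucleotide PWM.

The DP grid has the profile axis (the m matrix columns repeated N
times) on one side and the sequence S on the other.  A diagonal move
consumes one profile position and one base and scores
W(profile_col, channel(prev_base, cur_base)) where `prev_base` is the
most recent base consumed by a diagonal move on the best path into the
predecessor cell; after a run of profile skips — or when no base has
been matched yet — the dinucleotide context is dropped and the collapsed
matrix W1 (the boundary matrix E) scores the base alone.  Both skip
moves cost a flat `del` penalty.  The per-cell single-context memo makes
this a faithful heuristic rather than an exact three-dimensional DP: on
matrices with genuine context dependence the DP score is a lower bound
on the best path score (see `brute_force_align`).

Moves are encoded 0 = diagonal, 1 = sequence-skip (base consumed with no
profile advance; an extra MSA column), 2 = profile-skip (gap character
in the corresponding MSA row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .pwm import DinucPWM
from .sequences import GAP, EncodedSequence

__all__ = [
    "DpConfig",
    "AlignmentResult",
    "align_to_pwm",
    "rescore_path",
    "brute_force_align",
    "reconstruct_msa",
    "DIAG",
    "SSKIP",
    "PSKIP",
]

DIAG, SSKIP, PSKIP = 0, 1, 2


@dataclass
class DpConfig:
    """Dynamic-programming knobs.

    del_penalty is the flat per-event indel cost; use_context=False
    scores every diagonal with the collapsed matrix W1, giving the
    context-free profile baseline.
    """

    del_penalty: float = 25.0
    use_context: bool = True

    def __post_init__(self) -> None:
        if self.del_penalty <= 0:
            raise ValueError("del penalty must be positive")


@dataclass
class AlignmentResult:
    score: float
    path: np.ndarray              # move codes from (0,0) to (P, Ls)
    P: int                        # profile axis length N*m
    m: int
    n_repeats: int
    seq_length: int

    @property
    def n_gap_moves(self) -> int:
        return int(np.count_nonzero(self.path != DIAG))


@njit(cache=True, nogil=True)
def _dp_score(s0, P, m, W, W1, del_, use_context):  # pragma: no cover
    Ls = s0.shape[0]
    Fprev = np.zeros(Ls + 1, np.float64)
    Fcur = np.zeros(Ls + 1, np.float64)
    cprev = np.zeros(Ls + 1, np.int64)
    ccur = np.zeros(Ls + 1, np.int64)
    for i in range(1, P + 1):
        row = (i - 1) % m
        Fcur[0] = 0.0
        ccur[0] = 0
        for j in range(1, Ls + 1):
            cur = s0[j - 1]
            c = cprev[j - 1]
            if use_context and c > 0:
                sc = W[row, s0[c - 1] + 4 * cur]
            else:
                sc = W1[row, cur]
            d = Fprev[j - 1] + sc
            lft = Fcur[j - 1] - del_
            up = Fprev[j] - del_
            if d >= lft and d >= up:
                Fcur[j] = d
                ccur[j] = j
            elif lft >= up:
                Fcur[j] = lft
                ccur[j] = ccur[j - 1]
            else:
                Fcur[j] = up
                ccur[j] = 0
        Fprev, Fcur = Fcur, Fprev
        cprev, ccur = ccur, cprev
    return Fprev[Ls]


@njit(cache=True, nogil=True)
def _dp_full(s0, P, m, W, W1, del_, use_context):  # pragma: no cover
    Ls = s0.shape[0]
    F = np.zeros((P + 1, Ls + 1), np.float64)
    ctx = np.zeros((P + 1, Ls + 1), np.int64)
    ptr = np.zeros((P + 1, Ls + 1), np.int8)
    for i in range(1, P + 1):
        row = (i - 1) % m
        for j in range(1, Ls + 1):
            cur = s0[j - 1]
            c = ctx[i - 1, j - 1]
            if use_context and c > 0:
                sc = W[row, s0[c - 1] + 4 * cur]
            else:
                sc = W1[row, cur]
            d = F[i - 1, j - 1] + sc
            lft = F[i, j - 1] - del_
            up = F[i - 1, j] - del_
            if d >= lft and d >= up:
                F[i, j] = d
                ctx[i, j] = j
                ptr[i, j] = 0
            elif lft >= up:
                F[i, j] = lft
                ctx[i, j] = ctx[i, j - 1]
                ptr[i, j] = 1
            else:
                F[i, j] = up
                ctx[i, j] = 0
                ptr[i, j] = 2
    return F[P, Ls], ptr


def _as_codes0(S) -> np.ndarray:
    codes = S.codes if isinstance(S, EncodedSequence) else np.asarray(S)
    if np.any(codes < 1) or np.any(codes > 4):
        raise ValueError("sequence must be ungapped codes 1..4")
    return (codes - 1).astype(np.int64)


def pwm_score(S, pwm: DinucPWM, n_repeats: int,
              cfg: DpConfig | None = None) -> float:
    """Terminal DP score only (cheap rolling-array kernel)."""
    cfg = cfg or DpConfig()
    s0 = _as_codes0(S)
    return float(_dp_score(s0, n_repeats * pwm.m, pwm.m, pwm.W, pwm.W1,
                           cfg.del_penalty, cfg.use_context))


def align_to_pwm(S, pwm: DinucPWM, n_repeats: int,
                 cfg: DpConfig | None = None) -> AlignmentResult:
    """Full DP with traceback."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    cfg = cfg or DpConfig()
    s0 = _as_codes0(S)
    P = n_repeats * pwm.m
    score, ptr = _dp_full(s0, P, pwm.m, pwm.W, pwm.W1,
                          cfg.del_penalty, cfg.use_context)
    moves = []
    i, j = P, s0.shape[0]
    while i > 0 or j > 0:
        if i == 0:
            mv = SSKIP
        elif j == 0:
            mv = PSKIP
        else:
            mv = int(ptr[i, j])
        moves.append(mv)
        if mv == DIAG:
            i -= 1
            j -= 1
        elif mv == SSKIP:
            j -= 1
        else:
            i -= 1
    path = np.array(moves[::-1], dtype=np.int8)
    return AlignmentResult(score=float(score), path=path, P=P, m=pwm.m,
                           n_repeats=n_repeats, seq_length=s0.shape[0])


def rescore_path(path, S, pwm: DinucPWM, cfg: DpConfig | None = None,
                 m: int | None = None) -> float:
    """Score a fixed path with the exact context rules of the DP.

    Self-consistency oracle: rescoring the DP's own traceback must
    reproduce its score.
    """
    cfg = cfg or DpConfig()
    s0 = _as_codes0(S)
    m = m or pwm.m
    W, W1 = pwm.W, pwm.W1
    i = j = 0
    ctx = 0
    total = 0.0
    for mv in np.asarray(path):
        if mv == DIAG:
            i += 1
            j += 1
            if j > s0.shape[0]:
                raise ValueError("path overruns the sequence")
            cur = s0[j - 1]
            if cfg.use_context and ctx > 0:
                total += W[(i - 1) % m, s0[ctx - 1] + 4 * cur]
            else:
                total += W1[(i - 1) % m, cur]
            ctx = j
        elif mv == SSKIP:
            # boundary row/column cells are all zero, so leading skips
            # (taken while still on the grid edge) are free
            if i > 0:
                total -= cfg.del_penalty
            j += 1
        elif mv == PSKIP:
            if j > 0:
                total -= cfg.del_penalty
            i += 1
            ctx = 0
        else:
            raise ValueError(f"unknown move code {mv}")
    if j != s0.shape[0]:
        raise ValueError("path does not consume the whole sequence")
    return total


def brute_force_align(S, pwm: DinucPWM, n_repeats: int,
                      cfg: DpConfig | None = None,
                      max_paths: int = 2_000_000) -> float:
    """Enumerate every monotone path and return the best exact score.

    Exponential; intended as an oracle on tiny instances.  On matrices
    without genuine context dependence it must agree with the DP; in
    general the DP score is a lower bound.
    """
    cfg = cfg or DpConfig()
    s0 = _as_codes0(S)
    P = n_repeats * pwm.m
    Ls = s0.shape[0]
    if (P + 1) * (Ls + 1) > 120:
        raise ValueError("instance too large for exhaustive enumeration")
    W, W1, m, dl = pwm.W, pwm.W1, pwm.m, cfg.del_penalty
    best = -np.inf
    count = 0

    def rec(i, j, ctx, acc):
        nonlocal best, count
        if i == P and j == Ls:
            count += 1
            if count > max_paths:
                raise ValueError("too many paths")
            if acc > best:
                best = acc
            return
        if i < P and j < Ls:
            cur = s0[j]
            if cfg.use_context and ctx > 0:
                sc = W[i % m, s0[ctx - 1] + 4 * cur]
            else:
                sc = W1[i % m, cur]
            rec(i + 1, j + 1, j + 1, acc + sc)
        if j < Ls:
            rec(i, j + 1, ctx, acc - (dl if i > 0 else 0.0))
        if i < P:
            rec(i + 1, j, 0, acc - (dl if j > 0 else 0.0))

    rec(0, 0, 0, 0.0)
    return float(best)


def reconstruct_msa(result: AlignmentResult, seqs: list[EncodedSequence]
                    ) -> list[EncodedSequence]:
    """Cut the two-dimensional path into one gapped row per input.

    Each profile position is an MSA column; sequence-skip moves open
    extra columns.  Rows are assembled from each input's own bases (a
    base matched out of register — e.g. across a tile boundary — is
    demoted to an insertion), so removing gaps from row r always returns
    input r exactly.
    """
    m, P = result.m, result.P
    lengths = [len(s) for s in seqs]
    if sum(lengths) != result.seq_length:
        raise ValueError("sequences do not match the aligned concatenation")
    starts = np.cumsum([0] + lengths)

    # per consumed base: profile column (1..m) or 0 for an insertion
    base_col = np.zeros(result.seq_length, dtype=np.int64)
    i = j = 0
    for mv in result.path:
        if mv == DIAG:
            i += 1
            j += 1
            base_col[j - 1] = (i - 1) % m + 1
        elif mv == SSKIP:
            j += 1
            base_col[j - 1] = 0
        else:
            i += 1

    rows_matched = []   # per row: dict col -> code
    rows_inserts = []   # per row: dict anchor_col -> list of codes
    for r, seq in enumerate(seqs):
        matched: dict[int, int] = {}
        inserts: dict[int, list[int]] = {}
        lc = 0
        for k in range(starts[r], starts[r + 1]):
            c = base_col[k]
            code = int(seq.codes[k - starts[r]])
            if c > lc:
                matched[c] = code
                lc = c
            else:
                inserts.setdefault(lc, []).append(code)
        rows_matched.append(matched)
        rows_inserts.append(inserts)

    n_ins = np.zeros(m + 1, dtype=np.int64)
    for inserts in rows_inserts:
        for anchor, codes in inserts.items():
            n_ins[anchor] = max(n_ins[anchor], len(codes))

    out = []
    for r, seq in enumerate(seqs):
        row: list[int] = []
        for anchor in range(m + 1):
            if anchor > 0:
                row.append(rows_matched[r].get(anchor, GAP))
            ins = rows_inserts[r].get(anchor, [])
            row.extend(ins)
            row.extend([GAP] * (n_ins[anchor] - len(ins)))
        out.append(EncodedSequence(np.array(row, dtype=np.int8), seq.name))
    return out
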