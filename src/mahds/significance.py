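"""Monte-Carlo significance of fitted alignments and statistical
scoring of externally produced MSAs.

The null model for a fitted score is re-optimization on composition-
preserving shuffles of the fused sequence: each shuffle gets its own
random candidate population (plus the incumbent matrix under test) and
the same genetic-algorithm budget, and the observed score is expressed
as a Z value against the mean and variance of the null scores.  An
alignment is called non-random at Z > 6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .pipeline import fit_sequence_set
from .pwm import (DinucPWM, FreqMatrix, channel_index, collapse_pwm,
                  dinucleotide_probs, frequency_to_pwm, transform_pwm)
from .sequences import GAP, EncodedSequence

__all__ = [
    "ZResult",
    "z_score",
    "null_distribution",
    "fit_significance",
    "ExternalMsaScore",
    "score_external_msa",
    "msa_significance",
]


@dataclass
class ZResult:
    z: float
    observed: float
    null_mean: float
    null_variance: float
    n_null: int

    def __post_init__(self) -> None:
        if self.null_variance <= 0:
            raise ValueError("null variance must be positive")


def z_score(observed: float, mean: float, variance: float,
            n_null: int = 0) -> ZResult:
    """Z = (observed - mean) / sqrt(variance)."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return ZResult(z=(observed - mean) / float(np.sqrt(variance)),
                   observed=observed, null_mean=mean,
                   null_variance=variance, n_null=n_null)


def null_distribution(codes: np.ndarray, lengths: list[int], m: int, N: int,
                      cfg: RunConfig, incumbent: DinucPWM | None,
                      n_shuffles: int | None = None, seed=None
                      ) -> tuple[float, float, np.ndarray]:
    """Re-optimize on shuffles of the fused sequence.

    Each shuffle runs the full pipeline (fresh random population, with
    the incumbent matrix injected when given) with the same budget as
    the observed fit; returns (mean, variance, samples) of the null
    maximum scores.
    """
    n_shuffles = n_shuffles if n_shuffles is not None else cfg.n_shuffles
    if n_shuffles < 2:
        raise ValueError("need at least 2 null shuffles")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    extra = (incumbent,) if incumbent is not None else ()
    samples = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(codes)
        out = fit_sequence_set(shuffled, lengths, m, N, cfg, rng,
                               extra_matrices=extra)
        samples[k] = out.max_score
    var = float(np.var(samples, ddof=1))
    if var <= 0:
        raise ValueError("degenerate null distribution (all scores equal)")
    return float(np.mean(samples)), var, samples


def fit_significance(outcome, cfg: RunConfig, n_shuffles: int | None = None,
                     seed=None) -> ZResult:
    """Z of a fitted score against shuffle re-optimization."""
    mean, var, samples = null_distribution(
        outcome.codes, outcome.lengths, outcome.m, outcome.n_repeats,
        cfg, outcome.best_pwm, n_shuffles, seed)
    return z_score(outcome.max_score, mean, var, n_null=len(samples))


# ---------------------------------------------------------------------------
# External MSA scoring
# ---------------------------------------------------------------------------

@dataclass
class ExternalMsaScore:
    """Decomposition of the score of an externally produced alignment.

    F1: dinucleotide terms over adjacent non-gap pairs; F2: collapsed-
    matrix terms where the previous symbol is absent (after a gap, and
    at the very first symbol of the merged sequence — mirroring the
    DP's boundary scoring); the penalty removes del per gap kept (k1)
    and per nucleotide discarded with sparse columns (k2).
    F5 = F1 + F2 - (k1 + k2) * del.
    """

    F1: float
    F2: float
    F5: float
    k1: int
    k2: int
    kept_columns: int
    n_rows: int
    pwm: DinucPWM
    filtered_rows: list

    @property
    def gap_penalty(self) -> float:
        return self.F1 + self.F2 - self.F5


def _check_rectangular(rows: list[EncodedSequence]) -> int:
    K = {len(r) for r in rows}
    if len(K) != 1:
        raise ValueError(f"MSA rows have unequal lengths {sorted(K)}")
    return K.pop()


def score_external_msa(rows: list[EncodedSequence],
                       cfg: RunConfig | None = None,
                       restrict_f2_to_gaps: bool = False
                       ) -> ExternalMsaScore:
    """Score an aligned set of gapped rows with its own image matrix.

    Columns with fewer than N/2 non-gap characters are dropped (their
    k2 nucleotides are charged as deletions); the surviving alignment
    A' yields a transformed PWM, and the merged gapped sequence is
    scored against it position by position.
    """
    cfg = cfg or RunConfig()
    if not rows:
        raise ValueError("empty alignment")
    K = _check_rectangular(rows)
    N = len(rows)
    mat = np.stack([r.codes for r in rows])          # (N, K), 0 = gap
    nongap = (mat > 0).sum(axis=0)
    keep = nongap * 2 >= N
    k2 = int(mat[:, ~keep].astype(bool).sum())
    A = mat[:, keep]
    Kp = int(keep.sum())
    if Kp == 0:
        raise ValueError("no columns left after sparse-column filtering")
    k1 = int((A == GAP).sum())

    s4 = A.reshape(-1)                               # merged rows, gaps kept
    s5 = np.tile(np.arange(1, Kp + 1, dtype=np.int64), N)
    p2 = dinucleotide_probs(s4)

    # frequency matrix over adjacent non-gap pairs (row joins included)
    prev = s4[:-1].astype(np.int64)
    cur = s4[1:].astype(np.int64)
    rows_idx = s5[1:] - 1
    valid = (prev > 0) & (cur > 0)
    chans = (prev[valid] - 1) + 4 * (cur[valid] - 1)
    flat = np.bincount(rows_idx[valid] * 16 + chans, minlength=Kp * 16)
    W = frequency_to_pwm(FreqMatrix(flat.reshape(Kp, 16)), p2=p2)
    WT = transform_pwm(W, cfg.r0_coef * Kp, cfg.k0)
    E = collapse_pwm(WT.W)

    F1 = 0.0
    F2 = 0.0
    L = s4.shape[0]
    for i in range(L):
        if s4[i] == GAP:
            continue
        row = int(s5[i]) - 1
        if i > 0 and s4[i - 1] != GAP:
            F1 += WT.W[row, channel_index(int(s4[i - 1]), int(s4[i])) - 1]
        else:
            if restrict_f2_to_gaps and (i == 0 or i % Kp == 0):
                continue
            F2 += E[row, int(s4[i]) - 1]

    F5 = F1 + F2 - (k1 + k2) * cfg.del_penalty
    filtered = [EncodedSequence(A[r], rows[r].name) for r in range(N)]
    return ExternalMsaScore(F1=F1, F2=F2, F5=F5, k1=k1, k2=k2,
                            kept_columns=Kp, n_rows=N, pwm=WT,
                            filtered_rows=filtered)


def msa_significance(rows: list[EncodedSequence],
                     cfg: RunConfig | None = None,
                     n_shuffles: int | None = None, seed=None) -> ZResult:
    """Z of an external MSA: its F5 against re-optimized shuffles of the
    ungapped merged sequence, with the alignment's own matrix injected
    into each null population."""
    cfg = cfg or RunConfig()
    ext = score_external_msa(rows, cfg)
    ungapped = [r.ungapped() for r in ext.filtered_rows]
    codes = np.concatenate([r.codes for r in ungapped])
    lengths = [len(r) for r in ungapped]
    mean, var, samples = null_distribution(
        codes, lengths, ext.kept_columns, ext.n_rows, cfg, ext.pwm,
        n_shuffles, seed)
    return z_score(ext.F5, mean, var, n_null=len(samples))
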