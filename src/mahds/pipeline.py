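"""End-to-end fit of the PWM image to a set of sequences.

This glues the stages together: fuse the inputs into one sequence S,
build the random candidate population from shuffles of S, optionally add
the matrix of the naive ungapped stacking as a starting point, and run
the genetic algorithm.  Null re-optimizations for significance reuse the
same entry points on shuffles of S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import DIAG, SSKIP, DpConfig, align_to_pwm
from .config import RunConfig
from .ga import OptimizeResult, optimize_pwm
from .pwm import (DinucPWM, FreqMatrix, PwmSet, dinucleotide_probs,
                  frequency_to_pwm, generate_random_pwm_set, transform_pwm)
from .sequences import EncodedSequence

__all__ = ["FitOutcome", "stack_pwm", "fit_sequence_set", "fuse"]


def fuse(seqs: list[EncodedSequence], profile_length: int | None = None
         ) -> tuple[np.ndarray, list[int], int, int]:
    """Concatenate (possibly ragged) ungapped sequences.

    Returns (codes, lengths, m, N) where m is the profile length —
    the rounded mean length unless given explicitly.
    """
    if not seqs:
        raise ValueError("no sequences")
    for s in seqs:
        if s.is_gapped:
            raise ValueError(f"sequence {s.name!r} contains gaps")
    lengths = [len(s) for s in seqs]
    codes = np.concatenate([s.codes for s in seqs])
    m = profile_length or int(round(float(np.mean(lengths))))
    return codes, lengths, m, len(seqs)


def stack_pwm(codes: np.ndarray, lengths: list[int], m: int,
              R0: float, K0: float, p2: np.ndarray | None = None
              ) -> DinucPWM:
    """Transformed PWM of the naive ungapped stacking of the inputs.

    Each fused chunk restarts the profile track at 1; dinucleotide pairs
    falling beyond profile position m are ignored.  This matrix is the
    identity-alignment hypothesis and serves as an optional starting
    point for the optimizer.
    """
    track = np.concatenate([np.arange(1, ln + 1, dtype=np.int64)
                            for ln in lengths])
    prev = codes[:-1].astype(np.int64)
    cur = codes[1:].astype(np.int64)
    rows = track[1:] - 1
    keep = rows < m
    chans = (prev - 1) + 4 * (cur - 1)
    flat = np.bincount(rows[keep] * 16 + chans[keep], minlength=m * 16)
    if p2 is None:
        p2 = dinucleotide_probs(codes)
    W = frequency_to_pwm(FreqMatrix(flat.reshape(m, 16)), p2=p2)
    return transform_pwm(W, R0, K0)


def pwm_from_alignment(result, codes: np.ndarray, m: int, R0: float,
                       K0: float, p2: np.ndarray | None = None) -> DinucPWM:
    """Rebuild the transformed PWM from an alignment's columnization.

    Adjacent sequence bases that were both consumed diagonally are
    counted into the profile column of the second base; bases routed
    through sequence-skips contribute no pairs.
    """
    base_col = np.zeros(codes.shape[0], dtype=np.int64)
    i = j = 0
    for mv in result.path:
        if mv == DIAG:
            i += 1
            j += 1
            base_col[j - 1] = (i - 1) % m + 1
        elif mv == SSKIP:
            j += 1
        else:
            i += 1
    M = np.zeros((m, 16), dtype=np.int64)
    prev = codes[:-1].astype(np.int64)
    cur = codes[1:].astype(np.int64)
    cols = base_col[1:]
    valid = (base_col[:-1] > 0) & (cols > 0)
    chans = (prev - 1) + 4 * (cur - 1)
    np.add.at(M, (cols[valid] - 1, chans[valid]), 1)
    if p2 is None:
        p2 = dinucleotide_probs(codes)
    W = frequency_to_pwm(FreqMatrix(M), p2=p2)
    return transform_pwm(W, R0, K0)


def refined_stack_pwm(codes: np.ndarray, lengths: list[int], m: int, N: int,
                      R0: float, K0: float, dp_cfg: DpConfig,
                      rounds: int = 2) -> DinucPWM:
    """Self-consistent stack initialization.

    The naive-stack matrix is degraded wherever an indel shifts a
    sequence out of register; aligning with it and rebuilding the
    matrix from the realigned columns restores those counts.  A couple
    of rounds suffice; the result seeds the optimizer population.
    """
    p2 = dinucleotide_probs(codes)
    pwm = stack_pwm(codes, lengths, m, R0, K0, p2)
    for _ in range(rounds):
        res = align_to_pwm(codes, pwm, N, dp_cfg)
        pwm = pwm_from_alignment(res, codes, m, R0, K0, p2)
    return pwm


@dataclass
class FitOutcome:
    """Result of one full pipeline run on a sequence set."""

    best_pwm: DinucPWM
    max_score: float
    optimize: OptimizeResult
    m: int
    n_repeats: int
    lengths: list[int]
    codes: np.ndarray


def fit_sequence_set(codes: np.ndarray, lengths: list[int], m: int, N: int,
                     cfg: RunConfig, seed=None,
                     extra_matrices: tuple[DinucPWM, ...] = ()
                     ) -> FitOutcome:
    """Run the full pipeline on an already-fused sequence set.

    `extra_matrices` are appended to the initial population (used to
    inject an incumbent matrix into null re-optimizations).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    R0 = cfg.r0_coef * m
    dp_cfg = DpConfig(del_penalty=cfg.del_penalty,
                      use_context=cfg.use_context)
    Q = generate_random_pwm_set(codes, m, cfg.q_candidates, cfg.n1,
                                R0, cfg.k0, rng)
    mats = list(Q.matrices)
    if cfg.seed_with_stack:
        mats.append(stack_pwm(codes, lengths, m, R0, cfg.k0))
        mats.append(refined_stack_pwm(codes, lengths, m, N, R0, cfg.k0,
                                      dp_cfg))
    mats.extend(extra_matrices)
    opt = optimize_pwm(codes, PwmSet(mats, D0=Q.D0), N, dp_cfg, cfg.ga, rng)
    return FitOutcome(best_pwm=opt.best_pwm, max_score=opt.best_score,
                      optimize=opt, m=m, n_repeats=N, lengths=list(lengths),
                      codes=codes)


def fit_sequences(seqs: list[EncodedSequence], cfg: RunConfig,
                  profile_length: int | None = None, seed=None) -> FitOutcome:
    codes, lengths, m, N = fuse(seqs, profile_length)
    return fit_sequence_set(codes, lengths, m, N, cfg, seed)
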