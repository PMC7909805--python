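"""Genetic-algorithm optimization of the candidate matrix population.

The objective of a matrix is the terminal DP score F(L,L) of the input
sequence against the matrix tiled N times.  The population is kept
sorted by objective; each cycle (i) draws two parents by linear rank
selection, (ii) builds a descendant by quadrant crossover, (iii)
replaces the current worst matrix with the descendant, (iv) mutates a
fixed fraction of matrices by one uniformly drawn element each, and (v)
re-sorts.  The best matrix ever evaluated is retained separately, so
the returned optimum is well-defined even when mutation later damages
the incumbent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align import AlignmentResult, DpConfig, align_to_pwm, pwm_score
from .config import GaConfig
from .pwm import DinucPWM

__all__ = ["rank_select", "crossover", "mutate_set", "optimize_pwm",
           "OptimizeResult"]


def rank_select(n1: int, rng: np.random.Generator) -> tuple[int, int]:
    """Two distinct indices into the ascending-sorted population, drawn
    with probability proportional to rank (1..n1), without replacement."""
    if n1 < 2:
        raise ValueError("rank selection needs at least 2 individuals")
    ranks = np.arange(1, n1 + 1, dtype=np.float64)
    p = ranks / ranks.sum()
    first = int(rng.choice(n1, p=p))
    p2 = p.copy()
    p2[first] = 0.0
    p2 /= p2.sum()
    second = int(rng.choice(n1, p=p2))
    return first, second


def _apply_quadrants(a: np.ndarray, b: np.ndarray, r0: int, c0: int,
                     mask) -> np.ndarray:
    """Copy the pivot-anchored quadrants of `a` flagged in `mask`
    (above-left, above-right, below-left, below-right) onto a copy of
    `b`.  The four blocks partition the matrix, so an all-true mask
    returns `a` and an all-false mask returns `b`."""
    child = b.copy()
    blocks = ((slice(0, r0), slice(0, c0)),
              (slice(0, r0), slice(c0, None)),
              (slice(r0, None), slice(0, c0)),
              (slice(r0, None), slice(c0, None)))
    for flag, (rs, cs) in zip(mask, blocks):
        if flag:
            child[rs, cs] = a[rs, cs]
    return child


def crossover(parent_a: np.ndarray, parent_b: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Quadrant crossover: uniform pivot cell in parent_a, each of the
    four pivot-anchored rectangles independently copied into a copy of
    parent_b with probability 0.25."""
    if parent_a.shape != parent_b.shape:
        raise ValueError("parent shapes differ")
    r0 = int(rng.integers(parent_a.shape[0]))
    c0 = int(rng.integers(parent_a.shape[1]))
    mask = rng.random(4) < 0.25
    return _apply_quadrants(parent_a, parent_b, r0, c0, mask)


def mutate_set(mats: list[np.ndarray], cfg: GaConfig,
               rng: np.random.Generator) -> list[int]:
    """Mutate ceil(mutation_fraction * n) matrices in place, one
    uniformly chosen element each, drawn from the mutation range.
    Returns the indices of the mutated matrices (for re-evaluation)."""
    n = len(mats)
    k = math.ceil(cfg.mutation_fraction * n)
    if k == 0:
        return []
    idxs = rng.choice(n, size=k, replace=False)
    for idx in idxs:
        W = mats[idx]
        r = int(rng.integers(W.shape[0]))
        c = int(rng.integers(W.shape[1]))
        W[r, c] = rng.uniform(cfg.mutation_low, cfg.mutation_high)
    return [int(i) for i in idxs]


@dataclass
class OptimizeResult:
    best_pwm: DinucPWM
    best_score: float
    alignment: AlignmentResult
    history: np.ndarray          # best-so-far after each cycle
    n_cycles: int
    n_evaluations: int


def optimize_pwm(S, Q0, n_repeats: int, dp_cfg: DpConfig,
                 ga_cfg: GaConfig, seed=None) -> OptimizeResult:
    """Evolve the population Q0 against sequence S; return the best
    matrix ever seen, its score, its alignment and the score history."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mats = [q.W.copy() for q in Q0.matrices] if hasattr(Q0, "matrices") \
        else [np.array(q, dtype=np.float64) for q in Q0]
    if not mats:
        raise ValueError("empty initial population")
    template = Q0.matrices[0] if hasattr(Q0, "matrices") else None
    p1 = template.p1.copy() if template is not None else None
    p2 = template.p2.copy() if template is not None else None
    n1 = len(mats)
    n_evals = 0

    def score(W: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return pwm_score(S, DinucPWM(W, p1=p1, p2=p2), n_repeats, dp_cfg)

    V = np.array([score(W) for W in mats])
    order = np.argsort(V, kind="stable")
    mats = [mats[i] for i in order]
    V = V[order]
    best_score = float(V[-1])
    best = mats[-1].copy()
    history = [best_score]
    since_improved = 0
    cycle = 0
    while cycle < ga_cfg.max_cycles:
        cycle += 1
        prev_max = float(V[-1])
        if n1 >= 2:
            ia, ib = rank_select(n1, rng)
            child = crossover(mats[ia], mats[ib], rng)
            mats[0] = child          # replace current worst
            V[0] = score(child)
        for idx in mutate_set(mats, ga_cfg, rng):
            V[idx] = score(mats[idx])
        order = np.argsort(V, kind="stable")
        mats = [mats[i] for i in order]
        V = V[order]
        if V[-1] > best_score:
            best_score = float(V[-1])
            best = mats[-1].copy()
            since_improved = 0
        else:
            since_improved += 1
        history.append(best_score)
        if ga_cfg.stop_on_decrease and V[-1] < prev_max:
            break
        if since_improved >= ga_cfg.patience:
            break

    best_pwm = DinucPWM(best, p1=p1, p2=p2)
    alignment = align_to_pwm(S, best_pwm, n_repeats, dp_cfg)
    # the traceback score equals the best evaluated score by construction;
    # keep the evaluated value as the canonical objective
    return OptimizeResult(best_pwm=best_pwm, best_score=best_score,
                          alignment=alignment, history=np.array(history),
                          n_cycles=cycle, n_evaluations=n_evals)
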