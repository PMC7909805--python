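"""Per-position dinucleotide conservation profiles over a class MSA.

For each alignment column l >= 2 and each of the 16 dinucleotide
channels, the observed count of (base at l-1, base at l) pairs across
rows is compared with the expectation N*p(i)*p(j) under independent
bases, as a binomial z-score

    Z(l, n) = (M(l, n) - N p(i) p(j)) / sqrt(N p(i) p(j) (1 - p(i) p(j)))

The per-position statistic chi(l) = sum_n Z(l, n)^2 follows a
chi-squared law with f = 15 degrees of freedom under the null and is
mapped to the normal scale with X(l) = sqrt(2 chi) - sqrt(2 f - 1).
Pairs interrupted by a gap in the row are skipped; position 1 has no
previous base and carries zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import GAP, EncodedSequence

__all__ = [
    "ConservationProfile",
    "dinucleotide_conservation",
    "chi_to_normal",
    "pair_group_zscore",
    "shuffle_msa_preserving_gaps",
]

DOF = 15


@dataclass
class ConservationProfile:
    Zmat: np.ndarray        # (m, 16)
    chi: np.ndarray         # (m,)
    X: np.ndarray           # (m,)
    counts: np.ndarray      # (m, 16) observed dinucleotide counts
    base_probs: np.ndarray  # 4-vector p(a), p(t), p(c), p(g)
    f: int = DOF

    @property
    def positions(self) -> np.ndarray:
        """1-based alignment columns."""
        return np.arange(1, self.Zmat.shape[0] + 1)


def _msa_matrix(rows: list[EncodedSequence]) -> np.ndarray:
    K = {len(r) for r in rows}
    if len(K) != 1:
        raise ValueError("MSA rows must have equal gapped length")
    return np.stack([r.codes for r in rows])


def _pair_counts(mat: np.ndarray) -> np.ndarray:
    """(m x 16) counts of adjacent-column non-gap pairs per column."""
    m = mat.shape[1]
    counts = np.zeros((m, 16), dtype=np.int64)
    prev = mat[:, :-1].astype(np.int64)
    cur = mat[:, 1:].astype(np.int64)
    valid = (prev > 0) & (cur > 0)
    cols, chans = [], []
    col_idx = np.broadcast_to(np.arange(1, m), prev.shape)
    chan = (prev - 1) + 4 * (cur - 1)
    flat = np.bincount(col_idx[valid] * 16 + chan[valid], minlength=m * 16)
    return flat.reshape(m, 16)


def dinucleotide_conservation(rows: list[EncodedSequence],
                              base_probs: np.ndarray | None = None,
                              warn_small: bool = True
                              ) -> ConservationProfile:
    """Build the conservation profile of a rectangular gapped MSA.

    Base probabilities are measured from all non-gap characters of the
    alignment unless provided.  With fewer than 20 rows the normal
    approximation is poor; a warning is emitted but the profile is
    still computed.
    """
    mat = _msa_matrix(rows)
    N = mat.shape[0]
    if N < 20 and warn_small:
        import warnings
        warnings.warn(f"only {N} rows; the binomial normal approximation "
                      "is unreliable", stacklevel=2)
    if base_probs is None:
        bases = mat[mat > 0]
        base_probs = np.bincount(bases, minlength=5)[1:5] / bases.size
    base_probs = np.asarray(base_probs, dtype=np.float64)

    counts = _pair_counts(mat)
    # channel ch = prev + 4*(cur-1); expected p(prev)*p(cur)
    p_pair = np.outer(base_probs, base_probs).T.reshape(-1)
    t = N * p_pair
    D = N * p_pair * (1.0 - p_pair)
    Zmat = np.zeros_like(counts, dtype=np.float64)
    ok = D > 0          # channels with degenerate expectation score 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Zmat[1:, ok] = (counts[1:, ok] - t[ok]) / np.sqrt(D[ok])
    chi = np.sum(Zmat ** 2, axis=1)
    X = chi_to_normal(chi, DOF)
    return ConservationProfile(Zmat=Zmat, chi=chi, X=X, counts=counts,
                               base_probs=base_probs)


def chi_to_normal(chi, f: int = DOF):
    """Normal-scale transform sqrt(2 chi) - sqrt(2 f - 1) of a
    chi-squared variable with f degrees of freedom."""
    chi = np.asarray(chi, dtype=np.float64)
    if np.any(chi < 0):
        raise ValueError("chi-squared values must be non-negative")
    out = np.sqrt(2.0 * chi) - np.sqrt(2.0 * f - 1.0)
    return float(out) if out.ndim == 0 else out


def pair_group_zscore(rows: list[EncodedSequence], column: int,
                      pairs: list[str],
                      base_probs: np.ndarray | None = None
                      ) -> tuple[float, float, float, float]:
    """Aggregated binomial z for a group of dinucleotides at one column.

    Counts rows whose (column-1, column) pair is any of `pairs` (e.g.
    ["at", "ta", "cg", "gc"]), against the pooled probability
    P = sum p(i) p(j).  Returns (P, expected, variance, z) — the worked
    small-alignment arithmetic: 12 rows of pooled probability 0.25 give
    expectation 3, variance 2.25, and z = (12 - 3)/1.5 = 6 when all 12
    rows carry an allowed pair.
    """
    from .pwm import channel_index
    from .sequences import encode

    mat = _msa_matrix(rows)
    N = mat.shape[0]
    if base_probs is None:
        bases = mat[mat > 0]
        base_probs = np.bincount(bases, minlength=5)[1:5] / bases.size
    if column < 2 or column > mat.shape[1]:
        raise ValueError("column must be in 2..K")
    channels = []
    P = 0.0
    for lbl in pairs:
        prev, cur = encode(lbl)
        channels.append(channel_index(int(prev), int(cur)) - 1)
        P += base_probs[prev - 1] * base_probs[cur - 1]
    counts = _pair_counts(mat)
    observed = float(counts[column - 1, channels].sum())
    expected = N * P
    variance = N * P * (1.0 - P)
    z = (observed - expected) / np.sqrt(variance)
    return P, expected, variance, float(z)


def shuffle_msa_preserving_gaps(rows: list[EncodedSequence], seed=None
                                ) -> list[EncodedSequence]:
    """Control profile input: permute each row's bases among its own
    non-gap positions, keeping every gap where it is."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = []
    for r in rows:
        codes = r.codes.copy()
        idx = np.where(codes != GAP)[0]
        codes[idx] = rng.permutation(codes[idx])
        out.append(EncodedSequence(codes, r.name))
    return out
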