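"""Synthetic data: star-divergence sequence sets, indel planting, and
small worked-example fixtures (a 12-sequence dinucleotide-grammar toy
alignment and a bundled 5-position example matrix pair).

The divergence parameter x is the expected number of substitution
*events* per site between any pair of sequences (an evolutionary
distance, not the observed difference).  Sets are generated on a star
phylogeny: one uniform random ancestor, each descendant mutated with
branch length x/2 so that any pair is separated by x events on average.
Substitution events follow the Jukes-Cantor kernel (uniform choice among
the three other bases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import DinucPWM
from .sequences import EncodedSequence

__all__ = [
    "DivergenceSpec",
    "IndelEvent",
    "mutate_sequence",
    "generate_divergent_set",
    "generate_family_collection",
    "toy_grammar_set",
    "example_random_matrix",
    "example_transformed_matrix",
]


@dataclass
class DivergenceSpec:
    """Parameters of one divergent set G(x)."""

    n_sequences: int
    length: int
    x: float
    n_insertions: int = 0
    n_deletions: int = 0
    indel_length: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("x must be >= 0")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if min(self.n_sequences, self.n_insertions, self.n_deletions,
               self.indel_length) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class IndelEvent:
    """Ground-truth record of one planted insertion or deletion.

    `position` is the 1-based coordinate in the sequence at the moment
    the event was applied (events are applied in random order, so later
    events shift earlier coordinates).
    """

    sequence: int          # 0-based index into the returned list
    position: int
    kind: str              # "ins" | "del"
    length: int


def mutate_sequence(s: EncodedSequence, branch_x: float, seed=None
                    ) -> EncodedSequence:
    """Apply a Poisson(branch_x) number of substitution events per site.

    Each event replaces the current base by one of the three other bases
    chosen uniformly, so the per-site process is the Jukes-Cantor chain
    and the probability that a site is left untouched is exp(-branch_x).
    """
    if s.is_gapped:
        raise ValueError("mutate_sequence expects an ungapped sequence")
    if branch_x < 0:
        raise ValueError("branch_x must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    codes = s.codes.astype(np.int64).copy()
    counts = rng.poisson(branch_x, codes.shape[0])
    while True:
        active = counts > 0
        if not active.any():
            break
        shift = rng.integers(1, 4, int(active.sum()))
        codes[active] = (codes[active] - 1 + shift) % 4 + 1
        counts[active] -= 1
    return EncodedSequence(codes.astype(np.int8), s.name)


def _random_sequence(m: int, rng: np.random.Generator, name: str = ""
                     ) -> EncodedSequence:
    return EncodedSequence(rng.integers(1, 5, m).astype(np.int8), name)


def generate_divergent_set(spec: DivergenceSpec
                           ) -> tuple[list[EncodedSequence], list[IndelEvent]]:
    """Simulate a G(x) set plus its ground-truth indel ledger.

    A single uniform ancestor of length m is drawn; every descendant is
    mutated with branch length x/2 (star phylogeny, so pairwise expected
    events per site equal x).  Then `n_insertions` insertions and
    `n_deletions` deletions of `indel_length` nt are applied at uniform
    positions of uniformly chosen sequences, in random interleaved order.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = _random_sequence(spec.length, rng)
    seqs = []
    for i in range(spec.n_sequences):
        d = mutate_sequence(ancestor, spec.x / 2.0, rng)
        d.name = f"seq{i + 1}"
        seqs.append(d)

    events = ["ins"] * spec.n_insertions + ["del"] * spec.n_deletions
    rng.shuffle(events)
    ledger: list[IndelEvent] = []
    for kind in events:
        if kind == "ins":
            r = int(rng.integers(spec.n_sequences))
            codes = seqs[r].codes
            pos = int(rng.integers(len(codes) + 1))
            insert = rng.integers(1, 5, spec.indel_length).astype(np.int8)
            seqs[r] = EncodedSequence(
                np.concatenate([codes[:pos], insert, codes[pos:]]),
                seqs[r].name)
            ledger.append(IndelEvent(r, pos + 1, "ins", spec.indel_length))
        else:
            while True:
                r = int(rng.integers(spec.n_sequences))
                codes = seqs[r].codes
                if len(codes) >= spec.indel_length + 1:
                    break
            pos = int(rng.integers(len(codes) - spec.indel_length + 1))
            seqs[r] = EncodedSequence(
                np.concatenate([codes[:pos],
                                codes[pos + spec.indel_length:]]),
                seqs[r].name)
            ledger.append(IndelEvent(r, pos + 1, "del", spec.indel_length))
    return seqs, ledger


def generate_family_collection(n_families: int, family_size: int, length: int,
                               x: float, seed=None
                               ) -> tuple[list[EncodedSequence], np.ndarray]:
    """Mixture of unrelated divergent families, shuffled together.

    Each family descends from its own independent random ancestor with
    within-family pairwise divergence x.  Returns the pooled sequences in
    random order plus the true family label of each.
    """
    rng = np.random.default_rng(seed)
    seqs: list[EncodedSequence] = []
    labels = []
    for fam in range(n_families):
        fam_seqs, _ = generate_divergent_set(DivergenceSpec(
            n_sequences=family_size, length=length, x=x,
            seed=int(rng.integers(2 ** 31))))
        for i, s in enumerate(fam_seqs):
            s.name = f"fam{fam + 1}_{i + 1}"
            seqs.append(s)
            labels.append(fam)
    order = rng.permutation(len(seqs))
    return [seqs[i] for i in order], np.asarray(labels)[order]


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

_TOY_STRINGS = ("atcg", "tagc", "cgat", "gcta", "atat", "tata",
                 "gcgc", "cgcg", "atta", "taat", "cgta", "gcat")


def toy_grammar_set() -> list[EncodedSequence]:
    """The 12 four-nt toy sequences whose leading columns are
    individually uniform while positions 1-2 and 3-4 carry only the
    dinucleotides at/ta/cg/gc — per-column base frequencies say nothing
    about the strong adjacent-base correlation."""
    return [EncodedSequence.from_string(s, f"toy{i + 1}")
            for i, s in enumerate(_TOY_STRINGS)]


# Bundled 16-row x 5-column example matrices (rows labelled by
# (previous, current) dinucleotide in the order aa,at,ac,ag,ta,tt,...).
# Stored transposed relative to the (positions x 16 channels) layout.
_EXAMPLE_ROW_LABELS = ("aa", "at", "ac", "ag", "ta", "tt", "tc", "tg",
                      "ca", "ct", "cc", "cg", "ga", "gt", "gc", "gg")

_EXAMPLE_RANDOM = """
-1.6 -1.0 -1.6 -1.6 -1.6
-1.7  1.7 -1.7 -1.0  3.2
-1.3  0.2 -1.3 -1.3  3.5
-1.3 -1.3 -0.6 -1.3 -1.3
-1.0 -1.7  2.7 -1.0 -1.7
 1.5 -1.1 -0.5  2.1 -0.5
 1.7 -1.3 -0.6 -0.5 -1.3
 0.0 -0.7  1.5 -0.6 -1.4
-1.3 -1.3  0.2 -1.3 -1.3
 0.1 -0.6 -1.3  1.7 -1.3
-1.0 -1.0 -1.0  0.9 -1.0
-1.1 -1.1 -0.1 -1.0 -1.0
-1.3 -1.3 -0.6 -1.3 -0.5
-0.7  3.0 -1.4 -1.4 -1.4
-1.1 -1.1 -1.1 -1.0 -1.0
-1.1 -1.1 -1.1 -1.1 -1.1
"""

_EXAMPLE_TRANSFORMED = """
-5.4 -2.9 -5.4 -5.3 -5.3
-5.7  7.6 -5.7 -3.0 13.4
-4.1  1.9 -4.1 -4.0 14.7
-4.4 -4.4 -1.4 -4.2 -4.2
-3.2 -5.7 11.4 -3.0 -5.6
 6.8 -3.5 -1.2  9.2 -1.0
 7.7 -4.3 -1.3 -1.2 -4.2
 1.1 -1.7  6.8 -1.5 -4.5
-4.1 -4.1  1.9 -4.0 -4.0
 1.6 -1.3 -4.3  7.8 -4.2
-3.1 -3.1 -3.1  4.5 -3.0
-3.3 -3.3  0.3 -3.2 -3.2
-4.4 -4.4 -1.4 -4.2 -1.2
-1.7 12.5 -4.6 -4.5 -4.5
-3.3 -3.3 -3.3 -3.2 -3.2
-3.5 -3.5 -3.5 -3.4 -3.4
"""


def _parse_table(text: str) -> np.ndarray:
    from .pwm import channel_index
    from .sequences import encode

    rows = np.array([[float(v) for v in line.split()]
                     for line in text.strip().splitlines()])
    assert rows.shape == (16, 5)
    W = np.zeros((5, 16))
    for r, label in enumerate(_EXAMPLE_ROW_LABELS):
        prev, cur = encode(label)
        ch = channel_index(int(prev), int(cur))
        W[:, ch - 1] = rows[r]
    return W


def example_random_matrix() -> DinucPWM:
    """The bundled untransformed 5-position example matrix (R^2 ~ 155)."""
    return DinucPWM(_parse_table(_EXAMPLE_RANDOM))


def example_transformed_matrix() -> DinucPWM:
    """Its reference transform with targets R^2 = 2000, K_d = -1.5
    (uniform dinucleotide probabilities)."""
    return DinucPWM(_parse_table(_EXAMPLE_TRANSFORMED))
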