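"""DNA sequence encoding, FASTA I/O and the concatenated sequence model.

Bases are coded a=1, t=2, c=3, g=4; 0 is reserved for the gap character
in gapped (aligned) sequences.  All public position reports are 1-based;
internally numpy 0-based arrays are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "EncodedSequence",
    "ConcatSet",
    "encode",
    "decode",
    "read_fasta",
    "write_fasta",
    "concatenate",
    "shuffle_sequence",
]

logger = logging.getLogger(__name__)

GAP = 0
_CODE = {"a": 1, "t": 2, "c": 3, "g": 4, "-": GAP}
_BASE = np.array(["-", "a", "t", "c", "g"])


def encode(text: str, *, allow_gaps: bool = False) -> np.ndarray:
    """Encode a DNA string into integer codes (a=1, t=2, c=3, g=4).

    Raises ValueError naming the 1-based position of the first symbol
    outside the alphabet.
    """
    codes = np.empty(len(text), dtype=np.int8)
    for pos, ch in enumerate(text.lower()):
        code = _CODE.get(ch)
        if code is None or (code == GAP and not allow_gaps):
            raise ValueError(
                f"invalid symbol {ch!r} at position {pos + 1}: "
                "expected a/t/c/g" + ("/-" if allow_gaps else "")
            )
        codes[pos] = code
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; gaps become '-'."""
    return "".join(_BASE[np.asarray(codes, dtype=int)])


@dataclass
class EncodedSequence:
    """A named DNA sequence held as integer codes."""

    codes: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)

    @classmethod
    def from_string(cls, text: str, name: str = "", *, allow_gaps: bool = False
                    ) -> "EncodedSequence":
        return cls(encode(text, allow_gaps=allow_gaps), name)

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return decode(self.codes)

    @property
    def is_gapped(self) -> bool:
        return bool(np.any(self.codes == GAP))

    def ungapped(self) -> "EncodedSequence":
        return EncodedSequence(self.codes[self.codes != GAP], self.name)


@dataclass
class ConcatSet:
    """N equal-length sequences fused into one sequence S with the
    periodic profile-index track S1 = (1..m) repeated N times."""

    S: EncodedSequence
    S1: np.ndarray
    N: int
    m: int
    names: list = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.S)


def read_fasta(path, *, allow_gaps: bool = False, seed: int | None = 0
               ) -> list[EncodedSequence]:
    """Read a (possibly aligned) FASTA file into encoded sequences.

    Ambiguity codes ('n', case-insensitive) are replaced by a seeded
    uniform random base so downstream four-letter arithmetic stays exact;
    the number of replacements is logged.  Any other non-nucleotide
    symbol raises ValueError with the record and 1-based position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    rng = np.random.default_rng(seed)
    out: list[EncodedSequence] = []
    n_replaced = 0
    for rec in records:
        text = str(rec.seq).lower()
        if "n" in text:
            chars = list(text)
            for i, ch in enumerate(chars):
                if ch == "n":
                    chars[i] = "atcg"[rng.integers(4)]
                    n_replaced += 1
            text = "".join(chars)
        try:
            codes = encode(text, allow_gaps=allow_gaps)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from None
        out.append(EncodedSequence(codes, rec.description or rec.id))
    if n_replaced:
        logger.info("replaced %d 'n' symbols with random bases", n_replaced)
    return out


def write_fasta(seqs: Iterable[EncodedSequence], path) -> None:
    """Write sequences as lowercase FASTA, names preserved verbatim."""
    records = [
        SeqRecord(Seq(decode(s.codes)), id=s.name or f"seq{i + 1}",
                  description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(seqs: Sequence[EncodedSequence]) -> ConcatSet:
    """Fuse >= 2 equal-length ungapped sequences into the S/S1 model."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to build a model")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths {sorted(lengths)}; "
                         "model building requires a fixed length")
    for s in seqs:
        if s.is_gapped:
            raise ValueError(f"sequence {s.name!r} contains gaps")
    m = lengths.pop()
    N = len(seqs)
    S = EncodedSequence(np.concatenate([s.codes for s in seqs]), "S")
    S1 = np.tile(np.arange(1, m + 1, dtype=np.int32), N)
    return ConcatSet(S=S, S1=S1, N=N, m=m, names=[s.name for s in seqs])


def split_concat(cs: ConcatSet) -> list[EncodedSequence]:
    """Inverse of :func:`concatenate`."""
    return [
        EncodedSequence(cs.S.codes[i * cs.m:(i + 1) * cs.m],
                        cs.names[i] if cs.names else f"seq{i + 1}")
        for i in range(cs.N)
    ]


def shuffle_sequence(s: EncodedSequence, seed=None) -> EncodedSequence:
    """Uniform random permutation of the codes (composition preserved).

    `seed` may be an int or a numpy Generator.
    """
    if s.is_gapped:
        raise ValueError("shuffling is defined for ungapped sequences")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return EncodedSequence(rng.permutation(s.codes), s.name)
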