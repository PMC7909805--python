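"""Model/Results interface to the divergent-alignment pipeline.

`MahdsModel` holds a set of DNA sequences and the run configuration;
`fit()` optimizes the dinucleotide PWM image by the genetic algorithm
and returns a `MahdsResults` carrying the fitted matrix, the objective
F(L,L), the reconstructed multiple alignment, and methods for
Monte-Carlo significance, conservation profiling and a summary table.
"""

from __future__ import annotations

import numpy as np

from .align import DpConfig, reconstruct_msa
from .config import RunConfig
from .conservation import ConservationProfile, dinucleotide_conservation
from .pipeline import FitOutcome, fit_sequence_set, fuse
from .pwm import DinucPWM
from .sequences import EncodedSequence, read_fasta, write_fasta
from .significance import ZResult, fit_significance

__all__ = ["MahdsModel", "MahdsResults"]


class MahdsModel:
    """Alignment-image model of a set of divergent DNA sequences.

    Parameters
    ----------
    sequences : list of EncodedSequence
        Ungapped input sequences (near-equal lengths; the profile
        length defaults to the rounded mean).
    profile_length : int, optional
        Number of PWM columns m; pass to override the default.
    config : RunConfig, optional
        Pipeline parameters; `RunConfig.desk()` is a workstation-scale
        preset.
    """

    def __init__(self, sequences: list[EncodedSequence],
                 profile_length: int | None = None,
                 config: RunConfig | None = None):
        if len(sequences) < 1:
            raise ValueError("need at least one sequence")
        self.sequences = list(sequences)
        self.config = config or RunConfig()
        codes, lengths, m, N = fuse(self.sequences, profile_length)
        self.codes = codes
        self.lengths = lengths
        self.profile_length = m
        self.n_sequences = N

    @classmethod
    def from_fasta(cls, path, profile_length: int | None = None,
                   config: RunConfig | None = None, seed: int | None = 0
                   ) -> "MahdsModel":
        return cls(read_fasta(path, seed=seed), profile_length, config)

    @property
    def dp_config(self) -> DpConfig:
        return DpConfig(del_penalty=self.config.del_penalty,
                        use_context=self.config.use_context)

    def fit(self, seed=None) -> "MahdsResults":
        """Run the full pipeline (random population, optional stack
        seeding, genetic algorithm) and wrap the outcome."""
        outcome = fit_sequence_set(self.codes, self.lengths,
                                   self.profile_length, self.n_sequences,
                                   self.config, seed)
        return MahdsResults(self, outcome)


class MahdsResults:
    """Fit results: the optimized matrix, its objective and alignment."""

    def __init__(self, model: MahdsModel, outcome: FitOutcome):
        self.model = model
        self._outcome = outcome
        self.pwm: DinucPWM = outcome.best_pwm
        self.score: float = outcome.max_score
        self.history: np.ndarray = outcome.optimize.history
        self.n_cycles: int = outcome.optimize.n_cycles
        self.n_evaluations: int = outcome.optimize.n_evaluations
        self.alignment = outcome.optimize.alignment
        self._msa: list[EncodedSequence] | None = None
        self._zresult: ZResult | None = None

    @property
    def gap_moves(self) -> int:
        """Number of indel moves on the optimal path."""
        return self.alignment.n_gap_moves

    @property
    def msa(self) -> list[EncodedSequence]:
        """Reconstructed gapped rows (one per input sequence)."""
        if self._msa is None:
            self._msa = reconstruct_msa(self.alignment,
                                        self.model.sequences)
        return self._msa

    def zscore(self, n_shuffles: int | None = None, seed=None) -> ZResult:
        """Monte-Carlo significance of the fitted score: shuffles of
        the fused sequence are re-optimized with the same budget (the
        fitted matrix joins each null population) and the observed
        score is standardized against them.  Cached after first call."""
        if self._zresult is None:
            self._zresult = fit_significance(self._outcome, self.model.config,
                                             n_shuffles, seed)
        return self._zresult

    def conservation(self, base_probs=None) -> ConservationProfile:
        """Dinucleotide conservation profile of the fitted MSA."""
        return dinucleotide_conservation(self.msa, base_probs,
                                         warn_small=False)

    def to_fasta(self, path) -> None:
        write_fasta(self.msa, path)

    def summary(self) -> str:
        cfg = self.model.config
        rows = [
            ("sequences (N)", self.model.n_sequences),
            ("profile length (m)", self.model.profile_length),
            ("fused length (L)", len(self.model.codes)),
            ("objective F(L,L)", f"{self.score:.2f}"),
            ("gap moves", self.gap_moves),
            ("GA cycles", self.n_cycles),
            ("matrix evaluations", self.n_evaluations),
            ("population n1", cfg.n1),
            ("R0", f"{cfg.r0_coef:g} * m = "
                   f"{cfg.r0_coef * self.model.profile_length:g}"),
            ("K0", f"{cfg.k0:g}"),
            ("del penalty", f"{cfg.del_penalty:g}"),
        ]
        if self._zresult is not None:
            zr = self._zresult
            rows += [("Z (vs %d nulls)" % zr.n_null, f"{zr.z:.2f}"),
                     ("null mean", f"{zr.null_mean:.2f}"),
                     ("null sd", f"{np.sqrt(zr.null_variance):.2f}")]
        width = max(len(k) for k, _ in rows)
        lines = ["MAHDS alignment fit", "=" * (width + 24)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)
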