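"""Run configuration shared by the pipeline, model facade and CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["GaConfig", "RunConfig"]


@dataclass
class GaConfig:
    """Genetic-algorithm knobs.

    Each cycle creates one crossover descendant which replaces the
    current worst matrix, then perturbs `mutation_fraction` of the
    population by one uniformly drawn element each.  The optimizer
    tracks the best matrix/score ever seen and stops after `patience`
    cycles without improvement (or, with `stop_on_decrease`, at the
    first cycle where the population maximum drops — the stricter
    historical rule).
    """

    mutation_fraction: float = 0.10
    mutation_low: float = -10.0
    mutation_high: float = 10.0
    max_cycles: int = 10_000
    patience: int = 500
    stop_on_decrease: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ValueError("mutation_fraction must be in [0, 1]")
        if self.mutation_low >= self.mutation_high:
            raise ValueError("mutation range must be increasing")
        if self.max_cycles < 0 or self.patience < 1:
            raise ValueError("invalid cycle limits")


@dataclass
class RunConfig:
    """End-to-end pipeline parameters.

    R0 = r0_coef * m and K0 are the normalization targets of every
    candidate matrix; del_penalty is the flat indel cost of the DP;
    n1 is the population size; q_candidates the number of shuffled-
    sequence matrices generated before distance filtering.
    """

    del_penalty: float = 25.0
    r0_coef: float = 110.0
    k0: float = -1.8
    n1: int = 100
    q_candidates: int = 10_000
    ga: GaConfig = field(default_factory=GaConfig)
    n_shuffles: int = 200          # null re-optimizations for Z
    seq_null_shuffles: int = 1000  # fixed-matrix per-sequence null
    z_nonrandom: float = 6.0
    z0_class: float = 5.0
    sample_size: int = 500
    min_class: int = 100
    seed_with_stack: bool = True
    use_context: bool = True
    class_refit_rounds: int = 2    # 0 = gate only against the sample image

    def __post_init__(self) -> None:
        if isinstance(self.ga, dict):
            self.ga = GaConfig(**self.ga)
        if self.del_penalty <= 0 or self.r0_coef <= 0:
            raise ValueError("del_penalty and r0_coef must be positive")
        if min(self.n1, self.q_candidates, self.n_shuffles,
               self.seq_null_shuffles, self.sample_size, self.min_class) < 1:
            raise ValueError("counts must be positive")

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Workstation-scale preset: population 50, a few hundred
        matrix evaluations per fit, 20 null re-optimizations."""
        base = dict(
            n1=50,
            q_candidates=150,
            ga=GaConfig(max_cycles=120, patience=60),
            n_shuffles=20,
            seq_null_shuffles=100,
            sample_size=40,
            min_class=20,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
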