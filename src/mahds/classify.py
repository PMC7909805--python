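"""Iterative discovery of sequence classes in a large collection.

Each round fits a PWM image to a random sample of the remaining
sequences, scores every remaining sequence against the fitted matrix,
and assigns those whose Z (against a per-sequence shuffle null scored
with the same fixed matrix — no re-optimization) exceeds the class
gate Z0 = 5.  Assigned sequences are removed and the procedure repeats
until a round yields fewer than `min_class` members; the undersized
class is still reported, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import DpConfig, pwm_score
from .config import RunConfig
from .pipeline import fit_sequence_set, fuse, refined_stack_pwm
from .pwm import DinucPWM
from .sequences import EncodedSequence, shuffle_sequence
from .significance import ZResult, z_score

__all__ = ["ClassModel", "score_sequence_against_model", "sequence_z",
           "classify_sequences"]


@dataclass
class ClassModel:
    model_matrix: DinucPWM
    members: list[int]           # indices into the original collection
    member_z: list[float]
    iteration: int
    undersized: bool = False


def score_sequence_against_model(seq: EncodedSequence, model: DinucPWM,
                                 dp_cfg: DpConfig | None = None) -> float:
    """Terminal DP score of a single sequence against the fixed matrix."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return pwm_score(seq.codes, model, 1, dp_cfg or DpConfig())


def sequence_z(seq: EncodedSequence, model: DinucPWM,
               n_shuffles: int = 1000, dp_cfg: DpConfig | None = None,
               seed=None) -> ZResult:
    """Z of one sequence against its own shuffles, all scored with the
    same fixed matrix (no re-optimization)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    dp_cfg = dp_cfg or DpConfig()
    observed = score_sequence_against_model(seq, model, dp_cfg)
    null = np.array([
        score_sequence_against_model(shuffle_sequence(seq, rng), model,
                                     dp_cfg)
        for _ in range(n_shuffles)
    ])
    return z_score(observed, float(null.mean()),
                   float(null.var(ddof=1)), n_null=n_shuffles)


def classify_sequences(collection: list[EncodedSequence],
                       cfg: RunConfig | None = None,
                       profile_length: int | None = None,
                       seed=None, max_iterations: int = 100,
                       undersized_grace: int = 1
                       ) -> tuple[list[ClassModel], list[int]]:
    """Greedy iterative classification of a fixed-length collection.

    Returns the ordered class models and the indices left unassigned.
    Sequences must be within 5% of the profile length; sequences used
    to build a round's model are rescored and gated like all others.
    `undersized_grace` is the number of *consecutive* undersized
    classes tolerated before stopping: 1 stops at the first undersized
    class; a value of 2 reproduces the behavior of continuing past an
    isolated small class when the next one is large again.
    """
    cfg = cfg or RunConfig()
    if not collection:
        raise ValueError("empty collection")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    m = profile_length or int(round(float(np.mean(
        [len(s) for s in collection]))))
    for s in collection:
        if abs(len(s) - m) > 0.05 * m:
            raise ValueError(
                f"sequence {s.name!r} length {len(s)} deviates more than "
                f"5% from the profile length {m}")
    dp_cfg = DpConfig(del_penalty=cfg.del_penalty,
                      use_context=cfg.use_context)

    remaining = list(range(len(collection)))
    classes: list[ClassModel] = []
    consecutive_undersized = 0
    for iteration in range(1, max_iterations + 1):
        if not remaining:
            break
        take = min(cfg.sample_size, len(remaining))
        sample_idx = rng.choice(len(remaining), size=take, replace=False)
        sample = [collection[remaining[i]] for i in sample_idx]
        codes, lengths, _, N = fuse(sample, m)
        outcome = fit_sequence_set(codes, lengths, m, N, cfg, rng)
        model = outcome.best_pwm

        def gate(mat: DinucPWM) -> tuple[list[int], list[float]]:
            hit, hit_z = [], []
            for idx in remaining:
                zr = sequence_z(collection[idx], mat,
                                cfg.seq_null_shuffles, dp_cfg, rng)
                if zr.z > cfg.z0_class:
                    hit.append(idx)
                    hit_z.append(zr.z)
            return hit, hit_z

        members, member_z = gate(model)
        # purification: rebuild the image from the members found and
        # re-gate, so the stored matrix is the image of the class
        # itself rather than of the mixed sample
        for _ in range(cfg.class_refit_rounds):
            if len(members) < 2:
                break
            mem_seqs = [collection[i] for i in members]
            mcodes, mlengths, _, mN = fuse(mem_seqs, m)
            model = refined_stack_pwm(mcodes, mlengths, m, mN,
                                      cfg.r0_coef * m, cfg.k0, dp_cfg)
            members, member_z = gate(model)
        undersized = len(members) < cfg.min_class
        classes.append(ClassModel(model_matrix=model,
                                  members=members, member_z=member_z,
                                  iteration=iteration,
                                  undersized=undersized))
        member_set = set(members)
        remaining = [i for i in remaining if i not in member_set]
        consecutive_undersized = consecutive_undersized + 1 if undersized \
            else 0
        if consecutive_undersized >= undersized_grace:
            break
    return classes, remaining
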