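"""Synthetic homolog families with exactly controlled identity/similarity.

Each generated pair partitions positions into the three classes a column of
a gap-free alignment can fall in — identical, similar-but-not-identical
(a within-group substitution) and not similar — with class sizes fixed by
half-up rounding of the targets times the length. Scoring a generated pair
(default model, shortest-sequence denominator) therefore recovers the
rounded targets exactly, which makes every downstream stage testable
without real sequences.

The generator is deliberately not an evolutionary simulator: there are no
indels, no substitution-rate matrices, and only member-versus-seed targets
are guaranteed in a family (member-versus-member homology is emergent,
since fixing all pairwise targets simultaneously is over-constrained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import STANDARD_RESIDUES
from .homology_engine import SimilarityModel, default_similarity_model
from .sequence_io import SequenceRecord, ValidationError

__all__ = [
    "FamilySpec",
    "expected_counts",
    "generate_pair",
    "generate_family",
]

_RESIDUES = sorted(STANDARD_RESIDUES)


def expected_counts(length: int, target_identity: float,
                    target_similarity: float) -> tuple[int, int, int]:
    """(n_identical, n_similar_only, n_dissimilar) a generated pair will have.

    Class sizes come from half-up rounding: the similar-only count is
    round((S - I) * length), the dissimilar count round((1 - S) * length),
    and the identical count is the remainder. These are the exact values
    scoring recovers, stated here so tests can derive them independently.
    """
    n_sim_only = _round_half_up((target_similarity - target_identity) * length)
    n_dissim = _round_half_up((1.0 - target_similarity) * length)
    n_ident = length - n_sim_only - n_dissim
    if n_ident < 0:
        raise ValueError(
            f"rounded class sizes exceed length {length}: the targets "
            f"({target_identity}, {target_similarity}) are inconsistent "
            f"at this length"
        )
    return n_ident, n_sim_only, n_dissim


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _check_targets(target_identity: float, target_similarity: float) -> None:
    if not 0.0 <= target_identity <= target_similarity <= 1.0:
        raise ValueError(
            f"targets must satisfy 0 <= identity <= similarity <= 1; got "
            f"identity={target_identity}, similarity={target_similarity}"
        )


def _random_seed_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_RESIDUES, size=length))


def _seed_with_grouped(length: int, min_grouped: int,
                       rng: np.random.Generator,
                       model: SimilarityModel) -> str:
    """A random seed sequence with at least *min_grouped* grouped residues.

    Within-group substitutions need grouped residues to act on, so when the
    similar-but-not-identical class is large the uniform draw is topped up
    by converting randomly chosen ungrouped positions to grouped residues.
    """
    if min_grouped > length:
        raise ValueError("more within-group substitutions requested than "
                         "sequence positions")
    grouped_residues = sorted(r for r in _RESIDUES
                              if model.group_of(r) is not None)
    seq = list(_random_seed_sequence(length, rng))
    ungrouped_pos = [i for i, r in enumerate(seq)
                     if model.group_of(r) is None]
    deficit = min_grouped - (length - len(ungrouped_pos))
    if deficit > 0:
        idx = rng.choice(len(ungrouped_pos), size=deficit, replace=False)
        for i in idx:
            pos = ungrouped_pos[i]
            seq[pos] = grouped_residues[rng.integers(len(grouped_residues))]
    return "".join(seq)


def _mutate_from_seed(seed_seq: str, target_identity: float,
                      target_similarity: float, rng: np.random.Generator,
                      model: SimilarityModel) -> str:
    length = len(seed_seq)
    _, n_sim_only, n_dissim = expected_counts(length, target_identity,
                                              target_similarity)
    grouped_pos = [i for i, r in enumerate(seed_seq)
                   if model.group_of(r) is not None]
    if len(grouped_pos) < n_sim_only:
        raise ValueError("seed sequence has too few grouped residues")
    sim_pos = rng.choice(len(grouped_pos), size=n_sim_only, replace=False) \
        if n_sim_only else np.empty(0, dtype=int)
    sim_pos = {grouped_pos[i] for i in sim_pos}
    remaining = [i for i in range(length) if i not in sim_pos]
    dis_idx = rng.choice(len(remaining), size=n_dissim, replace=False) \
        if n_dissim else np.empty(0, dtype=int)
    dis_pos = {remaining[i] for i in dis_idx}

    out = list(seed_seq)
    for i in sorted(sim_pos):
        group = model.group_of(seed_seq[i])
        assert group is not None
        choices = sorted(group - {seed_seq[i]})
        out[i] = choices[rng.integers(len(choices))]
    for i in sorted(dis_pos):
        original = seed_seq[i]
        group = model.group_of(original) or frozenset()
        choices = [r for r in _RESIDUES if r != original and r not in group]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_pair(length: int, target_identity: float,
                  target_similarity: float, seed: int,
                  ids: tuple[str, str] = ("synthetic_1", "synthetic_2"),
                  ) -> tuple[SequenceRecord, SequenceRecord]:
    """A gap-free sequence pair hitting the rounded (I, S) targets exactly.

    The second sequence is the first with exactly
    ``round((S - I) * length)`` within-group substitutions and
    ``round((1 - S) * length)`` out-of-group substitutions. Within-group
    substitutions require grouped seed residues at the chosen positions, so
    the seed sequence is drawn with at least that many grouped residues.
    Fully deterministic in *seed*.
    """
    _check_targets(target_identity, target_similarity)
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    model = default_similarity_model()
    rng = np.random.default_rng(seed)
    _, n_sim_only, _ = expected_counts(length, target_identity,
                                       target_similarity)
    seed_seq = _seed_with_grouped(length, n_sim_only, rng, model)
    derived = _mutate_from_seed(seed_seq, target_identity, target_similarity,
                                rng, model)
    return (SequenceRecord(id=ids[0], seq=seed_seq),
            SequenceRecord(id=ids[1], seq=derived))


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for a synthetic family of homologs.

    ``pair_targets`` fixes each member's (identity, similarity) against the
    first (seed) sequence; alternatively ``identity_range`` samples member
    identities uniformly, with similarity drawn between the identity and
    ``min(1, identity + max_similarity_margin)``.
    """

    n: int
    length: int
    seed: int
    pair_targets: tuple[tuple[float, float], ...] | None = None
    identity_range: tuple[float, float] = (0.2, 0.9)
    max_similarity_margin: float = 0.3
    name: str = "synthetic_family"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"a family needs n >= 2 sequences, "
                                  f"got n={self.n}")
        if self.length < 1:
            raise ValidationError("length must be >= 1")
        if self.pair_targets is not None:
            targets = tuple(tuple(t) for t in self.pair_targets)
            object.__setattr__(self, "pair_targets", targets)
            if len(targets) != self.n - 1:
                raise ValidationError(
                    f"pair_targets must list one (I, S) per non-seed member: "
                    f"expected {self.n - 1}, got {len(targets)}"
                )
            for ti, ts in targets:
                _check_targets(ti, ts)
        lo, hi = self.identity_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError(f"invalid identity_range: "
                                  f"{self.identity_range}")


def generate_family(spec: FamilySpec) -> list[SequenceRecord]:
    """n sequences derived from one seed sequence, reproducible from seed.

    The first record is the seed; each other member hits its (identity,
    similarity) target against the seed exactly (after rounding to counts).
    """
    model = default_similarity_model()
    rng = np.random.default_rng(spec.seed)
    if spec.pair_targets is not None:
        targets = list(spec.pair_targets)
    else:
        lo, hi = spec.identity_range
        targets = []
        for _ in range(spec.n - 1):
            ti = float(rng.uniform(lo, hi))
            ts = float(rng.uniform(ti, min(1.0, ti +
                                           spec.max_similarity_margin)))
            targets.append((ti, ts))

    max_sim_only = max(
        expected_counts(spec.length, ti, ts)[1] for ti, ts in targets
    )
    try:
        seed_seq = _seed_with_grouped(spec.length, max_sim_only, rng, model)
    except ValueError as exc:  # pragma: no cover - guarded by FamilySpec
        raise ValidationError(f"infeasible pair_targets: {exc}") from exc

    records = [SequenceRecord(id=f"{spec.name}_01", seq=seed_seq)]
    for i, (ti, ts) in enumerate(targets, start=2):
        derived = _mutate_from_seed(seed_seq, ti, ts, rng, model)
        records.append(SequenceRecord(id=f"{spec.name}_{i:02d}", seq=derived))
    return records
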