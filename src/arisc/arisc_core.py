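"""The A-RISC index, risk categories, family matrices and summaries.

The A-RISC index (Allergens' Relative Identity, Similarity and
Cross-reactivity) for a pair of homologous proteins with identity I and
similarity S (fractions, S >= I) is::

    A-RISC = I + w * (S - I)          (default w = 0.5, i.e. (I + S) / 2)

The weight w is the assumed probability that a similar-but-not-identical
residue participates in binding a cross-reactive antibody; w = 0.5 is the
standard assumption. The index estimates the fraction of residues able to
support cross-reactive antibody binding and maps onto four risk categories:

    high         A-RISC >= 0.75
    medium-high  0.75 > A-RISC >= 0.50
    medium-low   0.50 > A-RISC >= 0.25
    low          A-RISC < 0.25

Boundaries are closed from below (0.75 is high). Categorization always uses
the unrounded index; rounding to two decimals happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

from . import homology_engine as he
from .sequence_io import Alignment, SequenceRecord, ValidationError

__all__ = [
    "Category",
    "CATEGORIES",
    "HomologyScore",
    "FamilyMatrix",
    "FamilySummary",
    "arisc_index",
    "categorize",
    "build_family_matrix",
    "summarize_family",
    "rank_families",
]

Category = Literal["high", "medium-high", "medium-low", "low"]
CATEGORIES: tuple[Category, ...] = ("high", "medium-high", "medium-low", "low")


def arisc_index(I: float, S: float, w: float = 0.5) -> float:
    """A-RISC index I + w*(S - I) for identity I and similarity S.

    Requires 0 <= I <= S <= 1 (similar includes identical) and w in [0, 1].
    At the default w = 0.5 this is the arithmetic mean (I + S) / 2; the
    result always lies in [I, S].
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"participation weight w must be in [0, 1], got {w}")
    if not 0.0 <= I <= 1.0 or not 0.0 <= S <= 1.0:
        raise ValueError(f"I and S must be fractions in [0, 1], got {I}, {S}")
    if I > S:
        raise ValueError(
            f"identity {I} exceeds similarity {S}: similar includes identical"
        )
    return I + w * (S - I)


def categorize(arisc: float) -> Category:
    """Map an A-RISC value to its cross-reactivity risk category."""
    if not 0.0 <= arisc <= 1.0:
        raise ValueError(f"A-RISC value out of [0, 1]: {arisc}")
    if arisc >= 0.75:
        return "high"
    if arisc >= 0.50:
        return "medium-high"
    if arisc >= 0.25:
        return "medium-low"
    return "low"


@dataclass(frozen=True)
class HomologyScore:
    """Identity, similarity, A-RISC and category for one sequence pair."""

    I: float
    S: float
    arisc: float
    category: Category
    counts: he.PairCounts
    denominator_convention: str = "shortest"

    def __post_init__(self) -> None:
        if self.I > self.S:
            raise ValueError("identity exceeds similarity")


def _self_score(record_len: int,
                denominator: str = "shortest") -> HomologyScore:
    counts = he.PairCounts(n_identical=record_len, n_similar=record_len,
                           n_columns=record_len,
                           len1=record_len, len2=record_len)
    return HomologyScore(I=1.0, S=1.0, arisc=1.0, category="high",
                         counts=counts,
                         denominator_convention=denominator)


@dataclass
class FamilyMatrix:
    """Symmetric table of pair scores over all members of one family."""

    ids: list[str]
    scores: dict[tuple[str, str], HomologyScore]
    mode: Literal["msa", "pairwise"]
    params: dict

    def get(self, id1: str, id2: str) -> HomologyScore:
        if (id1, id2) in self.scores:
            return self.scores[(id1, id2)]
        if (id2, id1) in self.scores:
            return self.scores[(id2, id1)]
        raise KeyError(f"no score for pair ({id1!r}, {id2!r})")

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered off-diagonal pairs, in id order."""
        out = []
        for i, a in enumerate(self.ids):
            for b in self.ids[i + 1:]:
                out.append((a, b))
        return out

    @property
    def n(self) -> int:
        return len(self.ids)


InputSeqs = Union[Sequence[SequenceRecord], Alignment]


def build_family_matrix(input: InputSeqs,
                        mode: Literal["msa", "pairwise"] = "msa",
                        model: he.SimilarityModel | None = None,
                        denominator: he.DenominatorConvention = "shortest",
                        w: float = 0.5,
                        align_params: he.AlignParams | None = None,
                        ) -> FamilyMatrix:
    """Score every unordered pair of family members.

    ``mode="msa"`` extracts each pair from a supplied multiple alignment
    (the workflow that matches Clustal-Omega-based analyses);
    ``mode="pairwise"`` globally aligns each pair internally from unaligned
    records. The diagonal holds the trivial self-score (I = S = A-RISC = 1).
    """
    if model is None:
        model = he.default_similarity_model()

    if mode == "msa":
        if not isinstance(input, Alignment):
            raise ValidationError(
                "mode='msa' requires an Alignment input; got unaligned "
                "sequences (use mode='pairwise' or supply an MSA)"
            )
        ids = list(input.ids)
        if len(ids) < 2:
            raise ValidationError("a family matrix needs >= 2 sequences")
        pair_of = {
            (a, b): he.extract_pair_from_msa(input, a, b)
            for i, a in enumerate(ids) for b in ids[i + 1:]
        }
        lengths = {rec.id: len(rec) for rec in input.degap()}
    elif mode == "pairwise":
        if isinstance(input, Alignment):
            records = input.degap()
        else:
            records = list(input)
        if len(records) < 2:
            raise ValidationError("a family matrix needs >= 2 sequences")
        ids = [rec.id for rec in records]
        by_id = dict(zip(ids, records))
        pair_of = {
            (a, b): he.align_pair_global(by_id[a], by_id[b],
                                         params=align_params)
            for i, a in enumerate(ids) for b in ids[i + 1:]
        }
        lengths = {rid: len(rec) for rid, rec in by_id.items()}
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    scores = {
        key: he.score_pair(pair, model, denominator=denominator, w=w)
        for key, pair in pair_of.items()
    }
    for rid in ids:
        scores[(rid, rid)] = _self_score(lengths[rid], denominator)

    return FamilyMatrix(
        ids=ids, scores=scores, mode=mode,
        params={"denominator": denominator, "w": w, "model": model.name},
    )


@dataclass(frozen=True)
class FamilySummary:
    """Per-family means and ranges over all unordered off-diagonal pairs."""

    family_name: str
    n: int
    mean_identity: float
    mean_similarity: float
    mean_arisc: float
    min_identity: float
    max_identity: float
    min_similarity: float
    max_similarity: float
    min_arisc: float
    max_arisc: float
    n_pairs: int = field(default=0)

    def as_dict(self) -> dict:
        """Summary row with identity/similarity echoed as integer percent."""
        return {
            "family": self.family_name,
            "n_sequences": self.n,
            "n_pairs": self.n_pairs,
            "mean_identity_pct": round(100 * self.mean_identity),
            "mean_similarity_pct": round(100 * self.mean_similarity),
            "identity_range_pct": [round(100 * self.min_identity),
                                   round(100 * self.max_identity)],
            "similarity_range_pct": [round(100 * self.min_similarity),
                                     round(100 * self.max_similarity)],
            "mean_arisc": round(self.mean_arisc, 2),
            "arisc_range": [round(self.min_arisc, 2),
                            round(self.max_arisc, 2)],
        }


def summarize_family(matrix: FamilyMatrix,
                     family_name: str = "family") -> FamilySummary:
    """Mean and range of I, S and A-RISC over off-diagonal pairs only.

    Self-comparisons are excluded; with n sequences the statistics run over
    exactly n*(n-1)/2 unordered pairs.
    """
    pairs = matrix.pairs()
    if not pairs:
        raise ValidationError("family summary needs >= 2 sequences")
    Is = [matrix.get(a, b).I for a, b in pairs]
    Ss = [matrix.get(a, b).S for a, b in pairs]
    As = [matrix.get(a, b).arisc for a, b in pairs]
    return FamilySummary(
        family_name=family_name, n=matrix.n, n_pairs=len(pairs),
        mean_identity=sum(Is) / len(Is),
        mean_similarity=sum(Ss) / len(Ss),
        mean_arisc=sum(As) / len(As),
        min_identity=min(Is), max_identity=max(Is),
        min_similarity=min(Ss), max_similarity=max(Ss),
        min_arisc=min(As), max_arisc=max(As),
    )


def rank_families(summaries: Sequence[FamilySummary]) -> list[FamilySummary]:
    """Families ordered by decreasing cross-reactivity propensity.

    Propensity is the family's mean A-RISC; ties break alphabetically by
    family name so the ranking is deterministic.
    """
    if not summaries:
        raise ValidationError("rank_families needs >= 1 summary")
    return sorted(summaries, key=lambda s: (-s.mean_arisc, s.family_name))
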