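"""Similarity-group model and pairwise identity/similarity counting.

Two residues are *similar* when they are identical standard residues or
when both belong to the same physicochemical group. The default model uses
the six groups of the SIAS web server: aromatic (F, Y, W), aliphatic
(I, L, V), positively charged (H, K, R), negatively charged (D, E), small
with a hydroxyl group (S, T) and neutral polar (N, Q); the remaining five
residues (A, C, G, M, P) belong to no group and are similar only to
themselves.

Identity I and similarity S for one aligned pair are fractions of a chosen
denominator — by default the length of the shorter sequence — so that
``similar`` counts include ``identical`` and S >= I always holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Literal

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import STANDARD_RESIDUES
from .sequence_io import Alignment, SequenceRecord, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .arisc_core import HomologyScore

__all__ = [
    "SimilarityModel",
    "AlignedPair",
    "PairCounts",
    "AlignParams",
    "default_similarity_model",
    "load_similarity_model",
    "are_similar",
    "count_pair",
    "score_pair",
    "align_pair_global",
    "extract_pair_from_msa",
]

DenominatorConvention = Literal["shortest", "longest", "mean", "alignment"]

_DEFAULT_GROUPS = (
    frozenset("FYW"),   # aromatic
    frozenset("ILV"),   # aliphatic
    frozenset("HKR"),   # positively charged
    frozenset("DE"),    # negatively charged
    frozenset("ST"),    # small with hydroxyl group
    frozenset("NQ"),    # neutral polar
)


@dataclass(frozen=True)
class SimilarityModel:
    """Disjoint residue groups defining which substitutions count as similar."""

    groups: tuple[frozenset[str], ...]
    name: str = "custom"
    _group_of: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        groups = tuple(frozenset(r.upper() for r in g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        group_of: dict[str, int] = {}
        for i, g in enumerate(groups):
            if len(g) < 2:
                raise ValueError(
                    f"similarity group {sorted(g)} has fewer than 2 members"
                )
            if not g <= STANDARD_RESIDUES:
                bad = sorted(g - STANDARD_RESIDUES)
                raise ValueError(
                    f"similarity group contains non-standard residues: {bad}"
                )
            for r in g:
                if r in group_of:
                    raise ValueError(
                        f"residue {r} appears in more than one group"
                    )
                group_of[r] = i
        object.__setattr__(self, "_group_of", group_of)

    def group_of(self, residue: str) -> frozenset[str] | None:
        """The group containing *residue*, or None if it is ungrouped."""
        idx = self._group_of.get(residue.upper())
        return None if idx is None else self.groups[idx]


def default_similarity_model() -> SimilarityModel:
    """The six SIAS similarity groups; A, C, G, M, P remain ungrouped."""
    return SimilarityModel(groups=_DEFAULT_GROUPS, name="sias-default")


def load_similarity_model(path: str | Path) -> SimilarityModel:
    """Load a similarity model from a YAML/JSON file.

    Expected keys: ``name`` (optional) and ``groups``, a list of residue
    strings or lists, e.g. ``groups: [FYW, ILV, HKR, DE, ST, NQ]``.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} \
        else json.loads(text)
    groups = tuple(frozenset("".join(g)) for g in data["groups"])
    return SimilarityModel(groups=groups, name=data.get("name", path.stem))


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped rows for one sequence pair.

    Columns gapped in both rows carry no information and are removed at
    construction, so ``len(row1)`` is the number of comparable-or-gapped
    columns.
    """

    id1: str
    id2: str
    row1: str
    row2: str
    provenance: Literal["msa-extracted", "pairwise-aligned"] = "msa-extracted"

    def __post_init__(self) -> None:
        if len(self.row1) != len(self.row2):
            raise ValidationError(
                f"aligned rows differ in length: {len(self.row1)} vs "
                f"{len(self.row2)}"
            )
        r1 = self.row1.upper().replace(".", "-")
        r2 = self.row2.upper().replace(".", "-")
        kept1, kept2 = [], []
        for a, b in zip(r1, r2):
            if a == "-" and b == "-":
                continue
            kept1.append(a)
            kept2.append(b)
        if not kept1:
            raise ValidationError("aligned pair has no non-empty columns")
        object.__setattr__(self, "row1", "".join(kept1))
        object.__setattr__(self, "row2", "".join(kept2))

    def swapped(self) -> "AlignedPair":
        return AlignedPair(id1=self.id2, id2=self.id1,
                           row1=self.row2, row2=self.row1,
                           provenance=self.provenance)


@dataclass(frozen=True)
class PairCounts:
    """Raw column counts for one aligned pair; similar includes identical."""

    n_identical: int
    n_similar: int
    n_columns: int
    len1: int
    len2: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_identical <= self.n_similar <= min(self.len1,
                                                              self.len2):
            raise ValueError(
                f"inconsistent counts: identical={self.n_identical}, "
                f"similar={self.n_similar}, lengths=({self.len1}, {self.len2})"
            )


@dataclass(frozen=True)
class AlignParams:
    """Scoring for the internal global aligner (alignment-free input mode)."""

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must be <= gap_open")


def are_similar(model: SimilarityModel, a: str, b: str) -> bool:
    """True iff *a* and *b* are identical standard residues or share a group.

    Gap characters and ambiguity codes (X, B, Z, J, U, O) are never similar,
    not even to themselves: an unknown residue cannot support a claimed
    epitope-level match.
    """
    a, b = a.upper(), b.upper()
    if a == b:
        return a in STANDARD_RESIDUES
    ga = model.group_of(a)
    return ga is not None and b in ga


def count_pair(pair: AlignedPair, model: SimilarityModel) -> PairCounts:
    """Count identical and similar columns of an aligned pair.

    A column with a gap in either row counts toward neither identity nor
    similarity. Identity requires equal standard residues; similarity is
    identity or same-group membership per *model*.
    """
    n_ident = n_sim = 0
    for a, b in zip(pair.row1, pair.row2):
        if a == "-" or b == "-":
            continue
        if a == b and a in STANDARD_RESIDUES:
            n_ident += 1
            n_sim += 1
        elif are_similar(model, a, b):
            n_sim += 1
    return PairCounts(
        n_identical=n_ident,
        n_similar=n_sim,
        n_columns=len(pair.row1),
        len1=len(pair.row1.replace("-", "")),
        len2=len(pair.row2.replace("-", "")),
    )


def _denominator(counts: PairCounts, convention: str) -> float:
    if convention == "shortest":
        return min(counts.len1, counts.len2)
    if convention == "longest":
        return max(counts.len1, counts.len2)
    if convention == "mean":
        return (counts.len1 + counts.len2) / 2
    if convention == "alignment":
        return counts.n_columns
    raise ValueError(f"unknown denominator convention: {convention!r}")


def score_pair(pair: AlignedPair, model: SimilarityModel | None = None,
               denominator: DenominatorConvention = "shortest",
               w: float = 0.5) -> "HomologyScore":
    """Score one aligned pair: identity, similarity, A-RISC and category.

    *denominator* selects what I and S are fractions of: the shorter
    ungapped sequence (default), the longer one, their mean, or the number
    of alignment columns. *w* is the participation weight of
    similar-but-not-identical residues in the A-RISC index.
    """
    from .arisc_core import HomologyScore, arisc_index, categorize

    if model is None:
        model = default_similarity_model()
    counts = count_pair(pair, model)
    denom = _denominator(counts, denominator)
    I = counts.n_identical / denom
    S = counts.n_similar / denom
    a = arisc_index(I, S, w=w)
    return HomologyScore(I=I, S=S, arisc=a, category=categorize(a),
                         counts=counts, denominator_convention=denominator)


def _translate_for_matrix(seq: str, alphabet: str) -> str:
    # letters absent from the substitution matrix score as X (any residue)
    return "".join(ch if ch in alphabet else "X" for ch in seq)


def align_pair_global(a: SequenceRecord, b: SequenceRecord,
                      params: AlignParams | None = None) -> AlignedPair:
    """Optimal global alignment of two sequences with affine gap penalties.

    Uses the named substitution matrix (default BLOSUM62), gap open 10 and
    gap extend 0.5. Among co-optimal alignments the first of the aligner's
    deterministic enumeration is returned, so output is reproducible. Note
    this is an alignment-free convenience path; family analyses intended to
    match an MSA-based workflow should supply the MSA instead.
    """
    if params is None:
        params = AlignParams()
    matrix = substitution_matrices.load(params.substitution_matrix)
    alphabet = str(matrix.alphabet)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    s1 = _translate_for_matrix(a.seq, alphabet)
    s2 = _translate_for_matrix(b.seq, alphabet)
    aln = next(iter(aligner.align(s1, s2)))
    g1, g2 = str(aln[0]), str(aln[1])
    # restore original residues (translation was for scoring only)
    row1 = _restore_residues(g1, a.seq)
    row2 = _restore_residues(g2, b.seq)
    return AlignedPair(id1=a.id, id2=b.id, row1=row1, row2=row2,
                       provenance="pairwise-aligned")


def _restore_residues(gapped: str, original: str) -> str:
    out, i = [], 0
    for ch in gapped:
        if ch == "-":
            out.append("-")
        else:
            out.append(original[i])
            i += 1
    return "".join(out)


def extract_pair_from_msa(aln: Alignment, id1: str, id2: str) -> AlignedPair:
    """The two named rows of an MSA, with gap-in-both columns removed."""
    for rid in (id1, id2):
        if rid not in aln.ids:
            raise KeyError(f"id not found in alignment: {rid!r}")
    return AlignedPair(id1=id1, id2=id2,
                       row1=aln.row(id1), row2=aln.row(id2),
                       provenance="msa-extracted")
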