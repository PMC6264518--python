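"""Reading and writing sequence, alignment and matrix files.

Unaligned protein input is plain FASTA; alignments come either as aligned
FASTA or Clustal (the output format of Clustal Omega, the aligner typically
used to build per-family MSAs). Result matrices are written as TSV.

FASTA headers are kept whole (trimmed of surrounding whitespace) so that
allergen nomenclature identifiers containing spaces, e.g. ``Der p 1.0101``,
survive the round trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Literal

from Bio import AlignIO, SeqIO

from .alphabet import ALLOWED_RESIDUES, GAP_CHARS

if TYPE_CHECKING:  # pragma: no cover
    from .arisc_core import FamilyMatrix

__all__ = [
    "SequenceRecord",
    "Alignment",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_matrix",
]


class ValidationError(ValueError):
    """Raised when an input file violates a contract (alphabet, ids, shape)."""


def _normalize_id(raw: str) -> str:
    return re.sub(r"\s+", " ", raw.strip())


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with its identifier.

    The sequence is uppercased at construction and must contain only the 20
    standard residues plus the ambiguity codes X, B, Z, J, U, O. Gap
    characters are rejected: gaps belong to alignments, not sequences.
    """

    id: str
    seq: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise ValidationError("sequence record has an empty identifier")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.seq, start=1):
            if ch in GAP_CHARS:
                raise ValidationError(
                    f"gap character in unaligned sequence at record "
                    f"{self.id!r}, position {pos}"
                )
            if ch not in ALLOWED_RESIDUES:
                raise ValidationError(
                    f"record {self.id!r}: invalid amino-acid character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: ordered (id, gapped-seq) rows.

    All rows share the same width; the ``.`` gap dialect is normalized to
    ``-`` at construction. Degapping any row must yield a valid
    :class:`SequenceRecord` sequence.
    """

    records: tuple[tuple[str, str], ...]
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment has no rows")
        rows = []
        for rid, row in self.records:
            rows.append((rid, row.upper().replace(".", "-")))
        object.__setattr__(self, "records", tuple(rows))
        widths = {len(row) for _, row in self.records}
        if len(widths) != 1:
            a, b = sorted(widths)[:2]
            raise ValidationError(
                f"ragged alignment: rows of length {a} and {b} found"
            )
        width = widths.pop()
        if width < 1:
            raise ValidationError("alignment width must be >= 1")
        object.__setattr__(self, "width", width)
        seen: set[str] = set()
        for rid, row in self.records:
            key = _normalize_id(rid)
            if key in seen:
                raise ValidationError(f"duplicate id in alignment: {rid!r}")
            seen.add(key)
            # validates the degapped sequence (alphabet, non-emptiness)
            SequenceRecord(id=rid, seq=row.replace("-", ""))

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, row in self.records:
            if r == rid:
                return row
        raise KeyError(f"id not found in alignment: {rid!r}")

    def degap(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(id=rid, seq=row.replace("-", ""))
            for rid, row in self.records
        ]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned protein FASTA into a list of :class:`SequenceRecord`.

    The full header line (up to the newline, trimmed) is the identifier.
    Terminal ``*`` stop characters are stripped; sequences are uppercased.
    Duplicate identifiers (after whitespace normalization) are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.description.strip()
        key = _normalize_id(rid)
        if key in seen:
            raise ValidationError(f"duplicate sequence id: {rid!r}")
        seen.add(key)
        seq = str(rec.seq).rstrip("*")
        records.append(SequenceRecord(id=rid, seq=seq))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, one full-header line per record."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


AlignmentFormat = Literal["aligned-fasta", "clustal", "auto"]


def _sniff_format(path: Path) -> str:
    with path.open() as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.upper().startswith("CLUSTAL"):
                return "clustal"
            if stripped.startswith(">"):
                return "aligned-fasta"
            break
    raise ValidationError(
        f"cannot determine alignment format of {path}: expected a CLUSTAL "
        f"header or a '>' record"
    )


def read_alignment(path: str | Path,
                   format: AlignmentFormat = "auto") -> Alignment:
    """Read a protein MSA from aligned FASTA or Clustal format.

    In ``auto`` mode the format is sniffed from the first non-blank line.
    Clustal blocks for the same id are concatenated; both ``-`` and ``.``
    gaps are accepted and normalized to ``-``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _sniff_format(path)  # type: ignore[assignment]
    if format == "aligned-fasta":
        rows = [(rec.description.strip(), str(rec.seq))
                for rec in SeqIO.parse(str(path), "fasta")]
        if not rows:
            raise ValidationError(f"no alignment records found in {path}")
        return Alignment(records=tuple(rows))
    if format == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise ValidationError(f"cannot parse Clustal file {path}: {exc}")
        return Alignment(
            records=tuple((rec.id, str(rec.seq)) for rec in aln)
        )
    raise ValidationError(f"unknown alignment format: {format!r}")


_MATRIX_FIELDS = ("identity", "similarity", "arisc", "category")


def write_matrix(matrix: "FamilyMatrix", path: str | Path,
                 field: str) -> None:
    """Write one field of a family pair matrix as a square TSV table.

    Identity and similarity are written as percentages with one decimal,
    A-RISC with two decimals, category as its name. Row/column order is the
    matrix's id order; the diagonal is the self-comparison
    (100.0 / 100.0 / 1.00 / high).
    """
    if field not in _MATRIX_FIELDS:
        raise ValueError(
            f"unknown matrix field {field!r}; expected one of {_MATRIX_FIELDS}"
        )
    path = Path(path)

    def fmt(score) -> str:
        if field == "identity":
            return f"{100 * score.I:.1f}"
        if field == "similarity":
            return f"{100 * score.S:.1f}"
        if field == "arisc":
            return f"{score.arisc:.2f}"
        return score.category

    with path.open("w") as fh:
        fh.write("\t".join([""] + list(matrix.ids)) + "\n")
        for rid in matrix.ids:
            cells = [fmt(matrix.get(rid, cid)) for cid in matrix.ids]
            fh.write("\t".join([rid] + cells) + "\n")
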