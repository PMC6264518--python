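"""Amino-acid alphabet constants shared across the package."""

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes accepted on input but never scored as
#: identical or similar: X (any), B (D/N), Z (E/Q), J (I/L),
#: U (selenocysteine), O (pyrrolysine).
AMBIGUITY_CODES = frozenset("XBZJUO")

ALLOWED_RESIDUES = STANDARD_RESIDUES | AMBIGUITY_CODES

GAP_CHARS = frozenset("-.")
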