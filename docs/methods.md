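# Methods

## Scoring model

A pair of aligned protein sequences is compared column by column. A column
is **identical** when both residues are the same standard amino acid,
**similar** when the residues are identical or belong to the same
physicochemical group, and **not similar** otherwise. The similarity
groups of the default model are aromatic {F, Y, W}, aliphatic {I, L, V},
positively charged {H, K, R}, negatively charged {D, E}, small with a
hydroxyl group {S, T} and neutral polar {N, Q}; the remaining five
residues (A, C, G, M, P) belong to no group, so they are similar only to
themselves. This is the grouping used by the SIAS identity/similarity
server and is deliberately more conservative than, e.g., the Clustal
consensus groups; an alternative model can be supplied as a YAML/JSON file
(`load_similarity_model`) with disjoint groups of ≥ 2 standard residues.

Identity *I* and similarity *S* are the identical and similar column
counts divided by a **denominator convention**:

- `shortest` (default): length of the shorter ungapped sequence,
- `longest`, `mean`: the longer length or the mean of the two,
- `alignment`: number of alignment columns (after removing columns gapped
  in both rows).

The A-RISC index is `I + w·(S − I)` with participation weight `w = 0.5`
by default, i.e. the arithmetic mean of *I* and *S*. The weight encodes
the assumption that a similar-but-not-identical residue supports binding
of a cross-reactive antibody in half of the cases; it is exposed as a
parameter (`w ∈ [0, 1]`) because that 50% is an assumption, not a
measurement, but 0.5 is the value used throughout. Categories: high
(A-RISC ≥ 0.75), medium-high (≥ 0.50), medium-low (≥ 0.25), low (< 0.25);
boundaries are closed from below and categorization always uses the
unrounded value (rounding 0.7468 to 0.75 first would misclassify it).
The model uses primary structure only: no secondary/quaternary structure,
no posttranslational modifications, and it presumes family members share
an overall fold.

### Gap and ambiguity handling

Columns gapped in both rows are removed before any counting. Columns with
a gap opposite a residue count toward no class (they still count as
alignment columns for the `alignment` denominator). Ambiguity codes
(X, B, Z, J, U, O) are accepted on input — real database entries contain
them — but are never identical or similar, not even to themselves, while
still counting toward ungapped sequence length: an unknown residue cannot
support an epitope-level match claim, so scoring is conservative.

## Alignment sources

The intended workflow scores pairs extracted from a per-family multiple
sequence alignment built externally (typically Clustal Omega), which is
how published family analyses are produced. For unaligned input the
package also offers an internal global pairwise aligner (BLOSUM62, gap
open 10, gap extend 0.5 — classic global-alignment defaults) with
deterministic tie-breaking (the first alignment of the aligner's
deterministic enumeration of co-optima). Pairwise mode is convenient but
alignment-dependent; the CLI logs a warning when it is used. Residues
absent from the substitution matrix (U, O, J) are scored as X during
alignment but preserved in the output rows.

## Family statistics

A family matrix scores every unordered pair once; the diagonal holds the
trivial self-score (I = S = A-RISC = 1) and is excluded from all
statistics. Family means and ranges run over exactly n(n−1)/2 off-diagonal
pairs — including the diagonal would inflate every mean toward 1. Families
are ranked by descending mean A-RISC with alphabetical tie-break. Display
convention: identity/similarity as integer percent in summaries and one
decimal in matrix TSVs, A-RISC to two decimals; all internal computation
is unrounded.

## Synthetic data generator

The generator emulates the position-class structure the scoring model
sees: a derived sequence is the seed sequence with exactly
`round((S − I)·L)` within-group substitutions and `round((1 − S)·L)`
out-of-group substitutions (half-up rounding; the identical class is the
remainder, and target combinations whose rounded classes exceed L are
rejected as inconsistent). Within-group substitutions are placed only on
grouped seed residues, so the uniform-random seed sequence is topped up
with grouped residues when the similar-only class demands more than it
drew; out-of-group substitutions reject same-residue and same-group draws.
Scoring a generated pair (gap-free, shortest denominator, default model)
therefore recovers the rounded targets *exactly*, which is what the
round-trip tests assert.

A family derives n−1 members from one seed sequence. Only member-versus-
seed targets are guaranteed; member-versus-member homology is emergent,
because fixing all pairwise targets simultaneously is over-constrained.
When targets are sampled rather than given, member identities are uniform
on [0.2, 0.9] — spanning all four risk categories, as real allergen
families do — with similarity drawn between the identity and
identity + 0.3 (capped at 1), a margin typical of the published
identity/similarity gaps in allergen families. Everything is deterministic
in the spec's seed.

What the generator does **not** emulate: indels (generated families are
gap-free and equal-length; gap handling is tested with hand-built aligned
pairs), realistic substitution processes (no rate matrices, no
phylogeny), ambiguity codes, and length variation. Passing tests on
synthetic families therefore validate the arithmetic and plumbing, not
alignment quality on real, indel-rich families — for those, the MSA
supplied by the user determines the comparison columns.

## Visualization

Heatmap cells are colored by A-RISC with a linear colormap anchored at the
category boundaries (1.0 red, 0.75 orange, 0.50 yellow, 0.25
yellow-green, 0.0 dark green), so the legend text matches the rendered
bands; the published figures do not state their exact scale, so anchor
semantics were chosen over pixel fidelity. Diagonal self-comparison cells
are hatched since self-comparison is not a cross-reactivity claim.
Profile plots show each member's identity/similarity (percent) and A-RISC
against one reference with dashed guides at 75/50/25% (0.75/0.50/0.25),
sorted descending by value with alphabetical tie-break (input order
selectable). Both renderers expose data-export hooks (`heatmap_data`,
`profile_data`) returning exactly what is plotted, so tests assert on
data, not pixels; SVG output is byte-stable (fixed hash salt, no embedded
date).

## Numerical and design choices

- Denominator convention defaults to `shortest` and is configurable; when
  reproducing published values the convention that matches should be
  recorded, since the upstream server's default is not documented.
- FASTA identifiers are the full header line (trimmed), preserving
  allergen names with spaces ("Der p 1.0101"); ids must be unique after
  whitespace normalization.
- Matrix TSVs keep input order (no silent re-sorting) for reproducible
  diffs; CLI runs embed a provenance block (version, settings, input
  SHA-256) in the JSON summary.
- Problem sizes in tests and the acceptance script: 1,000 random pairs /
  target triples and a 5-member, 200-residue fixture family — large
  enough to exercise every rounding branch while keeping the whole suite
  in seconds.

## Known limitations

- Comparisons against published per-family values require the mature
  (signal/pro-peptide-free) sequences and the same MSA program; the
  package neither fetches sequences nor curates maturity, so those checks
  run only when the user supplies the alignment.
- The index is sequence-only: structural epitopes, posttranslational
  modifications and ligand effects are outside the model.
- Pairwise mode's internal alignments are not a substitute for a family
  MSA when comparing against MSA-derived numbers.
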