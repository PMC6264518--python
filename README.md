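# arisc

Pairwise protein homology analysis for allergen (or any homologous)
families: sequence identity and similarity under an explicit amino-acid
similarity-group model, the **A-RISC index** (Allergens' Relative Identity,
Similarity and Cross-reactivity), four-tier cross-reactivity risk
categories, per-family pair matrices, summaries and rankings, plus risk
heatmaps and per-reference homology profiles.

## Who this is for

IgE cross-reactivity — antibodies raised against one sensitizing allergen
binding a structurally similar protein, typically from the same family —
is central to component-resolved allergy diagnostics, avoidance guidance
and immunotherapy design. A single number that summarizes how homologous
two family members are, calibrated against clinically observed
cross-reactivity, makes those analyses systematic. `arisc` computes that
number and everything around it for anyone working with families of
homologous proteins.

## The model

For a pair of aligned sequences, each compared position is *identical*,
*similar but not identical* (both residues in one physicochemical group:
aromatic F/Y/W, aliphatic I/L/V, positively charged H/K/R, negatively
charged D/E, hydroxyl S/T, neutral polar N/Q — A, C, G, M, P are in no
group), or *not similar*. With identity fraction *I* and similarity
fraction *S* (similar includes identical, so *S ≥ I*), and assuming a
similar-but-not-identical residue supports cross-reactive antibody binding
half of the time:

```
A-RISC = I + (S − I)/2 = (I + S)/2
```

interpreted as the fraction of residues able to support binding of a
cross-reactive antibody, and mapped onto risk categories:

| A-RISC        | risk        |
|---------------|-------------|
| ≥ 0.75        | high        |
| 0.50 – 0.75   | medium-high |
| 0.25 – 0.50   | medium-low  |
| < 0.25        | low         |

Boundaries are closed from below (0.75 is high). By default *I* and *S*
are fractions of the shorter sequence's length; longest/mean/alignment
conventions are selectable. A family's cross-reactivity propensity is its
mean A-RISC over all unordered pairs, which also ranks families.

## Worked example

Generate a synthetic 5-member family and analyze it (the generator fixes
each member's identity/similarity to the first sequence, so results are
fully reproducible):

```
$ arisc simulate --n 5 --length 120 --seed 7 --out family.fasta
wrote 5 sequences to family.fasta
$ arisc compute --fasta family.fasta --out family
5 sequences, 10 pairs; mean A-RISC 0.49 (medium-low)
```

`family.arisc.tsv` holds the pair matrix (diagonal = self-comparison):

```
        synthetic_family_01  synthetic_family_02  synthetic_family_03 ...
synthetic_family_01   1.00     0.78     0.77     0.55     0.33
synthetic_family_02   0.78     1.00     0.62     0.50     0.31
```

Sequences 1 and 2 share 64.2% identity (see `family.identity.tsv`) and an
A-RISC of 0.78 — a *high* risk that an antibody against one cross-reacts
with the other — while sequences 1 and 5 (A-RISC 0.33, identity 22.5%)
are *medium-low* risk. `family.summary.json` reports the family-level
picture with full provenance (settings and input checksums):

```json
"mean_identity_pct": 38, "mean_similarity_pct": 59, "mean_arisc": 0.49
```

Figures:

```
arisc heatmap --fasta family.fasta --out family --export-data
arisc profile --fasta family.fasta --out family synthetic_family_01
```

give the triangular red-to-green risk heatmap and the per-member homology
profile against a chosen reference (dashed guides at 75%/50%/25%).
`arisc summary --fasta famA.fasta --fasta famB.fasta --out rank` ranks
several families by mean A-RISC. Real analyses normally start from a
per-family multiple sequence alignment (`--aln family.aln`, Clustal or
aligned FASTA); unaligned FASTA input is aligned internally pair by pair
(BLOSUM62 global alignment) and is alignment-dependent.

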