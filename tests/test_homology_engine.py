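"""Similarity-group scoring: counting, conventions, alignment, properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arisc import (
    AlignParams,
    Alignment,
    SequenceRecord,
    SimilarityModel,
    align_pair_global,
    are_similar,
    count_pair,
    default_similarity_model,
    extract_pair_from_msa,
    load_similarity_model,
    score_pair,
)
from conftest import make_pair

# the six groups, restated literally so this file is independent of the
# package's constant
GROUPS = ["FYW", "ILV", "HKR", "DE", "ST", "NQ"]
UNGROUPED = "ACGMP"
STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def naive_count(row1, row2):
    """Independent column-by-column re-count used as the oracle."""
    n_ident = n_sim = n_cols = 0
    for a, b in zip(row1.upper(), row2.upper()):
        if a == "-" and b == "-":
            continue
        n_cols += 1
        if a == "-" or b == "-":
            continue
        if a == b and a in STANDARD:
            n_ident += 1
            n_sim += 1
        elif any(a in g and b in g for g in GROUPS):
            n_sim += 1
    return n_ident, n_sim, n_cols


class TestSimilarityModel:
    def test_default_model_shape(self, model):
        assert len(model.groups) == 6
        assert sum(len(g) for g in model.groups) == 15
        assert model.group_of("W") == frozenset("FYW")
        for r in UNGROUPED:
            assert model.group_of(r) is None

    def test_groups_disjoint(self, model):
        seen = set()
        for g in model.groups:
            assert not (g & seen)
            seen |= g

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="more than one group"):
            SimilarityModel(groups=(frozenset("FYW"), frozenset("WIL")))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            SimilarityModel(groups=(frozenset("F"),))

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="non-standard"):
            SimilarityModel(groups=(frozenset("XZ"),))

    def test_load_from_yaml(self, tmp_path):
        p = tmp_path / "clustal_strong.yaml"
        p.write_text("name: alt\ngroups: [FYW, ILVM]\n")
        m = load_similarity_model(p)
        assert m.name == "alt"
        assert m.group_of("M") == frozenset("ILVM")


class TestAreSimilar:
    @pytest.mark.parametrize("a,b,expected", [
        ("F", "Y", True),    # aromatic group
        ("A", "C", False),   # both ungrouped
        ("D", "D", True),    # identical counts as similar
        ("X", "X", False),   # ambiguity codes carry no evidence
        ("D", "E", True),    # negatively charged
        ("S", "T", True),    # hydroxyl
        ("N", "Q", True),    # neutral polar
        ("K", "H", True),    # positively charged
        ("I", "L", True),    # aliphatic
        ("A", "A", True),    # ungrouped but identical
        ("F", "L", False),   # different groups
        ("-", "-", False),   # gaps never similar
        ("B", "B", False),
    ])
    def test_pairs(self, model, a, b, expected):
        assert are_similar(model, a, b) is expected
        assert are_similar(model, b, a) is expected


class TestCountPair:
    @pytest.mark.parametrize("row1,row2,n_ident,n_sim", [
        ("FYW", "YFW", 1, 3),       # F<->Y similar twice, W identical
        ("ACDE", "ACDE", 4, 4),     # self comparison
        ("KR-D", "RKHE", 0, 3),     # gap column skipped, D<->E similar
        ("XXXX", "XXXX", 0, 0),     # ambiguity codes never match
        ("FY--", "--FY", 0, 0),     # nothing aligned residue-to-residue
    ])
    def test_examples(self, model, row1, row2, n_ident, n_sim):
        counts = count_pair(make_pair(row1, row2), model)
        assert (counts.n_identical, counts.n_similar) == (n_ident, n_sim)

    def test_gap_gap_columns_removed_before_counting(self, model):
        counts = count_pair(make_pair("A--C", "A--C"), model)
        assert counts.n_columns == 2
        assert counts.n_identical == 2

    @given(st.data())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_naive_recount(self, model, data):
        alphabet = STANDARD + "XBZU-"
        n = data.draw(st.integers(min_value=1, max_value=50))
        row1 = data.draw(st.text(alphabet=alphabet, min_size=n, max_size=n))
        row2 = data.draw(st.text(alphabet=alphabet, min_size=n, max_size=n))
        if all(a == "-" and b == "-" for a, b in zip(row1, row2)):
            row1 = "A" + row1[1:]
        pair = make_pair(row1, row2)
        counts = count_pair(pair, model)
        n_ident, n_sim, n_cols = naive_count(row1, row2)
        assert counts.n_identical == n_ident
        assert counts.n_similar == n_sim
        assert counts.n_columns == n_cols
        assert counts.n_identical <= counts.n_similar

    def test_monotone_under_single_column_edits(self, model):
        base = count_pair(make_pair("FADE", "FADE"), model)
        within = count_pair(make_pair("FADE", "YADE"), model)  # F->Y aromatic
        outside = count_pair(make_pair("FADE", "CADE"), model)  # F->C
        assert within.n_identical == base.n_identical - 1
        assert within.n_similar == base.n_similar
        assert outside.n_identical == base.n_identical - 1
        assert outside.n_similar == base.n_similar - 1


class TestScorePair:
    def test_shortest_denominator(self, model):
        s = score_pair(make_pair("FYW", "YFW"), model)
        assert s.I == pytest.approx(1 / 3)
        assert s.S == 1.0
        assert s.arisc == pytest.approx(2 / 3)

    def test_identical_sequences(self, model):
        s = score_pair(make_pair("ACDEFGHIKL", "ACDEFGHIKL"), model)
        assert (s.I, s.S, s.arisc, s.category) == (1.0, 1.0, 1.0, "high")

    @pytest.mark.parametrize("denominator,expected_I", [
        ("shortest", 1.0),
        ("longest", 0.8),
        ("mean", 4 / 4.5),
        ("alignment", 0.8),
    ])
    def test_denominator_conventions(self, model, denominator, expected_I):
        s = score_pair(make_pair("ACDE-", "ACDEF"), model,
                       denominator=denominator)
        assert s.I == pytest.approx(expected_I)

    def test_symmetry_every_convention(self, model):
        pair = make_pair("FY-WACD", "YFAW-CE")
        for conv in ("shortest", "longest", "mean", "alignment"):
            a = score_pair(pair, model, denominator=conv)
            b = score_pair(pair.swapped(), model, denominator=conv)
            assert a.I == b.I and a.S == b.S and a.arisc == b.arisc

    def test_weight_passed_through(self, model):
        pair = make_pair("FYW", "YFW")  # I=1/3, S=1
        assert score_pair(pair, model, w=0.0).arisc == pytest.approx(1 / 3)
        assert score_pair(pair, model, w=1.0).arisc == 1.0

    def test_unknown_convention_rejected(self, model):
        with pytest.raises(ValueError, match="denominator"):
            score_pair(make_pair("AC", "AC"), model, denominator="median")


class TestAlignPairGlobal:
    def test_identical_sequences_align_without_gaps(self):
        pair = align_pair_global(SequenceRecord(id="a", seq="ACD"),
                                 SequenceRecord(id="b", seq="ACD"))
        assert (pair.row1, pair.row2) == ("ACD", "ACD")
        assert pair.provenance == "pairwise-aligned"

    def test_single_gap_for_length_difference(self):
        pair = align_pair_global(SequenceRecord(id="a", seq="MKV"),
                                 SequenceRecord(id="b", seq="MV"))
        assert pair.row1 == "MKV"
        assert pair.row2.count("-") == 1
        assert pair.row2.replace("-", "") == "MV"

    def test_symmetric_scores(self, model):
        a = SequenceRecord(id="a", seq="MKVLAT")
        b = SequenceRecord(id="b", seq="MKLATW")
        ab = score_pair(align_pair_global(a, b), model)
        ba = score_pair(align_pair_global(b, a), model)
        assert ab.I == ba.I and ab.S == ba.S

    def test_deterministic(self):
        a = SequenceRecord(id="a", seq="MKVLATGHW")
        b = SequenceRecord(id="b", seq="MKLATWGH")
        p1 = align_pair_global(a, b)
        p2 = align_pair_global(a, b)
        assert (p1.row1, p1.row2) == (p2.row1, p2.row2)

    def test_ambiguity_codes_survive_alignment(self):
        # U/O are absent from BLOSUM62; they are scored as X but the output
        # rows keep the original residues
        pair = align_pair_global(SequenceRecord(id="a", seq="MKUV"),
                                 SequenceRecord(id="b", seq="MKOV"))
        assert "U" in pair.row1 and "O" in pair.row2

    def test_invalid_gap_params_rejected(self):
        with pytest.raises(ValueError, match="gap_extend"):
            AlignParams(gap_open=1.0, gap_extend=2.0)


class TestExtractPairFromMsa:
    def test_gap_gap_column_dropped(self):
        aln = Alignment(records=(("A", "AC-D"), ("B", "AC-D")))
        pair = extract_pair_from_msa(aln, "A", "B")
        assert (pair.row1, pair.row2) == ("ACD", "ACD")
        assert pair.provenance == "msa-extracted"

    def test_columns_without_double_gap_kept(self):
        aln = Alignment(records=(("A", "A-CD"), ("B", "AEC-")))
        pair = extract_pair_from_msa(aln, "A", "B")
        assert (pair.row1, pair.row2) == ("A-CD", "AEC-")

    def test_unknown_id_reported(self):
        aln = Alignment(records=(("A", "ACD"), ("B", "ACD")))
        with pytest.raises(KeyError, match="missing"):
            extract_pair_from_msa(aln, "A", "missing")
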