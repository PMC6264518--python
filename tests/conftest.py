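import pytest

from arisc import (
    AlignedPair,
    Alignment,
    FamilySpec,
    build_family_matrix,
    default_similarity_model,
    generate_family,
)


@pytest.fixture(scope="session")
def model():
    return default_similarity_model()


@pytest.fixture(scope="session")
def fixture_family():
    """5-member synthetic family with known member-vs-seed targets."""
    spec = FamilySpec(
        n=5, length=200, seed=42,
        pair_targets=((0.9, 0.95), (0.6, 0.8), (0.3, 0.5), (0.1, 0.2)),
    )
    return spec, generate_family(spec)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_family):
    # generated sequences are equal-length and gap-free, so they form a
    # trivial alignment and scoring recovers the construction targets
    _, records = fixture_family
    aln = Alignment(records=tuple((r.id, r.seq) for r in records))
    return build_family_matrix(aln, mode="msa")


def make_pair(row1, row2, id1="s1", id2="s2"):
    return AlignedPair(id1=id1, id2=id2, row1=row1, row2=row2)
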