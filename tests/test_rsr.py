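"""Rank-code derivation, stability grouping, composition, rank comparisons."""

import random

import pytest

from oracles import selection_sort_ranking
from zfsite.rsr import (
    compare_rank_codes,
    composition_summary,
    compute_rsr_code,
    rank_shift_report,
    stability_grouping,
)
from zfsite.sequence import enumerate_triplets
from zfsite.tables import RsrCode, TripletAssayRecord


def test_sp1_code_recovered_from_counts_at_every_rank(assay_records, sp1_code):
    """Descending-count ranking with stable ties reproduces the published
    SP1 code at all 64 positions, including the six tied count pairs."""
    derived = compute_rsr_code(assay_records)
    assert derived.ranking == sp1_code.ranking
    # the tied pairs resolve in presentation order
    assert derived.rank_of("TAG") == 9 and derived.rank_of("CCG") == 10
    assert derived.rank_of("CCT") == 30 and derived.rank_of("CAA") == 31
    assert derived.rank_of("TTT") == 39 and derived.rank_of("CGA") == 40


def test_all_equal_counts_rank_in_input_order():
    records = [TripletAssayRecord(t, 7, None) for t in enumerate_triplets()]
    assert compute_rsr_code(records).ranking == tuple(enumerate_triplets())


@pytest.mark.parametrize("seed", range(5))
def test_ranking_agrees_with_selection_sort_oracle(seed):
    rng = random.Random(seed)
    records = [
        TripletAssayRecord(t, rng.randrange(0, 40), None) for t in enumerate_triplets()
    ]
    rng.shuffle(records)
    assert list(compute_rsr_code(records).ranking) == selection_sort_ranking(records)


def test_lexicographic_tie_policy():
    records = [TripletAssayRecord(t, 1, None) for t in reversed(enumerate_triplets())]
    assert compute_rsr_code(records, "lexicographic").ranking == tuple(enumerate_triplets())


def test_random_tie_policy_is_seeded():
    records = [TripletAssayRecord(t, 1, None) for t in enumerate_triplets()]
    a = compute_rsr_code(records, "random", seed=5)
    b = compute_rsr_code(records, "random", seed=5)
    c = compute_rsr_code(records, "random", seed=6)
    assert a.ranking == b.ranking != c.ranking
    assert sorted(a.ranking) == enumerate_triplets()


def test_duplicate_triplets_rejected(assay_records):
    broken = list(assay_records)
    broken[1] = broken[0]
    with pytest.raises(ValueError, match="64|duplicate"):
        compute_rsr_code(broken)


def test_stability_grouping_reproduces_published_sizes(assay_records):
    g = stability_grouping(assay_records, threshold=500, inclusive=True)
    assert g.sizes == (26, 35, 3)
    assert "CGC" in g.strong  # count exactly 500 sits in the strong group
    assert g.undetectable == {"AAA", "AAC", "ACC"}
    assert g.strong | g.weak | g.undetectable == set(enumerate_triplets())


def test_stability_grouping_variants(assay_records):
    assert stability_grouping(assay_records, threshold=1).sizes == (61, 0, 3)
    # exclusive comparison pushes the count==500 triplet into the weak group
    assert stability_grouping(assay_records, threshold=500, inclusive=False).sizes == (25, 36, 3)
    zeros = [TripletAssayRecord(t, 0, None) for t in enumerate_triplets()]
    assert stability_grouping(zeros).sizes == (0, 0, 64)
    with pytest.raises(ValueError, match="positive"):
        stability_grouping(assay_records, threshold=0)


def test_composition_of_top_26(assay_records):
    c = composition_summary(assay_records, top_k=26)
    assert (c.gc_rich, c.gc_triplet, c.at_rich, c.at_triplet) == (18, 6, 8, 3)
    assert c.gc_rich + c.at_rich == c.top_k


def test_top26_homogeneous_sets(sp1_code):
    from zfsite.sequence import gc_count

    top26 = sp1_code.top(26)
    assert {t for t in top26 if gc_count(t) == 3} == {"CGG", "GCG", "GGC", "CCC", "CCG", "CGC"}
    assert {t for t in top26 if gc_count(t) == 0} == {"TAA", "TAT", "AAT"}


def test_composition_edges(sp1_code, assay_records):
    full = composition_summary(sp1_code, top_k=64)
    assert (full.gc_rich, full.gc_triplet, full.at_rich, full.at_triplet) == (32, 8, 32, 8)
    # top_k=64 composition is ranking-independent
    shuffled = compute_rsr_code(assay_records, "lexicographic")
    alt = composition_summary(shuffled, top_k=64)
    assert alt == full
    top1 = composition_summary(sp1_code, top_k=1)
    assert (top1.gc_rich, top1.at_rich) == (1, 0)  # rank 1 is CGG
    with pytest.raises(ValueError):
        composition_summary(sp1_code, top_k=0)
    with pytest.raises(ValueError):
        composition_summary(sp1_code, top_k=65)


def test_compare_code_with_itself(sp1_code):
    cmp = compare_rank_codes(sp1_code, sp1_code)
    assert cmp.spearman_rho == pytest.approx(1.0)
    assert cmp.kendall_tau == pytest.approx(1.0)
    assert cmp.footrule_distance == 0
    assert all(v == 0 for v in cmp.per_triplet_shift.values())


def test_compare_with_reversed_code(sp1_code):
    reversed_code = RsrCode("rev", tuple(reversed(sp1_code.ranking)))
    cmp = compare_rank_codes(sp1_code, reversed_code)
    assert cmp.kendall_tau == pytest.approx(-1.0)
    assert cmp.spearman_rho == pytest.approx(-1.0)


def test_cgg_rank_shift_between_sp1_and_mq135(rank_codes):
    cmp = compare_rank_codes(rank_codes["SP1"], rank_codes["MQ135"])
    assert cmp.per_triplet_shift["CGG"] == 28  # rank 1 -> rank 29


def test_compare_rejects_mismatched_sets(sp1_code):
    other = RsrCode("x", tuple(enumerate_triplets()))
    swapped = list(other.ranking)
    cmp = compare_rank_codes(sp1_code, other)  # same triplet set: fine
    assert isinstance(cmp.footrule_distance, int)


def test_rank_shift_report(rank_codes):
    frame = rank_shift_report(rank_codes.values())
    assert frame.shape == (64, 6)
    assert list(frame.loc["CGG"]) == [1, 17, 14, 2, 29, 23]
    assert frame.loc["GCG", "SP1"] == 2
    # each column is a permutation of 1..64
    for col in frame.columns:
        assert sorted(frame[col]) == list(range(1, 65))
    with pytest.raises(ValueError, match="at least two"):
        rank_shift_report([rank_codes["SP1"]])
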