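"""Genome scanning: exact/degenerate matching, dimer search, expectations."""

import gzip
import random

import numpy as np
import pytest

from oracles import naive_pattern_scan, naive_revcomp, naive_scan
from zfsite.scan import (
    DimerQuery,
    Genome,
    PatternSizeError,
    count_exact,
    count_pattern,
    expected_occurrences,
    find_dimer_sites,
    offtarget_landscape,
)
from zfsite.sequence import enumerate_triplets, reverse_complement
from zfsite.simulate import GenomeSimulationConfig, simulate_genome

HBB_COMPOSITE = "GGCAGACTTGTGGAGAGGAGTCAG"  # left + 6 bp spacer + right


def random_genome(rng, n_records=1, max_len=800):
    return Genome(
        {
            f"rec{i}": "".join(rng.choice("ACGT") for _ in range(rng.randrange(0, max_len)))
            for i in range(n_records)
        }
    )


def test_overlapping_hand_enumeration():
    g = Genome({"r": "GGGGG"})
    assert count_exact(g, "GG").count == 4
    assert count_exact(g, "GG", overlapping=False).count == 2


def test_palindromic_query_reported_once_per_strand():
    g = Genome({"r": "GAATTC"})
    rep = count_exact(g, "GAATTC", strand_mode="both")
    assert rep.positions == (("r", 0, "+"), ("r", 0, "-"))


def test_empty_and_oversized_queries_yield_empty_reports():
    g = Genome({"r": "ACGT"})
    assert count_exact(g, "").count == 0
    assert count_exact(g, "ACGTACGTACGT").count == 0


def test_scanner_matches_naive_oracle_on_random_instances():
    """Exact scanning agrees with a character-by-character oracle across
    random genomes, queries, strand modes and overlap settings."""
    rng = random.Random(20_240_401)
    for trial in range(220):
        g = random_genome(rng, n_records=rng.randrange(1, 3))
        k = rng.randrange(1, 13)
        all_text = "".join(g.sequences.values())
        if all_text and rng.random() < 0.5 and len(all_text) >= k:
            start = rng.randrange(0, len(all_text) - k + 1)
            query = all_text[start : start + k]  # guaranteed-hit query
        else:
            query = "".join(rng.choice("ACGT") for _ in range(k))
        strand = rng.choice(["forward", "both"])
        overlapping = rng.random() < 0.5
        report = count_exact(g, query, strand, overlapping)
        assert list(report.positions) == naive_scan(g.sequences, query, strand, overlapping)


def test_strand_symmetry_under_genome_reversal():
    rng = random.Random(7)
    for _ in range(20):
        g = random_genome(rng)
        query = "".join(rng.choice("ACGT") for _ in range(6))
        flipped = Genome({n: reverse_complement(s) for n, s in g.sequences.items()})
        assert (
            count_exact(g, query, "both").count == count_exact(flipped, query, "both").count
        )


def test_count_pattern_on_all_64_instantiations():
    sites = ["GGG" + t + "GGG" for t in enumerate_triplets()]
    g = Genome({"r": "TTATT".join(sites)})
    reports = count_pattern(g, "GGGNNNGGG")
    assert len(reports) == 64
    assert all(rep.count == 1 for rep in reports.values())
    assert reports["CGG"].query == "GGGCGGGGG"


def test_count_pattern_reduces_to_exact_and_handles_no_match():
    g = Genome({"r": "GGGAAAGGGT"})
    solo = count_pattern(g, "GGGAAAGGG")
    assert list(solo) == [""] and solo[""].count == 1
    no_g = Genome({"r": "ATTATACATTA"})
    reports = count_pattern(no_g, "GGGNNNGGG")
    assert all(rep.count == 0 for rep in reports.values())


def test_count_pattern_matches_naive_oracle_and_totals():
    rng = random.Random(11)
    g = random_genome(rng, max_len=2000)
    reports = count_pattern(g, "GGNNA")
    oracle = naive_pattern_scan(g.sequences, "GGNNA")
    for key, rep in reports.items():
        assert rep.count == oracle.get(key, 0)
    # instantiation counts tile the degenerate match set without double counting
    total_positions = sorted(p for rep in reports.values() for p in rep.positions)
    assert len(total_positions) == len(set(total_positions))
    assert sum(rep.count for rep in reports.values()) == sum(oracle.values())


def test_count_pattern_refuses_blowup_unless_overridden():
    g = Genome({"r": "ACGT" * 4})
    with pytest.raises(PatternSizeError, match="N positions"):
        count_pattern(g, "N" * 7)
    reports = count_pattern(g, "N" * 7, allow_large=True)
    assert len(reports) == 4**7


def test_ns_in_genome_never_match():
    g = Genome({"r": "GGNGG"})
    assert count_exact(g, "GNG".replace("N", "A")).count == 0
    assert count_exact(g, "GG").count == 2
    reports = count_pattern(g, "GGN")
    assert sum(rep.count for rep in reports.values()) == 0


def test_dimer_search_on_planted_hbb_site():
    """A genome carrying the composite half-site pair exactly once yields
    exactly one dimer hit of the full 24-bp composite."""
    pattern = "GGCAGACTT" + "N" * 6 + "AGGAGTCAG"
    config = GenomeSimulationConfig(
        length=10_000,
        planted=((HBB_COMPOSITE, 1),),
        scrub_patterns=(pattern, reverse_complement(pattern, allow_n=True)),
        seed=3,
    )
    g = simulate_genome(config)
    hits = find_dimer_sites(g, DimerQuery("GGCAGACTT", "AGGAGTCAG", 6, 6))
    assert len(hits) == 1
    hit = hits[0]
    assert hit.composite_sequence == HBB_COMPOSITE
    assert hit.end - hit.start == 24
    assert hit.spacer_length == 6

    # the opposite-strand convention with the reverse-complemented right
    # site reconstructs the same literal and the same hit set
    alt = DimerQuery(
        "GGCAGACTT",
        reverse_complement("AGGAGTCAG"),
        6,
        6,
        right_site_convention="opposite_strand",
    )
    assert alt.effective_right == "AGGAGTCAG"
    assert find_dimer_sites(g, alt) == hits


def test_dimer_spacer_range_is_union_of_fixed_spacers():
    rng = random.Random(23)
    g = random_genome(rng, max_len=3000)
    left, right = "ACG", "TGA"
    ranged = find_dimer_sites(g, DimerQuery(left, right, 0, 3))
    fixed = []
    for s in range(0, 4):
        fixed.extend(find_dimer_sites(g, DimerQuery(left, right, s, s)))
    assert sorted(ranged, key=lambda h: (h.record, h.start, h.spacer_length, h.strand)) == sorted(
        fixed, key=lambda h: (h.record, h.start, h.spacer_length, h.strand)
    )
    assert len(set((h.record, h.start, h.spacer_length, h.strand) for h in ranged)) == len(ranged)


def test_dimer_search_without_left_site_is_empty():
    g = Genome({"r": "T" * 200})
    assert find_dimer_sites(g, DimerQuery("GGCAGACTT", "AGGAGTCAG", 6, 6)) == []


def test_expected_occurrences_closed_form():
    assert expected_occurrences("ACGTACGTA", 4**9 + 8) == pytest.approx(1.0)
    assert expected_occurrences("ACGTACGTA", 5) == 0.0
    with pytest.raises(ValueError, match="sum to 1"):
        expected_occurrences("ACG", 100, (0.5, 0.5, 0.5, 0.5))
    with pytest.raises(ValueError, match="non-negative"):
        expected_occurrences("ACG", 100, (-0.1, 0.5, 0.3, 0.3))


def test_expected_occurrences_monte_carlo():
    """Mean observed count over simulated genomes sits within 3 standard
    errors of the analytic i.i.d. expectation."""
    kmer, length, n = "ACGT", 1000, 220
    counts = [
        count_exact(
            simulate_genome(GenomeSimulationConfig(length=length, seed=s, scrub=False)), kmer
        ).count
        for s in range(n)
    ]
    expected = expected_occurrences(kmer, length)
    se = np.std(counts, ddof=1) / np.sqrt(n)
    assert abs(np.mean(counts) - expected) < 3 * se + 1e-9


def test_offtarget_landscape_from_fixture(assay_records, sp1_code):
    frame = offtarget_landscape(sp1_code, records=assay_records)
    assert list(frame["rank"]) == list(range(1, 65))
    assert frame.iloc[0]["triplet"] == "CGG"
    assert frame.iloc[0]["occurrences"] == 16697
    assert frame["occurrences"].sum() == 1_261_301


def test_offtarget_landscape_from_genome(sp1_code):
    sites = ["GGG" + t + "GGG" for t in enumerate_triplets()]
    g = Genome({"r": "TTATT".join(sites)})
    frame = offtarget_landscape(sp1_code, genome=g)
    assert set(frame["occurrences"]) == {1}
    bare = offtarget_landscape(sp1_code, genome=g, flank="")
    oracle = naive_pattern_scan(g.sequences, "NNN")
    for _, row in bare.iterrows():
        assert row["occurrences"] == oracle.get(row["triplet"], 0)
    with pytest.raises(ValueError, match="exactly one"):
        offtarget_landscape(sp1_code)


def test_fasta_round_trip(tmp_path):
    g = Genome({"chr1": "ACGT" * 40, "chr2": "GGCAGACTT"})
    path = tmp_path / "g.fasta"
    g.to_fasta(path)
    text = path.read_text()
    assert text.startswith(">chr1\n")
    assert max(len(line) for line in text.splitlines()) <= 60
    assert Genome.from_fasta(path).sequences == g.sequences

    gz = tmp_path / "g.fasta.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write(text)
    assert Genome.from_fasta(gz).sequences == g.sequences
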