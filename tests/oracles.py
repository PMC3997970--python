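"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — character-by-character scans and
selection sorts — and shares no code with the package's scanning or
ranking paths.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_scan(
    sequences: dict[str, str],
    query: str,
    strand_mode: str = "forward",
    overlapping: bool = True,
) -> list[tuple[str, int, str]]:
    """Character-by-character exact-match scan (positions are forward starts)."""
    queries = [(query, "+")]
    if strand_mode == "both":
        queries.append((naive_revcomp(query), "-"))
    hits: list[tuple[str, int, str]] = []
    for name, seq in sequences.items():
        for q, strand in queries:
            i = 0
            while i <= len(seq) - len(q):
                if all(seq[i + j] == q[j] for j in range(len(q))):
                    hits.append((name, i, strand))
                    i += 1 if overlapping else len(q)
                else:
                    i += 1
    return sorted(hits)


def naive_pattern_scan(sequences: dict[str, str], pattern: str) -> dict[str, int]:
    """Forward-strand overlap-aware scan of an ACGTN pattern.

    Returns counts keyed by the bases at the N positions.
    """
    n_pos = [i for i, c in enumerate(pattern) if c == "N"]
    counts: dict[str, int] = {}
    for seq in sequences.values():
        for i in range(len(seq) - len(pattern) + 1):
            window = seq[i : i + len(pattern)]
            if all(window[j] == pattern[j] or pattern[j] == "N" for j in range(len(pattern))):
                if any(window[j] not in "ACGT" for j in n_pos):
                    continue
                key = "".join(window[j] for j in n_pos)
                counts[key] = counts.get(key, 0) + 1
    return counts


def selection_sort_ranking(records) -> list[str]:
    """Rank triplets by repeatedly extracting the first-listed maximum count."""
    remaining = list(records)
    ordered = []
    while remaining:
        best = max(r.p32_count for r in remaining)
        pick = next(r for r in remaining if r.p32_count == best)
        ordered.append(pick.triplet)
        remaining.remove(pick)
    return ordered
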