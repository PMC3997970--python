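"""Exact and degenerate k-mer scanning of genomes, and paired dimer-site search.

Supports the occurrence-counting questions behind zinc finger nuclease
(ZFN) design: how many times a 9-bp half-site occurs in a genome, how
the 64 instantiations of a degenerate pattern like ``GGGNNNGGG`` are
distributed, and where two half-sites co-occur across a spacer so that
a FokI nuclease dimer could assemble and cut.

Conventions
-----------
* Coordinates are 0-based, half-open, and always given as forward-strand
  start positions (BED convention), including for minus-strand hits.
* Overlapping matches are counted by default.
* ``N`` in a genome never matches any query base; record boundaries are
  never crossed.
* The default strand mode is forward-only; ``strand_mode="both"``
  additionally matches the reverse complement of the query and labels
  each hit's strand.  A palindromic query is reported once per strand.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from math import prod
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from zfsite.sequence import reverse_complement, validate_sequence
from zfsite.tables import RsrCode, TripletAssayRecord

StrandMode = Literal["forward", "both"]


class PatternSizeError(ValueError):
    """A degenerate pattern would expand to too many instantiations."""


@dataclass
class Genome:
    """An ordered collection of named DNA sequences.

    Sequences may contain ``N`` (unresolved bases); queries never match
    them.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {
            name: validate_sequence(seq, allow_n=True, context=f"record {name!r}")
            for name, seq in self.sequences.items()
        }

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        """Read a (possibly gzip-compressed) multi-record FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            seqs: dict[str, str] = {}
            for rec in SeqIO.parse(fh, "fasta"):
                if rec.id in seqs:
                    raise ValueError(f"duplicate FASTA record name {rec.id!r}")
                seqs[rec.id] = str(rec.seq)
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        """Write as FASTA with 60-column line wrap."""
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
            writer.write_file(records)


@dataclass(frozen=True)
class OccurrenceReport:
    """All occurrences of one concrete query in a genome."""

    query: str
    strand_mode: StrandMode
    overlapping: bool
    positions: tuple[tuple[str, int, str], ...]  # (record, 0-based start, strand)

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DimerQuery:
    """Two half-sites plus spacer constraints for paired ZFN site search.

    ``right_site_convention`` controls how the right half-site is read:
    ``"as_written"`` matches it literally on the same strand as the left
    site; ``"opposite_strand"`` treats it as the sequence the second
    finger domain reads on the other strand, i.e. its reverse complement
    is matched on the left site's strand.
    """

    left_site: str
    right_site: str
    spacer_min: int = 6
    spacer_max: int = 6
    right_site_convention: Literal["as_written", "opposite_strand"] = "as_written"

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_site", validate_sequence(self.left_site, context="left_site"))
        object.__setattr__(self, "right_site", validate_sequence(self.right_site, context="right_site"))
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError(
                f"need 0 <= spacer_min <= spacer_max, got [{self.spacer_min}, {self.spacer_max}]"
            )

    @property
    def effective_right(self) -> str:
        """The right half-site as it must appear on the left site's strand."""
        if self.right_site_convention == "opposite_strand":
            return reverse_complement(self.right_site)
        return self.right_site


@dataclass(frozen=True)
class DimerHit:
    """One composite (left + spacer + right) occurrence."""

    record: str
    start: int  # forward-strand, 0-based
    end: int  # exclusive
    composite_sequence: str  # forward-strand slice genome[start:end]
    spacer_length: int
    strand: str


def _find_literal(text: str, query: str, overlapping: bool) -> list[int]:
    """Start positions of query in text (naive scan via str.find)."""
    hits: list[int] = []
    step = 1 if overlapping else len(query)
    i = text.find(query)
    while i != -1:
        hits.append(i)
        i = text.find(query, i + step)
    return hits


def count_exact(
    genome: Genome,
    kmer: str,
    strand_mode: StrandMode = "forward",
    overlapping: bool = True,
) -> OccurrenceReport:
    """Count all exact occurrences of a wildcard-free k-mer.

    In ``"both"`` mode the reverse complement of the query is also
    matched on the forward text and labelled strand ``-`` (positions
    remain forward-strand starts).  An empty query, or one longer than
    every record, yields a defined empty report.
    """
    kmer = validate_sequence(kmer, context="query")
    positions: list[tuple[str, int, str]] = []
    if kmer:
        queries = [(kmer, "+")]
        if strand_mode == "both":
            queries.append((reverse_complement(kmer), "-"))
        for name, seq in genome.sequences.items():
            for q, strand in queries:
                for start in _find_literal(seq, q, overlapping):
                    positions.append((name, start, strand))
    positions.sort(key=lambda p: (p[0], p[1], p[2]))
    return OccurrenceReport(
        query=kmer,
        strand_mode=strand_mode,
        overlapping=overlapping,
        positions=tuple(positions),
    )


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    """Overlap-aware regex for an ACGTN pattern (lookahead capture)."""
    body = "".join("[ACGT]" if c == "N" else c for c in pattern)
    return re.compile(f"(?=({body}))")


def count_pattern(
    genome: Genome,
    pattern: str,
    *,
    allow_large: bool = False,
) -> dict[str, OccurrenceReport]:
    """Count every concrete instantiation of an N-wildcard pattern in one pass.

    Returns a report per instantiation, keyed by the bases at the N
    positions (for ``GGGNNNGGG``: the central triplet, 64 keys), with
    zero-count instantiations included.  Matching is forward-strand and
    overlap-aware.  Patterns with more than 6 N positions are refused
    (4^N key blow-up) unless ``allow_large`` is set.
    """
    pattern = validate_sequence(pattern, allow_n=True, context="pattern")
    n_positions = [i for i, c in enumerate(pattern) if c == "N"]
    if len(n_positions) > 6 and not allow_large:
        raise PatternSizeError(
            f"pattern has {len(n_positions)} N positions "
            f"(4^{len(n_positions)} = {4 ** len(n_positions)} instantiations); "
            "pass allow_large=True to proceed"
        )
    if not n_positions:
        report = count_exact(genome, pattern)
        return {"": report}

    from itertools import product

    hits: dict[str, list[tuple[str, int, str]]] = {
        "".join(p): [] for p in product("ACGT", repeat=len(n_positions))
    }
    rx = _pattern_regex(pattern)
    for name, seq in genome.sequences.items():
        for m in rx.finditer(seq):
            window = m.group(1)
            key = "".join(window[i] for i in n_positions)
            hits[key].append((name, m.start(), "+"))
    out: dict[str, OccurrenceReport] = {}
    for key, pos in hits.items():
        concrete = list(pattern)
        for i, base in zip(n_positions, key):
            concrete[i] = base
        out[key] = OccurrenceReport(
            query="".join(concrete),
            strand_mode="forward",
            overlapping=True,
            positions=tuple(sorted(pos)),
        )
    return out


def find_dimer_sites(genome: Genome, query: DimerQuery) -> list[DimerHit]:
    """Find all composite left + spacer + right sites on both strands.

    For each spacer length in ``[spacer_min, spacer_max]`` the composite
    pattern ``left + N*spacer + right`` (with the right site resolved by
    the query's strand convention) is matched on the forward text, and
    its reverse complement is matched to capture minus-strand composites.
    Coordinates are forward-strand; ``composite_sequence`` is the
    forward-strand slice.
    """
    left = query.left_site
    right = query.effective_right
    hits: list[DimerHit] = []
    for spacer in range(query.spacer_min, query.spacer_max + 1):
        fwd = left + "N" * spacer + right
        patterns = [(fwd, "+")]
        rev = reverse_complement(right) + "N" * spacer + reverse_complement(left)
        if rev != fwd:
            patterns.append((rev, "-"))
        else:
            patterns.append((fwd, "-"))  # palindromic composite: once per strand
        for pat, strand in patterns:
            rx = _pattern_regex(pat)
            for name, seq in genome.sequences.items():
                for m in rx.finditer(seq):
                    start = m.start()
                    end = start + len(pat)
                    hits.append(
                        DimerHit(
                            record=name,
                            start=start,
                            end=end,
                            composite_sequence=seq[start:end],
                            spacer_length=spacer,
                            strand=strand,
                        )
                    )
    hits.sort(key=lambda h: (h.record, h.start, h.spacer_length, h.strand))
    return hits


def expected_occurrences(
    kmer: str,
    genome_length: int,
    base_probabilities: Mapping[str, float] | Sequence[float] | None = None,
) -> float:
    """Expected exact-match count of a k-mer in an i.i.d. random genome.

    ``(L - k + 1) * prod(p(base_i))``, clamped at 0 for genomes shorter
    than the query.  Default base probabilities are uniform (0.25 each).
    Useful for judging whether an observed occurrence count (e.g. of a
    9-bp half-site) is consistent with background.
    """
    kmer = validate_sequence(kmer, context="query")
    if base_probabilities is None:
        probs = {b: 0.25 for b in "ACGT"}
    elif isinstance(base_probabilities, Mapping):
        probs = {b.upper(): float(p) for b, p in base_probabilities.items()}
    else:
        probs = dict(zip("ACGT", (float(p) for p in base_probabilities)))
    if any(p < 0 for p in probs.values()):
        raise ValueError("base probabilities must be non-negative")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError(f"base probabilities must sum to 1, got {sum(probs.values())}")
    windows = genome_length - len(kmer) + 1
    if windows <= 0:
        return 0.0
    return windows * prod(probs[b] for b in kmer)


def offtarget_landscape(
    code: RsrCode,
    genome: Genome | None = None,
    records: Sequence[TripletAssayRecord] | None = None,
    flank: str = "GGG",
) -> pd.DataFrame:
    """Per-triplet occurrence counts of flank+triplet+flank, joined with ranks.

    Every genomic occurrence of one of the 64 flanked 9-mers is a
    potential off-target location for the corresponding complex, and the
    triplet's rank in the supplied code orders them by expected complex
    stability.  Counts come either from scanning ``genome`` with a single
    degenerate-pattern pass, or directly from a count table's recorded
    occurrence column (``records``).  A zero-length flank counts bare
    triplets.
    """
    if (genome is None) == (records is None):
        raise ValueError("supply exactly one of genome or records")
    flank = validate_sequence(flank, context="flank")
    if records is not None:
        counts = {r.triplet: r.huref_occurrences for r in records}
    else:
        reports = count_pattern(genome, flank + "NNN" + flank)
        counts = {key: rep.count for key, rep in reports.items()}
    rank = {t: i + 1 for i, t in enumerate(code.ranking)}
    frame = pd.DataFrame(
        {
            "triplet": list(code.ranking),
            "rank": [rank[t] for t in code.ranking],
            "site": [flank + t + flank for t in code.ranking],
            "occurrences": [counts[t] for t in code.ranking],
        }
    )
    return frame


def write_bed(report: OccurrenceReport, path: str | Path) -> None:
    """Write an occurrence report's positions as BED6 (score 0)."""
    with open(path, "w") as fh:
        for record, start, strand in report.positions:
            end = start + len(report.query)
            fh.write(f"{record}\t{start}\t{end}\t{report.query}\t0\t{strand}\n")


def write_occurrence_tsv(
    reports: Iterable[OccurrenceReport] | Mapping[str, OccurrenceReport],
    path: str | Path,
) -> None:
    """Write one or more occurrence reports as a query/count TSV table."""
    if isinstance(reports, Mapping):
        rows = [(key, rep.query, rep.count) for key, rep in reports.items()]
        header = "key\tquery\tcount\n"
    else:
        rows = [(rep.query, rep.query, rep.count) for rep in reports]
        header = "key\tquery\tcount\n"
    with open(path, "w") as fh:
        fh.write(header)
        for key, query, count in rows:
            fh.write(f"{key}\t{query}\t{count}\n")
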