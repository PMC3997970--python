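"""DNA sequence primitives shared by every other module.

Sequences are plain Python strings over the uppercase alphabet ``ACGT``
(``N`` is accepted only by operations that explicitly take wildcard
patterns).  A *triplet* is a 3-base sequence, the unit recognised by a
single C2H2 zinc finger.  Triplets are classified by G+C content: a
triplet with a G/C majority (2 or 3 of 3 bases) is *GC-rich*, otherwise
*AT-rich*; when all three bases fall on one side it is additionally
*homogeneous* (a "GC-triplet" or "AT-triplet").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains a character outside its permitted alphabet."""


def validate_sequence(seq: str, *, allow_n: bool = False, context: str = "sequence") -> str:
    """Fold to uppercase and reject characters outside ACGT (plus N if allowed).

    Returns the upper-cased sequence.  Raises :class:`AlphabetError` naming
    the first offending position.
    """
    if not isinstance(seq, str):
        raise AlphabetError(f"{context} must be a string, got {type(seq).__name__}")
    up = seq.upper()
    allowed = DNA_ALPHABET | {"N"} if allow_n else DNA_ALPHABET
    for i, ch in enumerate(up):
        if ch not in allowed:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i} in {context}; "
                f"allowed: {''.join(sorted(allowed))}"
            )
    return up


def complement(seq: str, *, allow_n: bool = False) -> str:
    """Base-wise Watson-Crick complement, orientation unchanged.

    This is the pairing used when a site is written together with the
    string that faces it on the other strand in the same 5'→3' register,
    e.g. ``TCCTCAGTC`` ↔ ``AGGAGTCAG``.  It is an involution.  With
    ``allow_n`` the wildcard N maps to itself (for pattern work).
    """
    return validate_sequence(seq, allow_n=allow_n).translate(_COMPLEMENT)


def reverse_complement(seq: str, *, allow_n: bool = False) -> str:
    """Watson-Crick complement read in reverse (the opposite-strand 5'→3' read)."""
    return validate_sequence(seq, allow_n=allow_n).translate(_COMPLEMENT)[::-1]


def gc_count(triplet: str) -> int:
    """Number of G or C bases in a triplet (0-3)."""
    t = validate_triplet(triplet)
    return sum(1 for b in t if b in "GC")


def validate_triplet(triplet: str) -> str:
    """Validate a 3-base wildcard-free sequence; returns it upper-cased."""
    t = validate_sequence(triplet, context="triplet")
    if len(t) != 3:
        raise ValueError(f"triplet must have exactly 3 bases, got {len(t)}: {triplet!r}")
    return t


class Richness(Enum):
    """G+C majority class of a triplet."""

    GC_RICH = "GC_RICH"
    AT_RICH = "AT_RICH"


@dataclass(frozen=True)
class TripletClass:
    """Composition class of a triplet.

    ``richness`` is GC_RICH iff at least 2 of the 3 bases are G or C
    (majority rule; 3 bases make a tie impossible).  ``homogeneous`` is
    true iff all three bases are on one side — the triplet is then a
    GC-triplet (gc_count 3) or an AT-triplet (gc_count 0).
    """

    richness: Richness
    homogeneous: bool


def classify_triplet(triplet: str) -> TripletClass:
    """Classify a triplet by its G+C content."""
    n = gc_count(triplet)
    return TripletClass(
        richness=Richness.GC_RICH if n >= 2 else Richness.AT_RICH,
        homogeneous=n in (0, 3),
    )


def enumerate_triplets() -> list[str]:
    """The 64 triplets in canonical order.

    Order is the four 16-triplet series starting with A, C, G and T,
    lexicographic within each series — i.e. plain lexicographic order
    over A < C < G < T.  This order is the stable key used by fixture
    files and reports.
    """
    return ["".join(p) for p in itertools.product("ACGT", repeat=3)]


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Yield (start, kmer) for every k-window of ``seq`` (no validation)."""
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]
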