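"""Composite binding-site construction for multi-finger domain designs.

A natural three-finger domain binds a 9-bp site, one triplet per finger.
Threading extra fingers onto the SP1 framework lengthens the site in
3-bp steps; the design strategies considered here are expressed as
*finger arrangements* — ordered layouts of SP1 finger labels such as
``321`` (the natural domain), ``3211`` (an added first finger for
binding initiation), ``321321`` (the tandem 2x3 six-finger design,
18-bp site), ``3213211`` (21 bp) and ``32113211`` (24 bp).

Candidate sites for a domain are enumerated from one RSR code per
finger, keeping each finger's top-r triplets and scoring a site by the
sum of its per-finger ranks (lower = preferred).  Fingers labelled 2 or
3 additionally contact the complementary-strand base one position 3' of
their own triplet (the adjacent finger's "4th base"); these overlap
loci are annotated as metadata since the contact stabilises the complex
without widening the matched site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice, product
from typing import Iterable, Iterator, Sequence

from zfsite.sequence import validate_triplet
from zfsite.tables import RsrCode


@dataclass(frozen=True)
class FingerArrangement:
    """An ordered finger layout, e.g. (3, 2, 1) for the natural SP1 domain."""

    layout: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.layout) < 1:
            raise ValueError("arrangement needs at least one finger")
        if any(f not in (1, 2, 3) for f in self.layout):
            raise ValueError(f"finger labels must be SP1 fingers 1-3, got {self.layout}")

    @classmethod
    def parse(cls, text: str | Iterable[int]) -> "FingerArrangement":
        """Parse a layout like ``"321321"`` or an iterable of labels."""
        if isinstance(text, str):
            return cls(tuple(int(c) for c in text.strip()))
        return cls(tuple(int(f) for f in text))

    @property
    def n_fingers(self) -> int:
        return len(self.layout)

    @property
    def site_length(self) -> int:
        """Length of the composite site in bp (3 bp per finger)."""
        return 3 * self.n_fingers

    def __str__(self) -> str:
        return "".join(str(f) for f in self.layout)


@dataclass(frozen=True)
class OverlapAnnotation:
    """A 4th-base overlap contact: ``finger_index`` (0-based in the layout)
    touches the complementary-strand base at site ``position`` (0-based,
    one past its own triplet)."""

    finger_index: int
    finger_label: int
    position: int


@dataclass(frozen=True)
class CompositeSite:
    """A concrete site built from one triplet per finger of an arrangement."""

    arrangement: FingerArrangement
    sequence: str
    overlap_annotations: tuple[OverlapAnnotation, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateSite:
    """A scored candidate site for a multi-finger domain."""

    site: str
    per_finger_ranks: tuple[int, ...]
    combined_rank_score: int


def annotate_overlap_loci(
    arrangement: FingerArrangement | str,
) -> tuple[OverlapAnnotation, ...]:
    """Mark the 4th-base overlap contact of every finger labelled 2 or 3.

    A finger at layout index ``i`` spans site positions ``[3i, 3i+3)``;
    its overlap contact is the complementary-strand base at position
    ``3i + 3`` — the first base of the neighbouring finger's triplet.
    Fingers labelled 1 make no overlap contact (their relaxed recognition
    is tied to binding initiation, not complex stabilisation).
    """
    if isinstance(arrangement, str):
        arrangement = FingerArrangement.parse(arrangement)
    return tuple(
        OverlapAnnotation(finger_index=i, finger_label=label, position=3 * i + 3)
        for i, label in enumerate(arrangement.layout)
        if label in (2, 3)
    )


def build_composite_site(
    arrangement: FingerArrangement | str,
    triplets: Sequence[str],
) -> CompositeSite:
    """Concatenate one triplet per finger (in layout order) into a site.

    The site length is 3 bp per finger: 9 bp for the natural ``321``
    domain, 18 bp for the tandem ``321321`` design, 24 bp for
    ``32113211``.
    """
    if isinstance(arrangement, str):
        arrangement = FingerArrangement.parse(arrangement)
    if len(triplets) != arrangement.n_fingers:
        raise ValueError(
            f"arrangement {arrangement} has {arrangement.n_fingers} fingers "
            f"but {len(triplets)} triplets were supplied"
        )
    seq = "".join(validate_triplet(t) for t in triplets)
    return CompositeSite(
        arrangement=arrangement,
        sequence=seq,
        overlap_annotations=annotate_overlap_loci(arrangement),
    )


def enumerate_candidate_sites(
    codes: Sequence[RsrCode],
    rank_cutoff: int,
) -> Iterator[CandidateSite]:
    """Lazily enumerate all candidate sites from per-finger rank codes.

    Each finger contributes its ``rank_cutoff`` strongest triplets, so
    the stream holds exactly ``rank_cutoff ** n_fingers`` sites (the full
    4^9 = 262,144 site space for a three-finger domain at cutoff 64).
    Sites are scored by the sum of per-finger ranks and yielded in
    lexicographic rank order, best-scoring first overall.
    """
    if not 1 <= rank_cutoff <= 64:
        raise ValueError(f"rank_cutoff must be in 1..64, got {rank_cutoff}")
    if not codes:
        raise ValueError("need at least one rank code")
    tops = [code.top(rank_cutoff) for code in codes]
    for combo in product(*(range(rank_cutoff) for _ in codes)):
        ranks = tuple(r + 1 for r in combo)
        site = "".join(top[r] for top, r in zip(tops, combo))
        yield CandidateSite(
            site=site,
            per_finger_ranks=ranks,
            combined_rank_score=sum(ranks),
        )


def best_candidate_sites(
    codes: Sequence[RsrCode],
    rank_cutoff: int,
    limit: int = 10,
) -> list[CandidateSite]:
    """The ``limit`` lowest-score candidates (ties in enumeration order)."""
    stream = enumerate_candidate_sites(codes, rank_cutoff)
    return sorted(stream, key=lambda c: c.combined_rank_score)[:limit]


def count_candidate_sites(codes: Sequence[RsrCode], rank_cutoff: int) -> int:
    """Number of candidate sites without materialising them."""
    # Consume the stream in chunks to keep memory flat.
    stream = enumerate_candidate_sites(codes, rank_cutoff)
    n = 0
    while True:
        chunk = len(list(islice(stream, 65536)))
        if not chunk:
            return n
        n += chunk
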