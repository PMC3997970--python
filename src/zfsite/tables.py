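"""Packaged reference tables and their typed readers/writers.

Three small TSV fixtures ship inside the package under ``zfsite/data/``:

``triplet_assay_sp1.tsv``
    The quantified EMSA band-shift screen of the SP1 three-finger domain
    against all 64 second-finger triplets: Phosphor Imager P32 counts
    plus the number of exact GGG+triplet+GGG matches in the HuRef human
    genome assembly.  Rows are in descending-count order (the published
    presentation order), which is what the default stable tie policy of
    :func:`zfsite.rsr.compute_rsr_code` keys on.

``rank_codes.tsv``
    The six rank-specific recognition codes (rank 1 = strongest complex)
    for wild-type SP1 and the five second-finger alpha-helix mutants
    CB1, MR14, MQ91, MQ135 and MQ151.

``mutant_helices.tsv``
    The 9-residue alpha-helical region of the second finger for each
    protein, with the exchanged positions recorded as metadata.

Loaders verify a recorded SHA-256 checksum and a handful of internal
consistency facts on every read, so silent fixture corruption cannot
propagate into downstream analyses.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from zfsite.sequence import enumerate_triplets, validate_triplet

PROTEINS = ("SP1", "CB1", "MR14", "MQ91", "MQ135", "MQ151")

_FIXTURE_SHA256 = {
    "triplet_assay_sp1.tsv": "ca0163e4564962894ffc2b0daaf57071fbdf67890fb087ad189648a4d11a05be",
    "rank_codes.tsv": "3f7ac33c556c86fa21204d95a97675ca1d69615d32823347a7be97d7bd818feb",
    "mutant_helices.tsv": "a02110b41715fd827c2084ee7ec601ca83d09f79f85678c11bfb74ca64c3c588",
}

# Facts re-checked on every load of the assay fixture.
ASSAY_OCCURRENCE_TOTAL = 1_261_301
ASSAY_ZERO_COUNT_TRIPLETS = frozenset({"AAA", "AAC", "ACC"})
ASSAY_CGG_ROW = ("CGG", 4570, 16697)


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture is missing, altered or internally inconsistent."""


class TripletAssayRecord(NamedTuple):
    """One triplet with its band-shift count and genome-occurrence count."""

    triplet: str
    p32_count: int
    huref_occurrences: int | None = None


@dataclass(frozen=True)
class RsrCode:
    """A rank-specific recognition code: one protein's full rank-ordered
    permutation of the 64 triplets, rank 1 = strongest complex."""

    protein_id: str
    ranking: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.ranking) != enumerate_triplets():
            seen: set[str] = set()
            dup = next((t for t in self.ranking if t in seen or seen.add(t)), None)
            missing = sorted(set(enumerate_triplets()) - set(self.ranking))
            raise ValueError(
                f"RSR code {self.protein_id!r} is not a permutation of the 64 "
                f"triplets (first duplicate: {dup}, missing: {missing[:3]}...)"
            )

    def rank_of(self, triplet: str) -> int:
        """1-based rank of a triplet in this code."""
        return self.ranking.index(validate_triplet(triplet)) + 1

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]


@dataclass(frozen=True)
class MutantHelix:
    """Alpha-helical residues of a second-finger variant (metadata only)."""

    name: str
    residues: str
    substituted_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.residues) != 9 or not self.residues.isalpha():
            raise ValueError(f"expected 9 one-letter residues, got {self.residues!r}")


def _fixture_text(name: str) -> str:
    try:
        raw = resources.files("zfsite.data").joinpath(name).read_bytes()
    except FileNotFoundError as exc:
        raise FixtureIntegrityError(f"packaged fixture {name} is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if digest != expected:
        raise FixtureIntegrityError(
            f"fixture {name} failed its checksum: sha256 {digest} != recorded {expected}"
        )
    return raw.decode("utf-8")


def _parse_tsv(text: str, source: str) -> tuple[list[str], list[list[str]]]:
    """Parse header + rows from TSV text, skipping '#' comment lines."""
    rows: list[list[str]] = []
    header: list[str] | None = None
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
        else:
            rows.append([f.strip() for f in fields])
    if header is None:
        raise ValueError(f"{source}: no header row found")
    return header, rows


def _records_from_rows(
    header: list[str], rows: list[list[str]], source: str
) -> list[TripletAssayRecord]:
    required = ["triplet", "p32_count"]
    for col in required:
        if col not in header:
            raise ValueError(f"{source}: missing required column {col!r} (header: {header})")
    has_occ = "occurrences" in header
    idx = {c: header.index(c) for c in header}
    records: list[TripletAssayRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        if len(row) != len(header):
            raise ValueError(f"{source}: row {i} has {len(row)} fields, expected {len(header)}")
        try:
            triplet = validate_triplet(row[idx["triplet"]])
            p32 = int(row[idx["p32_count"]])
            occ = int(row[idx["occurrences"]]) if has_occ and row[idx["occurrences"]] else None
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{source}: row {i} is malformed: {exc}") from exc
        if p32 < 0 or (occ is not None and occ < 0):
            raise ValueError(f"{source}: row {i}: counts must be non-negative")
        if triplet in seen:
            raise ValueError(f"{source}: duplicate triplet {triplet} at row {i}")
        seen.add(triplet)
        records.append(TripletAssayRecord(triplet, p32, occ))
    return records


def load_triplet_assay_table() -> list[TripletAssayRecord]:
    """Load the packaged 64-triplet SP1 assay table.

    Verifies the checksum plus three internal facts: the genome-occurrence
    total (1,261,301), the set of triplets with no detectable band shift
    ({AAA, AAC, ACC}), and the strongest row (CGG: 4570 counts, 16,697
    genomic locations).
    """
    header, rows = _parse_tsv(_fixture_text("triplet_assay_sp1.tsv"), "triplet_assay_sp1.tsv")
    records = _records_from_rows(header, rows, "triplet_assay_sp1.tsv")
    if len(records) != 64:
        raise FixtureIntegrityError(f"assay fixture has {len(records)} rows, expected 64")
    total = sum(r.huref_occurrences or 0 for r in records)
    if total != ASSAY_OCCURRENCE_TOTAL:
        raise FixtureIntegrityError(
            f"assay fixture occurrence total {total} != {ASSAY_OCCURRENCE_TOTAL}"
        )
    zeros = {r.triplet for r in records if r.p32_count == 0}
    if zeros != ASSAY_ZERO_COUNT_TRIPLETS:
        raise FixtureIntegrityError(f"assay fixture zero-count set {zeros} is wrong")
    cgg = next(r for r in records if r.triplet == "CGG")
    if (cgg.triplet, cgg.p32_count, cgg.huref_occurrences) != ASSAY_CGG_ROW:
        raise FixtureIntegrityError(f"assay fixture CGG row {cgg} != {ASSAY_CGG_ROW}")
    return records


def load_rank_tables() -> dict[str, RsrCode]:
    """Load the six packaged rank-specific recognition codes, keyed by protein.

    Each column is validated as a full permutation of the 64 triplets; a
    duplicated or missing triplet raises :class:`FixtureIntegrityError`
    naming the column and triplet.
    """
    header, rows = _parse_tsv(_fixture_text("rank_codes.tsv"), "rank_codes.tsv")
    if header[0] != "rank" or tuple(header[1:]) != PROTEINS:
        raise FixtureIntegrityError(f"rank fixture header {header} unexpected")
    if len(rows) != 64:
        raise FixtureIntegrityError(f"rank fixture has {len(rows)} rows, expected 64")
    codes: dict[str, RsrCode] = {}
    for j, protein in enumerate(PROTEINS, start=1):
        column = tuple(validate_triplet(row[j]) for row in rows)
        seen: set[str] = set()
        for t in column:
            if t in seen:
                raise FixtureIntegrityError(f"column {protein}: duplicate triplet {t}")
            seen.add(t)
        missing = set(enumerate_triplets()) - seen
        if missing:
            raise FixtureIntegrityError(
                f"column {protein}: missing triplet(s) {sorted(missing)}"
            )
        codes[protein] = RsrCode(protein_id=protein, ranking=column)
    return codes


def load_mutant_helices() -> dict[str, MutantHelix]:
    """Load the second-finger alpha-helix residues for all six proteins."""
    header, rows = _parse_tsv(_fixture_text("mutant_helices.tsv"), "mutant_helices.tsv")
    helices: dict[str, MutantHelix] = {}
    for row in rows:
        rec = dict(zip(header, row))
        subs = frozenset(
            int(p) for p in rec["substituted_positions"].split(",") if p.strip()
        )
        helices[rec["name"]] = MutantHelix(rec["name"], rec["residues"], subs)
    return helices


def read_assay_table(path: str | Path) -> list[TripletAssayRecord]:
    """Read a triplet-count table from a TSV file.

    Expected columns: ``triplet``, ``p32_count`` and optionally
    ``occurrences``; ``#`` comment lines are ignored.  A table must
    cover all 64 triplets exactly once.
    """
    path = Path(path)
    header, rows = _parse_tsv(path.read_text(encoding="utf-8"), str(path))
    records = _records_from_rows(header, rows, str(path))
    if len(records) != 64:
        raise ValueError(f"{path}: expected 64 triplet rows, found {len(records)}")
    return records


def write_assay_table(records: Iterable[TripletAssayRecord], path: str | Path) -> None:
    """Write records to TSV in the fixture schema (round-trips exactly)."""
    records = list(records)
    has_occ = any(r.huref_occurrences is not None for r in records)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["triplet", "p32_count"] + (["occurrences"] if has_occ else []))
        for r in records:
            row: list[object] = [r.triplet, r.p32_count]
            if has_occ:
                row.append("" if r.huref_occurrences is None else r.huref_occurrences)
            writer.writerow(row)


def fixture_checksums() -> dict[str, str]:
    """Recorded SHA-256 digests of the packaged fixtures (for provenance logs)."""
    return dict(_FIXTURE_SHA256)


def records_as_counts(records: Sequence[TripletAssayRecord]) -> dict[str, int]:
    """Convenience: triplet → p32_count mapping."""
    return {r.triplet: r.p32_count for r in records}
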