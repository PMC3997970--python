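"""Synthetic-data generators standing in for the wet lab and the genome.

Three generators:

* the EMSA probe library — the fixed 58-base double-stranded cassette
  with a 3-base substitution slot, instantiated for any or all of the
  64 triplets;
* noisy band-shift count tables with a known ground-truth rank order,
  for exercising rank-recovery behaviour of the analysis;
* random genomes with an exactly controlled number of planted motif
  occurrences, for exercising the scanner and the dimer-site search.

The EMSA noise model (geometric rank decay, multiplicative lognormal
error, Poisson sampling, detection floor) is a deliberately simple
stand-in whose only job is to produce count tables with the statistical
shape of a real screen — a strong leader decaying over two orders of
magnitude into an undetectable tail; its parameters are configuration,
not biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from zfsite.scan import Genome, _pattern_regex
from zfsite.sequence import enumerate_triplets, validate_sequence, validate_triplet
from zfsite.tables import RsrCode, TripletAssayRecord

#: The EMSA analysis cassette: 58 bases once the NNN slot (0-based
#: positions 27-29) is filled.  The slot sits between GGG flanks, so a
#: filled probe carries GGG+triplet+GGG at positions 24-32.
CASSETTE_TEMPLATE = "GTCGGATCCTGTCTGAGGTGAGTTGGGNNNGGGCTTGTCTTCCGACGTCGAATTCGCG"
CASSETTE_SLOT = slice(27, 30)
CASSETTE_FLANKED_SITE = slice(24, 33)

assert len(CASSETTE_TEMPLATE) == 58
assert CASSETTE_TEMPLATE[CASSETTE_SLOT] == "NNN"


class PlacementError(RuntimeError):
    """Planted motifs could not be placed or scrubbed within the retry budget."""


def generate_probe(triplet: str) -> str:
    """The 58-base cassette with the NNN slot replaced by ``triplet``.

    The triplet is recoverable at positions 27-29 and the probe carries
    the flanked site GGG+triplet+GGG at positions 24-32.
    """
    t = validate_triplet(triplet)
    return CASSETTE_TEMPLATE[: CASSETTE_SLOT.start] + t + CASSETTE_TEMPLATE[CASSETTE_SLOT.stop :]


def generate_probe_set() -> dict[str, str]:
    """One probe per triplet, in canonical enumeration order."""
    return {t: generate_probe(t) for t in enumerate_triplets()}


@dataclass(frozen=True)
class EmsaSimulationConfig:
    """Configuration of the synthetic band-shift screen.

    ``decay`` is either a geometric ratio (mean count at rank r is
    ``count_scale * decay**(r-1)``) or a callable rank → mean count;
    means must be non-increasing in rank.  Ranks whose mean falls below
    ``detection_limit`` read as 0 (no detectable band).  Noise is
    multiplicative lognormal (``sigma`` on the log scale, unit mean)
    followed by Poisson sampling; set ``sigma=0`` and ``poisson=False``
    for a noiseless table.

    Defaults mirror the dynamic range of a real screen: a strongest
    count of ~4570 decaying geometrically by 0.9 per rank to ~10 near
    rank 60, so the weakest few ranks sit at the detection floor.
    """

    true_code: RsrCode
    count_scale: float = 4570.0
    decay: float | Callable[[int], float] = 0.9
    sigma: float = 0.3
    poisson: bool = True
    detection_limit: float = 5.0
    seed: int = 0

    def mean_at(self, rank: int) -> float:
        if callable(self.decay):
            return float(self.decay(rank))
        return self.count_scale * self.decay ** (rank - 1)

    def __post_init__(self) -> None:
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        means = [self.mean_at(r) for r in range(1, 65)]
        if any(b > a for a, b in zip(means, means[1:])):
            raise ValueError("decay must yield non-increasing mean counts in rank")
        if means[-1] < 0:
            raise ValueError("mean counts must be non-negative")


def simulate_emsa_counts(config: EmsaSimulationConfig) -> list[TripletAssayRecord]:
    """Draw a synthetic 64-triplet count table under a known true code.

    Records are returned in the true code's rank order (the presentation
    order a screen report would use), so the stable tie policy of
    :func:`zfsite.rsr.compute_rsr_code` resolves any tied counts in
    favour of the truth — in particular a noiseless table is recovered
    exactly.  Output is a pure function of the config (seeded).
    """
    rng = np.random.default_rng(config.seed)
    records: list[TripletAssayRecord] = []
    for rank, triplet in enumerate(config.true_code.ranking, start=1):
        mean = config.mean_at(rank)
        if mean < config.detection_limit:
            count = 0
        else:
            lam = mean
            if config.sigma > 0:
                # unit-mean multiplicative lognormal error
                lam = mean * rng.lognormal(-config.sigma**2 / 2.0, config.sigma)
            if config.poisson:
                count = int(rng.poisson(lam))
            else:
                count = int(round(lam))
        records.append(TripletAssayRecord(triplet, count, None))
    return records


@dataclass(frozen=True)
class GenomeSimulationConfig:
    """Configuration of a synthetic genome with planted motifs.

    ``planted`` lists (motif, copies) pairs placed at non-overlapping
    random positions.  With ``scrub`` enabled, background windows that
    spuriously match a planted motif — or any extra ACGTN pattern in
    ``scrub_patterns`` — are resampled until each planted motif occurs
    exactly its planted number of times (forward strand), so occurrence
    counts are guaranteed by construction.
    """

    length: int
    base_probabilities: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted: tuple[tuple[str, int], ...] = ()
    scrub: bool = True
    scrub_patterns: tuple[str, ...] = ()
    seed: int = 0
    record_name: str = "sim"
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be non-negative")
        probs = self.base_probabilities
        if len(probs) != 4 or any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError(f"base probabilities must be 4 non-negatives summing to 1: {probs}")
        for motif, copies in self.planted:
            validate_sequence(motif, context="planted motif")
            if copies < 0:
                raise ValueError("planted copy number must be non-negative")
        for pat in self.scrub_patterns:
            validate_sequence(pat, allow_n=True, context="scrub pattern")


def _place_motifs(
    config: GenomeSimulationConfig, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """Choose non-overlapping (start, motif) placements."""
    placements: list[tuple[int, str]] = []
    occupied: list[tuple[int, int]] = []
    for motif, copies in config.planted:
        m = validate_sequence(motif)
        if copies and len(m) > config.length:
            raise PlacementError(f"motif {m} ({len(m)} bp) does not fit in {config.length} bp")
        for _ in range(copies):
            for _attempt in range(config.max_attempts):
                start = int(rng.integers(0, config.length - len(m) + 1))
                span = (start, start + len(m))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    placements.append((start, m))
                    break
            else:
                raise PlacementError(
                    f"could not place copy of {m} without overlap after "
                    f"{config.max_attempts} attempts (genome too crowded)"
                )
    return placements


def simulate_genome(config: GenomeSimulationConfig) -> Genome:
    """Generate a random genome with exactly controlled motif occurrences.

    Background bases are i.i.d. draws from ``base_probabilities``; the
    planted motifs are then written at non-overlapping random positions.
    When ``scrub`` is on, any occurrence of a planted motif (or of an
    extra scrub pattern) outside the planted placements is destroyed by
    resampling the offending window's background bases; scrubbing
    iterates until the genome is clean, failing after ``max_attempts``
    rounds.  The result is a pure function of the seed and config.
    """
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    if config.length == 0:
        if any(copies > 0 for _, copies in config.planted):
            raise PlacementError("cannot plant motifs in a zero-length genome")
        return Genome({config.record_name: ""})
    seq = rng.choice(bases, size=config.length, p=config.base_probabilities)
    placements = _place_motifs(config, rng)
    protected = np.zeros(config.length, dtype=bool)
    for start, motif in placements:
        seq[start : start + len(motif)] = list(motif)
        protected[start : start + len(motif)] = True
    planted_starts = {(start, motif) for start, motif in placements}

    if config.scrub:
        patterns = [m for m, c in config.planted] + list(config.scrub_patterns)
        planted_set = {m for m, _ in config.planted}
        for _round in range(config.max_attempts):
            text = "".join(seq)
            dirty: list[tuple[int, int]] = []
            for pat in patterns:
                rx = _pattern_regex(validate_sequence(pat, allow_n=True))
                for m in rx.finditer(text):
                    start = m.start()
                    if pat in planted_set and (start, pat) in planted_starts:
                        continue
                    if protected[start : start + len(pat)].all():
                        # produced entirely by planted sequence: intentional
                        continue
                    dirty.append((start, start + len(pat)))
            if not dirty:
                break
            for start, end in dirty:
                free = [i for i in range(start, end) if not protected[i]]
                idx = np.array(free)
                seq[idx] = rng.choice(bases, size=len(idx), p=config.base_probabilities)
        else:
            raise PlacementError(
                f"genome not clean after {config.max_attempts} scrub rounds"
            )
    return Genome({config.record_name: "".join(seq)})


def write_probe_fasta(path, *, double_stranded: bool = False) -> None:
    """Write the full 64-probe library as FASTA (60-column wrap).

    With ``double_stranded`` the reverse-complement strand of each probe
    is emitted alongside it (suffix ``_rc``), mirroring the annealed
    double-stranded oligo used in the assay.
    """
    from zfsite.sequence import reverse_complement

    probes = generate_probe_set()
    seqs: dict[str, str] = {}
    for triplet, probe in probes.items():
        seqs[f"probe_{triplet}"] = probe
        if double_stranded:
            seqs[f"probe_{triplet}_rc"] = reverse_complement(probe)
    Genome(seqs).to_fasta(path)
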