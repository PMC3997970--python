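# Methods

## The rank-specific recognition code

The object at the centre of the package is a full rank ordering of the
64 DNA triplets by the stability of the DNA-protein complex a zinc
finger domain forms on them, measured by Phosphor-Imager P32 counts of
EMSA band shifts.  The code is a *permutation*: every triplet appears
exactly once, rank 1 strongest.  This reflects the empirical picture
for the SP1 second finger — detectable complexes for 61 of 64 triplets
with a smooth stability gradient — and is why the package treats
recognition as ordinal throughout.  No binding-energy, PWM or
structural model is fitted; the data do not support one and the
downstream design logic (ordering candidate sites, flagging off-target
risk) only needs ranks.

**Derivation.**  `compute_rsr_code` sorts a 64-row count table by
descending count.  Ties are real (the packaged screen has six tied
pairs) and the default policy is *stable in input order*: the packaged
assay table is stored in its published presentation order, and stable
descending sort is the unique simple rule that reproduces the published
SP1 code at all 64 ranks, including every tied pair.  Lexicographic and
seeded-random tie policies are available for tables without a
meaningful input order.

**Stability grouping.**  The screen partitions at a count threshold
(default 500, in the screen's arbitrary Phosphor-Imager units) into
strong / weak / undetectable.  The comparison is *inclusive* (≥) by
default: the published group of 26 strong complexes contains a triplet
at exactly 500 counts, so a strict comparison would misplace it.  This
is a documented, flaggable choice (`inclusive=False`).

**Composition.**  A triplet is GC-rich iff at least 2 of its 3 bases
are G or C (majority rule — with 3 bases no tie is possible), and
homogeneous ("GC-triplet" / "AT-triplet") iff all three bases fall on
one side.  The majority rule is the unique composition rule consistent
with the published census of the 26 strongest binders (18 GC-rich, 6
GC-triplets, 8 AT-rich, 3 AT-triplets).

**Code comparison.**  Differences between codes (e.g. wild type vs a
second-finger mutant) are quantified with standard rank statistics on
the two rank vectors: Spearman's ρ, Kendall's τ, the Spearman footrule
(L1 distance of ranks) and the signed per-triplet shift.  The source
data support only ordinal claims of altered preference, so the package
reports the statistics and deliberately asserts no significance test.

## Genome scanning

Exact matching uses a straightforward `str.find` sweep; degenerate
(`N`-wildcard) patterns compile to an overlap-aware regex
(`(?=(...))` lookahead) and all `4^N` instantiations are counted in a
single pass, keyed by the bases at the wildcard positions.  Conventions,
fixed once:

- 0-based, half-open, forward-strand coordinates (BED convention), also
  for minus-strand hits;
- overlapping matches counted by default — exact-location counts
  conventionally include overlaps, and the alternative is one flag away;
- forward-strand scanning by default, `both` one flag away.  The
  published human-genome occurrence counts do not state a
  strand/overlap convention, so the scanner exposes all variants
  rather than hard-coding a guess;
- `N` in a genome never matches any query base; record boundaries are
  never crossed;
- patterns with more than 6 wildcard positions are refused (the 4^N
  instantiation table becomes unwieldy) unless explicitly overridden.

**Dimer search.**  A ZFN pair needs its two half-sites on opposite
strands across a spacer.  `find_dimer_sites` matches
`left + N*spacer + right` over a spacer-length range on both strands.
Because published half-site pairs are written in more than one
orientation convention, the query carries an explicit
`right_site_convention`: `as_written` (literal on the left site's
strand) or `opposite_strand` (the site as read 5'→3' on the other
strand, i.e. matched as its reverse complement).  A spacer range is by
construction the disjoint union of the fixed-spacer searches.

`expected_occurrences` gives the i.i.d. background expectation
`(L − k + 1)·Π p(base)` for judging whether an observed count is
surprising; it is validated against Monte-Carlo simulation in the test
suite.

## Composite-site design

Each finger spans 3 bp, so an arrangement of n fingers defines a
3n-bp site: 9 bp for the natural `321` domain up to 24 bp for the
`32113211` design.  This includes the added "first fingers" of the
`3211`-style layouts — whether those relaxed, binding-initiating
fingers truly engage a full triplet is an open biological question, and
the 3 bp/finger span is recorded here as an explicit modelling
assumption.

Candidate sites for a domain are the Cartesian product of each
finger's top-r triplets under its code, scored by the **sum of
per-finger ranks**.  The underlying data are ordinal, so the simplest
monotone aggregate is used; the enumeration is a generator (the full
three-finger space is 64³ = 262,144 sites and streams in well under a
second), and alternative aggregates can be computed from the per-finger
ranks carried on every candidate.

Fingers labelled 2 or 3 contact the complementary-strand base one
position 3' of their own triplet (the neighbouring finger's "4th
base"); finger 1 does not.  These overlap loci are annotated as
metadata only — the contact stabilises the complex but does not widen
the matched site, so annotations never change site length or matching.

## Synthetic data

**Probe library.**  The EMSA cassette is the fixed 58-base oligo
`GTCGGATCCTGTCTGAGGTGAGTTGGG NNN GGGCTTGTCTTCCGACGTCGAATTCGCG` with the
3-base slot at positions 27–29; a filled probe carries the flanked site
`GGG+triplet+GGG` at positions 24–32.  All 64 probes are distinct and
each contains exactly one match of the flanked-site pattern (verified
by scanning in the test suite).  Probes are emitted single-stranded
with an optional reverse-complement companion, mirroring the annealed
double-stranded assay oligo.

**EMSA count simulator.**  Generates count tables with a known true
code, solely to exercise rank recovery; its parameters are
configuration, not biology.  The mean count at rank r is
`scale · decay^(r−1)` (defaults: scale 4570, decay 0.9 per rank —
chosen to mirror the realized dynamic range of the packaged screen,
4570 at rank 1 down to ~10 near rank 60), a detection floor of 5 counts
zeroes the deepest tail, and noise is unit-mean multiplicative
lognormal (σ = 0.3) followed by Poisson sampling.  Records are emitted
in true-rank order, so under the stable tie policy a noiseless table
(`sigma=0, poisson=False`) is recovered *exactly* even where integer
rounding ties adjacent means.  Under default noise the recovered code's
mean Spearman ρ against truth over 100 seeds is ≥ 0.9 (a repository
regression bound; measured ≈ 0.99).

**Genome simulator.**  Backgrounds are i.i.d. draws from a base
distribution; motifs are planted at non-overlapping random positions.
With scrubbing on, any occurrence of a planted motif (or of an extra
user-supplied wildcard pattern) outside the planted placements is
destroyed by resampling the free bases of the offending window,
iterating until clean; matches produced entirely by planted sequence
are left intact, and the procedure fails loudly after a bounded number
of rounds.  After scrubbing, the forward-strand count of each planted
motif equals its planted copy number by construction.  Every generator
is a pure function of its seed and configuration.

**What the synthetic data does not emulate.**  Real genomes are not
i.i.d. — repeats, CpG depletion and GC isochores make real occurrence
counts of GC-rich 9-mers far from the background expectation — and the
count simulator models neither gel physics, protein-concentration
series nor condition dependence (the same finger can rank triplets
differently in different cellular conditions).  Passing tests therefore
demonstrate the *algorithms* are correct on data with known ground
truth, not that the biological conclusions transfer to any particular
genome or condition.  Reproducing the published human-genome occurrence
counts (e.g. 18,279 forward matches of a specific half-site) requires
the specific reference assembly and its unstated search convention;
that path is supported through the FASTA interface but intentionally
not exercised in tests.

## Numerical and interface choices

- Fixture TSVs are checksummed (SHA-256) and re-validated on every
  load, including three internal facts of the assay table (occurrence
  total 1,261,301; zero-count set {AAA, AAC, ACC}; the CGG row).
- Problem sizes in tests and examples are desk-scale by design: 64-row
  tables, genomes of 0.5–30 kb, 100-seed simulation studies — large
  enough to exercise every code path and guarantee the constructions,
  small enough to run in seconds.
- The CLI is a thin delegation layer: logging to stderr, data to files,
  and a provenance JSON (parameters, seed, fixture checksums, package
  version) beside every written output.

## Known limitations

- The five mutant rank codes are carried as given data; their raw
  counts were never published, so only the SP1 column can be re-derived
  from counts.
- No mismatch-tolerant or PWM scanning: matching is exact (plus `N`
  wildcards).  Off-target risk from *near*-matches is out of scope.
- The combined candidate score is ordinal and additive; it is not an
  affinity prediction.
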